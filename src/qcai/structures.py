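"""Structural ground truth for attribution benchmarks.

Parses TCR-pMHC complex structures (PDB or mmCIF, via gemmi), applies the
benchmark inclusion filters (complete TCR α/β chains, full peptide,
intact CDR3 regions, distinct peptide/MHC chain IDs) and computes
residue-level minimum interaction distances: each CDR3 residue to the
closest peptide atom, and each peptide residue to the closest atom in
either CDR3 region. Smaller distance = stronger interaction; these
distances are the proxy ground truth importance scores are scored
against.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "CHAIN_ROLES",
    "Residue",
    "ComplexStructure",
    "Rejection",
    "ResidueDistanceTable",
    "BenchmarkSample",
    "load_complex",
    "passes_inclusion_filters",
    "residue_min_distances",
    "binding_labels",
    "build_benchmark",
    "read_manifest",
]

CHAIN_ROLES = ("tcr_alpha", "tcr_beta", "peptide", "mhc")

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}


@dataclass
class Residue:
    name: str          # 3-letter code
    seqnum: int        # author residue number
    atoms: List[Tuple[str, np.ndarray]]  # (element symbol, xyz in Å)

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.empty((0, 3))
        return np.vstack([xyz for _, xyz in self.atoms])

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.name, "X")


@dataclass
class Rejection:
    sample_id: str
    reason: str


@dataclass
class ComplexStructure:
    sample_id: str
    chains: Dict[str, List[Residue]]
    cdr3_ranges: Dict[str, Tuple[int, int]]  # {"cdr3a": (lo, hi)} author numbers, inclusive

    def region_residues(self, region: str) -> List[Residue]:
        role = {"cdr3a": "tcr_alpha", "cdr3b": "tcr_beta"}[region]
        lo, hi = self.cdr3_ranges[region]
        return [r for r in self.chains.get(role, []) if lo <= r.seqnum <= hi]

    def region_coords(self, region: str) -> np.ndarray:
        residues = self.region_residues(region) if region != "peptide" \
            else self.chains.get("peptide", [])
        parts = [r.coords for r in residues if r.atoms]
        return np.vstack(parts) if parts else np.empty((0, 3))


@dataclass
class ResidueDistanceTable:
    distances: Dict[str, np.ndarray]  # sequence name -> min distances, Å


@dataclass
class BenchmarkSample:
    sample_id: str
    mhc_class: str
    sequences: Dict[str, str]
    distances: ResidueDistanceTable
    provenance: Dict[str, str] = field(default_factory=dict)


def _extract_residues(chain: "gemmi.Chain") -> List[Residue]:
    """Residues ordered by author number; hydrogens dropped; alternate
    locations resolved to the highest-occupancy conformer per atom name."""
    out = []
    for res in chain:
        best: Dict[str, Tuple[float, str, np.ndarray]] = {}
        for atom in res:
            if atom.is_hydrogen():
                continue
            occ = float(atom.occ)
            prev = best.get(atom.name)
            if prev is None or occ > prev[0]:
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                best[atom.name] = (occ, atom.element.name, pos)
        atoms = [(elem, xyz) for _, elem, xyz in best.values()]
        out.append(Residue(name=res.name, seqnum=res.seqid.num, atoms=atoms))
    out.sort(key=lambda r: r.seqnum)
    return out


def load_complex(
    structure_file: Union[str, Path],
    chain_map: Dict[str, str],
    cdr3_ranges: Dict[str, Tuple[int, int]],
    sample_id: Optional[str] = None,
) -> Union[ComplexStructure, Rejection]:
    """Parse one complex; returns a Rejection (not an exception) when a
    mapped chain is missing or the peptide/MHC chain IDs overlap."""
    path = Path(structure_file)
    sample_id = sample_id or path.stem
    if chain_map.get("peptide") == chain_map.get("mhc"):
        return Rejection(sample_id, "overlapping chain IDs")
    structure = gemmi.read_structure(str(path))  # raises on unparseable input
    if len(structure) == 0:
        return Rejection(sample_id, "structure contains no models")
    model = structure[0]  # model 1 for multi-model files
    available = {ch.name: ch for ch in model}
    chains: Dict[str, List[Residue]] = {}
    for role in CHAIN_ROLES:
        cid = chain_map.get(role)
        if cid is None or cid not in available:
            return Rejection(sample_id, f"missing chain ({role}={cid!r})")
        chains[role] = _extract_residues(available[cid])
    return ComplexStructure(sample_id=sample_id, chains=chains,
                            cdr3_ranges=dict(cdr3_ranges))


def passes_inclusion_filters(c: ComplexStructure) -> Tuple[bool, str]:
    """Benchmark inclusion decision with a reason string.

    Accept iff: both TCR chains present and non-empty, peptide non-empty
    with every residue resolved (has atoms), and both CDR3 ranges fully
    resolved (every residue number in the range present with atoms).
    Chain-ID overlap and missing chains are handled in load_complex.
    """
    for role in ("tcr_alpha", "tcr_beta"):
        if not c.chains.get(role):
            return False, f"incomplete TCR chains ({role} empty)"
    peptide = c.chains.get("peptide", [])
    if not peptide:
        return False, "empty peptide chain"
    if any(not r.atoms for r in peptide):
        return False, "unresolved peptide residues"
    for region in ("cdr3a", "cdr3b"):
        lo, hi = c.cdr3_ranges[region]
        residues = {r.seqnum: r for r in c.region_residues(region)}
        for num in range(lo, hi + 1):
            res = residues.get(num)
            if res is None or not res.atoms:
                return False, f"intact CDR3 regions violated ({region} residue {num})"
    return True, "accepted"


def residue_min_distances(region: Sequence[Residue], target_atoms: np.ndarray) -> np.ndarray:
    """Per-residue minimum Euclidean distance (Å) to any target atom."""
    target = np.asarray(target_atoms, dtype=float)
    if target.size == 0:
        raise ValueError("target atom set is empty")
    if not region:
        raise ValueError("residue region is empty")
    out = np.empty(len(region))
    for i, res in enumerate(region):
        coords = res.coords
        if coords.size == 0:
            raise ValueError(f"residue {res.seqnum} has no atoms")
        out[i] = cdist(coords, target).min()
    return out


def binding_labels(distances: np.ndarray, threshold: float) -> np.ndarray:
    """Binding-site labels: residue binds iff its distance <= threshold (Å)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.asarray(distances, dtype=float) <= threshold


def _parse_range(text: str) -> Tuple[int, int]:
    lo, hi = text.split("-")
    return int(lo), int(hi)


def read_manifest(manifest_path: Union[str, Path]) -> List[Dict[str, str]]:
    with open(manifest_path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValueError(f"manifest {manifest_path} lists no samples")
    return rows


def compute_sample_distances(c: ComplexStructure) -> ResidueDistanceTable:
    """Both distance directions: CDR3 regions vs peptide atoms, peptide vs
    the union of CDR3α and CDR3β atoms."""
    pep_atoms = c.region_coords("peptide")
    tables: Dict[str, np.ndarray] = {}
    cdr_atoms = []
    for region in ("cdr3a", "cdr3b"):
        residues = c.region_residues(region)
        tables[region] = residue_min_distances(residues, pep_atoms)
        cdr_atoms.append(np.vstack([r.coords for r in residues]))
    tables["peptide"] = residue_min_distances(c.chains["peptide"], np.vstack(cdr_atoms))
    return ResidueDistanceTable(distances=tables)


def build_benchmark(
    structure_dir: Union[str, Path],
    manifest: Union[str, Path, List[Dict[str, str]]],
) -> Tuple[List[BenchmarkSample], List[Rejection]]:
    """Apply inclusion filters and compute distances for every manifest entry."""
    if isinstance(manifest, (str, Path)):
        rows = read_manifest(manifest)
    else:
        rows = list(manifest)
        if not rows:
            raise ValueError("manifest lists no samples")
    structure_dir = Path(structure_dir)
    samples: List[BenchmarkSample] = []
    rejections: List[Rejection] = []
    for row in rows:
        sample_id = row["sample_id"]
        chain_map = {
            "tcr_alpha": row["chain_alpha"],
            "tcr_beta": row["chain_beta"],
            "peptide": row["chain_peptide"],
            "mhc": row["chain_mhc"],
        }
        ranges = {
            "cdr3a": _parse_range(row["cdr3a_range"]),
            "cdr3b": _parse_range(row["cdr3b_range"]),
        }
        loaded = load_complex(structure_dir / row["file"], chain_map, ranges,
                              sample_id=sample_id)
        if isinstance(loaded, Rejection):
            rejections.append(loaded)
            continue
        ok, reason = passes_inclusion_filters(loaded)
        if not ok:
            rejections.append(Rejection(sample_id, reason))
            continue
        table = compute_sample_distances(loaded)
        sequences = {
            "cdr3a": "".join(r.one_letter for r in loaded.region_residues("cdr3a")),
            "cdr3b": "".join(r.one_letter for r in loaded.region_residues("cdr3b")),
            "peptide": "".join(r.one_letter for r in loaded.chains["peptide"]),
        }
        samples.append(BenchmarkSample(
            sample_id=sample_id,
            mhc_class=row.get("mhc_class", ""),
            sequences=sequences,
            distances=table,
            provenance={"file": row["file"]},
        ))
    return samples, rejections
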