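"""Tabular input/output: importance TSVs, benchmark TSVs, results TSVs.

Every file starts with a provenance header (tool version, config hash,
seed) in ``#``-prefixed comment lines, followed by a tab-separated table.
Long/tidy layouts throughout so downstream plotting needs no reshaping.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .core import TokenImportance, normalize_scores
from .evaluation import EvalResult
from .structures import BenchmarkSample, Rejection

IMPORTANCE_COLUMNS = [
    "sample_id", "sequence_name", "position", "residue",
    "score_raw", "score_normalized", "method",
]
BENCHMARK_COLUMNS = [
    "sample_id", "sequence_name", "position", "residue", "min_distance_angstrom",
]
RESULT_COLUMNS = ["method", "sequence_name", "metric", "setting", "value", "n_samples"]


def config_hash(config: object) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def provenance_header(seed: Optional[int], config: object = None) -> str:
    lines = [f"# qcai {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    return "\n".join(lines) + "\n"


def _write_table(df: pd.DataFrame, path: Union[str, Path],
                 seed: Optional[int], config: object) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def importance_frame(
    per_sample: Dict[str, Dict[str, TokenImportance]], method: str
) -> pd.DataFrame:
    """Rows: sample x sequence x position (1-based), raw + normalized scores."""
    rows = []
    for sample_id, seq_map in per_sample.items():
        for seq_name, imp in sorted(seq_map.items()):
            norm = normalize_scores(imp.scores)
            residues = imp.residues or [""] * len(imp.scores)
            for i, (raw, nrm) in enumerate(zip(imp.scores, norm)):
                rows.append({
                    "sample_id": sample_id,
                    "sequence_name": seq_name,
                    "position": i + 1,
                    "residue": residues[i],
                    "score_raw": float(raw),
                    "score_normalized": float(nrm),
                    "method": method,
                })
    return pd.DataFrame(rows, columns=IMPORTANCE_COLUMNS)


def write_importance_tsv(per_sample, method, path, seed=None, config=None) -> None:
    _write_table(importance_frame(per_sample, method), path, seed, config)


def benchmark_frame(samples: Sequence[BenchmarkSample]) -> pd.DataFrame:
    rows = []
    for sample in samples:
        for seq_name in ("cdr3a", "cdr3b", "peptide"):
            seq = sample.sequences[seq_name]
            dist = sample.distances.distances[seq_name]
            for i, (aa, d) in enumerate(zip(seq, dist)):
                rows.append({
                    "sample_id": sample.sample_id,
                    "sequence_name": seq_name,
                    "position": i + 1,
                    "residue": aa,
                    "min_distance_angstrom": float(d),
                })
    return pd.DataFrame(rows, columns=BENCHMARK_COLUMNS)


def write_benchmark_tsv(samples, path, seed=None, config=None) -> None:
    _write_table(benchmark_frame(samples), path, seed, config)


def write_rejection_log(rejections: Sequence[Rejection], path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [{"sample_id": r.sample_id, "reason": r.reason} for r in rejections],
        columns=["sample_id", "reason"],
    )
    with open(path, "w") as fh:
        fh.write(provenance_header(None))
        df.to_csv(fh, sep="\t", index=False)


def results_frame(results: Iterable[EvalResult]) -> pd.DataFrame:
    rows = [{
        "method": r.method,
        "sequence_name": r.sequence_name,
        "metric": r.metric,
        "setting": r.setting,
        "value": r.value,
        "n_samples": r.n_samples,
    } for r in results]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_tsv(results, path, seed=None, config=None) -> None:
    _write_table(results_frame(results), path, seed, config)


def read_tsv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_sequences_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Sample sequences as plain amino-acid strings (columns: sample_id +
    one column per sequence name, e.g. cdr3a, cdr3b, peptide)."""
    df = pd.read_csv(path, comment="#")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: sequences CSV needs a sample_id column")
    return df
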