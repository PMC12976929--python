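"""Synthetic fixtures: a seeded toy encoder-decoder transformer, planted-contact
3-D complexes, and score/distance pairs with controlled association.

Everything here is a pure function of its seed, so every artifact is
reproducible bit-for-bit. The toy transformer implements the full capture
contract of :mod:`qcai.adapter` — attention, query/key activations, and
analytic gradients of the target score — in plain NumPy, with the forward
and backward passes written out explicitly. Realism is not the goal;
controllable, verifiable dependence structure is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .adapter import (
    CROSS_ATTENTION,
    SELF_ATTENTION,
    AttentionRecord,
    CaptureRun,
    ConfigurationError,
    LayerTopology,
    TargetSpec,
    TokenMap,
    compute_target_loss,
)

__all__ = [
    "AMINO_ACIDS",
    "SPECIAL_TOKENS",
    "PAD",
    "ToyModelConfig",
    "ToyTransformer",
    "make_toy_model",
    "PlantedComplexConfig",
    "make_planted_complex",
    "make_score_distance_pairs",
    "random_peptide",
    "write_fixture_suite",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD, BOS, EOS = "<PAD>", "<BOS>", "<EOS>"
SPECIAL_TOKENS = (PAD, BOS, EOS)
VOCAB: Dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
for i, tok in enumerate(SPECIAL_TOKENS):
    VOCAB[tok] = len(AMINO_ACIDS) + i

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


# ---------------------------------------------------------------------------
# toy encoder-decoder transformer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyModelConfig:
    """Configuration of the seeded toy transformer.

    One self-attention encoder stack per input sequence; the decoder runs
    ``n_decoder_layers`` rounds of one cross-attention block per key
    sequence, queries carried by ``query_seq``. When ``planted_key_seq``
    is set, the model output is constructed to depend on exactly the
    embeddings at ``planted_positions`` of that sequence and nothing
    else: keys and queries of the planted cross-attention block come from
    positional encodings only, values are zero outside the planted
    positions, and all other computation paths are cut from the readout.
    """

    d_model: int = 16
    n_heads: int = 2
    n_encoder_layers: int = 1
    n_decoder_layers: int = 1
    seed: int = 0
    query_seq: str = "cdr3b"
    key_seqs: Tuple[str, ...] = ("pep",)
    planted_key_seq: Optional[str] = None
    planted_positions: Tuple[int, ...] = ()
    head: str = "binary"  # "binary" (single logit) or "token" (per-position vocab logits)
    max_len: int = 64

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ConfigurationError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        if self.n_encoder_layers < 0 or self.n_decoder_layers < 1:
            raise ConfigurationError("need n_encoder_layers >= 0 and n_decoder_layers >= 1")
        if self.planted_key_seq is not None and self.planted_key_seq not in self.key_seqs:
            raise ConfigurationError(
                f"planted_key_seq {self.planted_key_seq!r} is not a key sequence"
            )
        if self.head not in ("binary", "token"):
            raise ConfigurationError(f"unknown head {self.head!r}")


@dataclass
class _Block:
    name: str
    kind: str
    query_source: str
    key_source: str
    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray
    w_o: np.ndarray
    planted: bool = False


@dataclass
class _BlockCache:
    block: _Block
    x_q: np.ndarray
    x_k: np.ndarray
    q: np.ndarray
    k: np.ndarray
    v: np.ndarray
    attn: np.ndarray  # [H, N, N']
    o: np.ndarray
    out: np.ndarray
    grad_attn: Optional[np.ndarray] = None
    grad_q: Optional[np.ndarray] = None
    grad_k: Optional[np.ndarray] = None


class ToyTransformer:
    """A tiny, deterministic encoder-decoder attention model in NumPy.

    Implements the :class:`~qcai.adapter.CaptureModel` protocol. The
    scalar differentiated during capture is the target log-likelihood
    (log-probability of the target class, or summed target-token
    log-probabilities), so a positive attention gradient marks evidence
    that supports the target.
    """

    EMB_SCALE = 0.6
    POS_SCALE = 0.05
    W_SCALE = 0.3

    def __init__(self, cfg: ToyModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.d_model
        self.emb = rng.normal(0.0, self.EMB_SCALE, size=(len(VOCAB), d))
        self.emb[VOCAB[PAD]] = 0.0  # padding carries no signal
        self.pos = rng.normal(0.0, self.POS_SCALE, size=(cfg.max_len, d))
        self.blocks: List[_Block] = []
        for s in self._all_seqs():
            for i in range(cfg.n_encoder_layers):
                self.blocks.append(self._make_block(rng, f"enc:{s}:{i}", SELF_ATTENTION, s, s))
        for r in range(cfg.n_decoder_layers):
            for s in cfg.key_seqs:
                blk = self._make_block(rng, f"dec:{s}:{r}", CROSS_ATTENTION, cfg.query_seq, s)
                blk.planted = cfg.planted_key_seq == s
                self.blocks.append(blk)
        self.w_read = rng.normal(0.0, self.W_SCALE, size=d)
        self.u_read = np.abs(rng.normal(0.0, 1.0, size=d)) + 0.5  # positive readout (planted mode)
        self.w_out = rng.normal(0.0, self.W_SCALE, size=(d, len(VOCAB)))
        self.bias = 0.0

    # -- plumbing ----------------------------------------------------------

    def _all_seqs(self) -> List[str]:
        return [self.cfg.query_seq] + [s for s in self.cfg.key_seqs if s != self.cfg.query_seq]

    def _make_block(self, rng, name, kind, qsrc, ksrc) -> _Block:
        d = self.cfg.d_model
        def w():
            return rng.normal(0.0, self.W_SCALE / math.sqrt(d), size=(d, d))
        return _Block(name, kind, qsrc, ksrc, w(), w(), w(), w())

    def sequence_names(self) -> Sequence[str]:
        return tuple(self._all_seqs())

    @staticmethod
    def tokenize(tokens: Sequence[str]) -> np.ndarray:
        ids = []
        for t in tokens:
            if t not in VOCAB:
                raise ConfigurationError(f"token {t!r} not in the model vocabulary")
            ids.append(VOCAB[t])
        return np.asarray(ids, dtype=int)

    # -- forward -----------------------------------------------------------

    def _split(self, m: np.ndarray) -> np.ndarray:
        t, d = m.shape
        h = self.cfg.n_heads
        return m.reshape(t, h, d // h).transpose(1, 0, 2)  # [H, T, dh]

    @staticmethod
    def _merge(m: np.ndarray) -> np.ndarray:
        h, t, dh = m.shape
        return m.transpose(1, 0, 2).reshape(t, h * dh)

    def _run_block(self, blk: _Block, x_q: np.ndarray, x_k: np.ndarray,
                   emb_k: np.ndarray, attn_override: Optional[np.ndarray]) -> _BlockCache:
        cfg = self.cfg
        dh = cfg.d_model // cfg.n_heads
        if blk.planted:
            n_q, n_k = x_q.shape[0], x_k.shape[0]
            q = self.pos[:n_q] @ blk.w_q
            k = self.pos[:n_k] @ blk.w_k
            v = np.zeros((n_k, cfg.d_model))
            mask = np.asarray(cfg.planted_positions, dtype=int)
            v[mask] = (emb_k[mask] @ blk.w_v) ** 2  # nonnegative planted values
        else:
            q = x_q @ blk.w_q
            k = x_k @ blk.w_k
            v = x_k @ blk.w_v
        qh, kh, vh = self._split(q), self._split(k), self._split(v)
        scores = qh @ kh.transpose(0, 2, 1) / math.sqrt(dh)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(axis=-1, keepdims=True)
        if attn_override is not None:
            attn = np.asarray(attn_override, dtype=float)
        oh = attn @ vh
        o = self._merge(oh)
        if blk.planted:
            out = o  # readout sees only the planted value path
        else:
            out = o @ blk.w_o + x_q
        return _BlockCache(blk, x_q, x_k, q, k, v, attn, o, out)


    def _forward(self, ids: Dict[str, np.ndarray],
                 attn_override: Optional[Dict[str, np.ndarray]] = None):
        cfg = self.cfg
        attn_override = attn_override or {}
        x = {s: self.emb[ids[s]] + self.pos[: len(ids[s])] for s in ids}
        caches: List[_BlockCache] = []
        enc_out = dict(x)
        for blk in self.blocks:
            if blk.kind != SELF_ATTENTION:
                continue
            cache = self._run_block(blk, enc_out[blk.query_source], enc_out[blk.query_source],
                                    x[blk.key_source], attn_override.get(blk.name))
            caches.append(cache)
            if cfg.planted_key_seq is None:
                enc_out[blk.query_source] = cache.out
            # planted mode: encoders are captured but pass inputs through,
            # keeping the output an exact function of the planted embeddings
        h = enc_out[cfg.query_seq]
        for blk in self.blocks:
            if blk.kind != CROSS_ATTENTION:
                continue
            cache = self._run_block(blk, h, enc_out[blk.key_source],
                                    x[blk.key_source], attn_override.get(blk.name))
            caches.append(cache)
            if cfg.planted_key_seq is None or blk.planted:
                h = cache.out
        if cfg.head == "binary":
            outputs = np.array([h.mean(axis=0) @ self._readout() + self.bias])
        else:
            outputs = h @ self.w_out
        return outputs, h, caches

    def _readout(self) -> np.ndarray:
        return self.u_read if self.cfg.planted_key_seq is not None else self.w_read

    # -- public API --------------------------------------------------------

    def forward_logits(self, inputs: Dict[str, Sequence[str]],
                       attn_override: Optional[Dict[str, np.ndarray]] = None) -> np.ndarray:
        ids = {s: self.tokenize(toks) for s, toks in inputs.items()}
        self._check_planted(ids)
        outputs, _, _ = self._forward(ids, attn_override)
        return outputs

    def target_score(self, inputs: Dict[str, Sequence[str]], target: TargetSpec,
                     attn_override: Optional[Dict[str, np.ndarray]] = None) -> float:
        """Target log-likelihood (the scalar whose gradients are captured)."""
        return -compute_target_loss(self.forward_logits(inputs, attn_override), target)

    def predict_proba(self, inputs: Dict[str, Sequence[str]], target: TargetSpec) -> float:
        return float(np.exp(self.target_score(inputs, target)))

    def _check_planted(self, ids: Dict[str, np.ndarray]) -> None:
        cfg = self.cfg
        if cfg.planted_key_seq is not None:
            n = len(ids[cfg.planted_key_seq])
            for p in cfg.planted_positions:
                if not 0 <= p < n:
                    raise ConfigurationError(
                        f"planted position {p} outside sequence of length {n}"
                    )

    def capture(self, inputs: Dict[str, Sequence[str]], target: TargetSpec) -> CaptureRun:
        ids = {s: self.tokenize(toks) for s, toks in inputs.items()}
        self._check_planted(ids)
        outputs, h, caches = self._forward(ids)
        loss = compute_target_loss(outputs, target)
        self._backward(outputs, h, caches, ids, target)
        records = []
        # decoder blocks come last in forward order; output->backwards means
        # reversed forward order, with layer_id 0 closest to the output
        for layer_id, cache in enumerate(reversed(caches)):
            blk = cache.block
            topo = LayerTopology(
                layer_id=layer_id,
                kind=blk.kind,
                query_source=blk.query_source,
                key_source=blk.key_source,
                upstream_ids=(layer_id + 1,) if layer_id + 1 < len(caches) else (),
            )
            records.append(AttentionRecord(
                topology=topo,
                attention=cache.attn,
                query_act=cache.q,
                key_act=cache.k,
                grad_attention=cache.grad_attn,
                grad_query=cache.grad_q,
                grad_key=cache.grad_k,
            ))
        token_maps = {
            s: TokenMap(list(toks), [t in SPECIAL_TOKENS for t in toks])
            for s, toks in inputs.items()
        }
        return CaptureRun(records=records, loss_value=float(loss),
                          target_spec=target, token_maps=token_maps)

    # -- backward ----------------------------------------------------------

    def _head_grad(self, outputs: np.ndarray, h: np.ndarray, target: TargetSpec) -> np.ndarray:
        """d(target log-likelihood)/dh for the decoder output h."""
        cfg = self.cfg
        if cfg.head == "binary":
            logit = float(outputs[0])
            if target.kind != "class":
                raise ConfigurationError("binary head supports class targets only")
            p = 1.0 / (1.0 + math.exp(-logit))
            dlogit = 1.0 - p  # d log sigma(logit) / d logit
            return np.tile((dlogit / h.shape[0]) * self._readout(), (h.shape[0], 1))
        # token head: outputs [T x V]
        logits = outputs
        m = logits.max(axis=-1, keepdims=True)
        ez = np.exp(logits - m)
        soft = ez / ez.sum(axis=-1, keepdims=True)
        dlogits = np.zeros_like(logits)
        for pos, tok in zip(target.positions or (), target.token_ids or ()):
            onehot = np.zeros(logits.shape[1])
            onehot[tok] = 1.0
            dlogits[pos] += onehot - soft[pos]
        return dlogits @ self.w_out.T

    def _backward(self, outputs, h, caches, ids, target) -> None:
        cfg = self.cfg
        dh = self._head_grad(outputs, h, target)
        d_enc: Dict[str, np.ndarray] = {s: np.zeros_like(self.emb[ids[s]]) for s in ids}
        dec_caches = [c for c in caches if c.block.kind == CROSS_ATTENTION]
        enc_caches = [c for c in caches if c.block.kind == SELF_ATTENTION]
        g = dh
        for cache in reversed(dec_caches):
            if cfg.planted_key_seq is not None and not cache.block.planted:
                self._zero_grads(cache)
                continue
            g, dxk = self._block_backward(cache, g)
            d_enc[cache.block.key_source] += dxk
        d_enc[cfg.query_seq] += g
        # encoder stacks, deepest layer first per sequence
        for cache in reversed(enc_caches):
            if cfg.planted_key_seq is not None:
                self._zero_grads(cache)  # passthrough: no gradient flows via attention
                continue
            seq = cache.block.query_source
            dxq, dxk = self._block_backward(cache, d_enc[seq])
            d_enc[seq] = dxq + dxk

    @staticmethod
    def _zero_grads(cache: _BlockCache) -> None:
        cache.grad_attn = np.zeros_like(cache.attn)
        cache.grad_q = np.zeros_like(cache.q)
        cache.grad_k = np.zeros_like(cache.k)

    def _block_backward(self, cache: _BlockCache, g: np.ndarray):
        """Backprop one attention block; returns (dL/dx_q, dL/dx_k)."""
        blk = cache.block
        cfg = self.cfg
        dh_dim = cfg.d_model // cfg.n_heads
        if blk.planted:
            do = g  # out = o
            dxq = np.zeros_like(cache.x_q)
        else:
            do = g @ blk.w_o.T
            dxq = g.copy()  # residual
        doh = self._split(do)
        ah = cache.attn
        vh = self._split(cache.v)
        qh, kh = self._split(cache.q), self._split(cache.k)
        d_attn = doh @ vh.transpose(0, 2, 1)
        dvh = ah.transpose(0, 2, 1) @ doh
        ds = ah * (d_attn - (d_attn * ah).sum(axis=-1, keepdims=True))
        dqh = ds @ kh / math.sqrt(dh_dim)
        dkh = ds.transpose(0, 2, 1) @ qh / math.sqrt(dh_dim)
        cache.grad_attn = d_attn
        cache.grad_q = self._merge(dqh)
        cache.grad_k = self._merge(dkh)
        dq, dk, dv = self._merge(dqh), self._merge(dkh), self._merge(dvh)
        if blk.planted:
            # queries/keys are positional: no token-embedding gradient there;
            # the value path flows only through the planted positions
            dxk = np.zeros_like(cache.x_k)
            mask = np.asarray(cfg.planted_positions, dtype=int)
            # v[mask] = (emb W_v)^2; gradient wrt emb omitted from records
            # (records carry dQ/dK only), so nothing more to propagate here
            return dxq, dxk
        dxq = dxq + dq @ blk.w_q.T
        dxk = dk @ blk.w_k.T + dv @ blk.w_v.T
        if blk.kind == SELF_ATTENTION:
            return dxq, dxk
        return dxq, dxk


def make_toy_model(cfg: ToyModelConfig) -> ToyTransformer:
    """Build the seeded toy transformer conforming to the capture contract."""
    return ToyTransformer(cfg)


# ---------------------------------------------------------------------------
# planted-contact complexes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedComplexConfig:
    """A synthetic TCR-pMHC complex with controlled interface distances.

    Residues are single pseudo-atoms on a lattice with spacing
    ``background_distance``; each ``interface_pairs`` entry
    ``(region, region_pos, peptide_pos)`` (0-based, region in
    {"cdr3a", "cdr3b"}) is placed at ``contact_distance`` (± up to 0.1 Å
    of seeded jitter) from its peptide partner, every other inter-region
    residue pair sits at >= ``background_distance``.
    """

    cdr3a_len: int = 12
    cdr3b_len: int = 13
    peptide_len: int = 9
    interface_pairs: Tuple[Tuple[str, int, int], ...] = ()
    contact_distance: float = 3.5
    background_distance: float = 10.0
    seed: int = 0
    flank_len: int = 3  # non-CDR3 residues on each side of the TCR chains
    mhc_class: str = "I"

    def __post_init__(self) -> None:
        if self.contact_distance >= self.background_distance:
            raise ValueError("contact_distance must be smaller than background_distance")
        lens = {"cdr3a": self.cdr3a_len, "cdr3b": self.cdr3b_len}
        seen = set()
        for region, rpos, ppos in self.interface_pairs:
            if region not in lens:
                raise ValueError(f"unknown region {region!r}")
            if not 0 <= rpos < lens[region]:
                raise ValueError(f"{region} position {rpos} out of range")
            if not 0 <= ppos < self.peptide_len:
                raise ValueError(f"peptide position {ppos} out of range")
            if (region, rpos) in seen:
                raise ValueError(
                    f"residue {region}[{rpos}] appears in more than one contact pair; "
                    "geometrically infeasible for a point residue"
                )
            seen.add((region, rpos))


def _pdb_atom_line(serial: int, resname: str, chain: str, resseq: int,
                   xyz: np.ndarray) -> str:
    return (
        f"ATOM  {serial:5d}  CA  {resname:>3s} {chain}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f" C"
    )


def make_planted_complex(cfg: PlantedComplexConfig, path: Path) -> Dict[str, object]:
    """Write a planted-contact complex as a PDB file; return the truth table.

    Returns a dict with the chain sequences, CDR3 residue-number ranges
    (1-based, inclusive) and intended per-residue minimum interaction
    distances for cdr3a, cdr3b (to peptide atoms) and peptide (to the
    union of CDR3 atoms).
    """
    rng = np.random.default_rng(cfg.seed)
    b, c = cfg.background_distance, cfg.contact_distance
    seqs = {
        "cdr3a": random_peptide(rng, cfg.cdr3a_len),
        "cdr3b": random_peptide(rng, cfg.cdr3b_len),
        "peptide": random_peptide(rng, cfg.peptide_len),
        "mhc": random_peptide(rng, 6),
        "flank_a": (random_peptide(rng, cfg.flank_len), random_peptide(rng, cfg.flank_len)),
        "flank_b": (random_peptide(rng, cfg.flank_len), random_peptide(rng, cfg.flank_len)),
    }
    pep_xyz = np.array([[i * b, 0.0, 0.0] for i in range(cfg.peptide_len)])
    region_xyz = {
        "cdr3a": np.array([[j * b, b, 0.0] for j in range(cfg.cdr3a_len)]),
        "cdr3b": np.array([[j * b, -b, 0.0] for j in range(cfg.cdr3b_len)]),
    }
    sides = {"cdr3a": 1.0, "cdr3b": -1.0}
    for region, rpos, ppos in cfg.interface_pairs:
        jitter = rng.uniform(-0.1, 0.1)
        region_xyz[region][rpos] = [ppos * b, sides[region] * (c + jitter), 0.0]
    # verify the construction: contacts near c, everything else >= b
    from scipy.spatial.distance import cdist

    truth: Dict[str, np.ndarray] = {}
    for region in ("cdr3a", "cdr3b"):
        d = cdist(region_xyz[region], pep_xyz).min(axis=1)
        truth[region] = d
    cdr_all = np.vstack([region_xyz["cdr3a"], region_xyz["cdr3b"]])
    truth["peptide"] = cdist(pep_xyz, cdr_all).min(axis=1)
    contact_rows = {("cdr3a", r): p for (reg, r, p) in cfg.interface_pairs if reg == "cdr3a"}
    contact_rows.update({("cdr3b", r): p for (reg, r, p) in cfg.interface_pairs if reg == "cdr3b"})
    for region in ("cdr3a", "cdr3b"):
        for j, d in enumerate(truth[region]):
            planted = (region, j) in contact_rows
            if planted and not abs(d - c) <= 0.1 + 1e-9:
                raise ValueError("geometric infeasibility: contact not at contact_distance")
            if not planted and d < b - 1e-9:
                raise ValueError(
                    "geometric infeasibility: too many contacts for the given lengths"
                )
    # assemble chains; flanks and MHC far from the interface
    far_z = 3 * b
    lines: List[str] = ["REMARK   1 SYNTHETIC PLANTED-CONTACT COMPLEX"]
    serial = 1

    def emit(chain: str, resseq: int, letter: str, xyz) -> None:
        nonlocal serial
        lines.append(_pdb_atom_line(serial, THREE_LETTER[letter], chain, resseq,
                                    np.asarray(xyz, dtype=float)))
        serial += 1

    ranges = {}
    for chain_id, region, flanks in (("A", "cdr3a", "flank_a"), ("B", "cdr3b", "flank_b")):
        resseq = 1
        pre, post = seqs[flanks]
        for i, aa in enumerate(pre):
            emit(chain_id, resseq, aa, [i * b, sides[region] * b, far_z])
            resseq += 1
        start = resseq
        for j, aa in enumerate(seqs[region]):
            emit(chain_id, resseq, aa, region_xyz[region][j])
            resseq += 1
        ranges[region] = (start, resseq - 1)
        for i, aa in enumerate(post):
            emit(chain_id, resseq, aa, [(10 + i) * b, sides[region] * b, far_z])
            resseq += 1
        lines.append("TER")
    for i, aa in enumerate(seqs["peptide"]):
        emit("C", i + 1, aa, pep_xyz[i])
    lines.append("TER")
    for i, aa in enumerate(seqs["mhc"]):
        emit("D", i + 1, aa, [i * b, 0.0, -far_z])
    lines.append("TER")
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return {
        "sequences": {k: seqs[k] for k in ("cdr3a", "cdr3b", "peptide")},
        "cdr3a_range": ranges["cdr3a"],
        "cdr3b_range": ranges["cdr3b"],
        "distances": truth,
        "interface_pairs": cfg.interface_pairs,
        "mhc_class": cfg.mhc_class,
    }


# ---------------------------------------------------------------------------
# score/distance pairs with controlled association
# ---------------------------------------------------------------------------

def make_score_distance_pairs(
    n_residues: int, association: float, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Distances uniform on [2,10] Å and scores with a target Spearman association.

    Uses a Gaussian copula: for a bivariate normal with Pearson correlation
    rho, the Spearman correlation is (6/pi)·asin(rho/2), so rho =
    2·sin(pi·association/6) hits the requested rank association. The
    endpoints ±1 are exact (scores a strictly monotone function of
    distance).
    """
    if not -1.0 <= association <= 1.0:
        raise ValueError(f"association must be in [-1,1], got {association}")
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_residues)
    if association == 1.0:
        y = x
    elif association == -1.0:
        y = -x
    else:
        rho = 2.0 * math.sin(math.pi * association / 6.0)
        y = rho * x + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n_residues)
    distances = 2.0 + 8.0 * norm.cdf(x)
    scores = norm.cdf(y)
    return scores, distances


# ---------------------------------------------------------------------------
# fixture suite (CLI entry)
# ---------------------------------------------------------------------------

def write_fixture_suite(out_dir: Path, seed: int = 0, n_complexes: int = 3,
                        drop_chain_in_last: bool = False) -> Dict[str, Path]:
    """Write a self-contained fixture set: PDB complexes + manifest + sequences.

    Each complex gets two planted CDR3α and two CDR3β contacts at 3.5 Å
    (background 10 Å). With ``drop_chain_in_last`` the final complex is
    written without its TCRα chain so the inclusion filters have
    something to reject.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest_rows = []
    seq_rows = []
    for i in range(n_complexes):
        cfg = PlantedComplexConfig(
            interface_pairs=(
                ("cdr3a", int(rng.integers(0, 12)), int(rng.integers(0, 9))),
                ("cdr3b", int(rng.integers(0, 13)), int(rng.integers(0, 9))),
            ),
            seed=int(rng.integers(0, 2**31 - 1)),
            mhc_class="I" if rng.random() < 0.8 else "II",
        )
        pdb_path = out_dir / f"complex_{i:03d}.pdb"
        truth = make_planted_complex(cfg, pdb_path)
        if drop_chain_in_last and i == n_complexes - 1:
            text = pdb_path.read_text().splitlines()
            kept = [ln for ln in text if not (ln.startswith("ATOM") and ln[21] == "A")]
            pdb_path.write_text("\n".join(kept) + "\n")
        a0, a1 = truth["cdr3a_range"]
        b0, b1 = truth["cdr3b_range"]
        manifest_rows.append(
            f"sample_{i:03d},{pdb_path.name},A,B,C,D,{a0}-{a1},{b0}-{b1},{truth['mhc_class']}"
        )
        s = truth["sequences"]
        seq_rows.append(f"sample_{i:03d},{s['cdr3a']},{s['cdr3b']},{s['peptide']}")
    manifest = out_dir / "manifest.csv"
    manifest.write_text(
        "sample_id,file,chain_alpha,chain_beta,chain_peptide,chain_mhc,"
        "cdr3a_range,cdr3b_range,mhc_class\n" + "\n".join(manifest_rows) + "\n"
    )
    sequences = out_dir / "sequences.csv"
    sequences.write_text("sample_id,cdr3a,cdr3b,peptide\n" + "\n".join(seq_rows) + "\n")
    return {"manifest": manifest, "sequences": sequences, "dir": out_dir}
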