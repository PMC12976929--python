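"""Cross-attention attribution (QCAI).

The method decomposes a gradient-weighted attention importance map into
per-token relevance for the query sequence and the key sequence of every
cross-attention layer, then aggregates across layers.

For one layer with post-softmax attention A (H x N x N'), queries Q
(N x d) and keys K (N' x d), and gradients of a scalar target loss:

* importance map          S(A) = E_H[ReLU(dL/dA * A)]  (+ I when square)
* intrinsic query scores  w_Q  = max_feat ReLU(dL/dQ * Q)
* attention-conditioned   w_A  = max_feat ReLU( S(A) @ pinv(K^T) )
  query scores — the map is projected back into query-feature space
  through the Moore-Penrose pseudoinverse of K^T, using the factorization
  A ~ Q K^T (softmax and 1/sqrt(d) treated as an approximation)
* intrinsic key scores    w_K  = max_feat ReLU(dL/dK * K)
* attention-conditioned   w_A' = max over queries of S(A) per key column
* combined                S(Q;A) = max(w_A, w_Q),  S(K;A) = max(w_A', w_K)

All scores live in the nonnegative cone, so element-wise max and product
are closed aggregation operators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .adapter import (
    CROSS_ATTENTION,
    AttentionRecord,
    CaptureRun,
    LayerTopology,
)

__all__ = [
    "ImportanceMap",
    "TokenImportance",
    "attention_importance_map",
    "intrinsic_token_importance",
    "project_to_query_space",
    "query_projection_importance",
    "key_attention_importance",
    "combine_importance",
    "aggregate_layers",
    "explain",
    "normalize_scores",
]

logger = logging.getLogger(__name__)

#: SVD cutoff for the pseudoinverse; keeps rank-deficient keys well-defined.
PINV_RCOND = 1e-10
#: condition number above which a warning is logged.
CONDITION_WARN = 1e8


@dataclass
class ImportanceMap:
    """Head-averaged gradient-weighted attention importance for one layer."""

    values: np.ndarray  # [N x N'], nonnegative
    layer_id: int
    includes_identity: bool

    def __post_init__(self) -> None:
        if (np.asarray(self.values) < 0).any():
            raise ValueError("importance map entries must be nonnegative")


@dataclass
class TokenImportance:
    """Per-token nonnegative relevance for one named input sequence."""

    sequence_name: str
    scores: np.ndarray
    provenance: str = "combined"
    residues: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if (self.scores < 0).any():
            raise ValueError("token importance scores must be nonnegative")

    @property
    def normalized(self) -> np.ndarray:
        return normalize_scores(self.scores)


def normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0,1]; a constant vector maps to zeros.

    Reporting-only rescale so percentile-based metrics and cross-method
    comparisons share a scale; ranking is unchanged.
    """
    s = np.asarray(scores, dtype=float)
    span = s.max() - s.min() if s.size else 0.0
    if span <= 0:
        return np.zeros_like(s)
    return (s - s.min()) / span


def attention_importance_map(record: AttentionRecord) -> ImportanceMap:
    """Head-average of ReLU(dL/dA * A), plus I on square (self-attention) maps.

    The identity term models the residual connection, which only exists
    when query and key sequences coincide, so it is omitted for the
    non-square cross-attention case.
    """
    a = np.asarray(record.attention, dtype=float)
    g = np.asarray(record.grad_attention, dtype=float)
    if a.shape != g.shape:
        raise ValueError(f"attention {a.shape} and gradient {g.shape} shapes differ")
    values = np.maximum(g * a, 0.0).mean(axis=0)
    n, n_keys = values.shape
    square = n == n_keys
    if square:
        values = values + np.eye(n)
    return ImportanceMap(values=values, layer_id=record.topology.layer_id,
                         includes_identity=square)


def intrinsic_token_importance(activation: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Per-token max over features of ReLU(grad * activation).

    Works for both queries and keys; tokens along axis 0. Per-head
    activations ([H, T, d]) are head-averaged after the ReLU, mirroring
    the head average in the attention importance map.
    """
    act = np.asarray(activation, dtype=float)
    g = np.asarray(grad, dtype=float)
    if act.shape != g.shape:
        raise ValueError(f"activation {act.shape} and gradient {g.shape} shapes differ")
    rel = np.maximum(g * act, 0.0)
    if rel.ndim == 3:
        rel = rel.mean(axis=0)
    return rel.max(axis=-1)


def project_to_query_space(values: np.ndarray, key_act: np.ndarray) -> np.ndarray:
    """X = S @ pinv(K^T): undo the key factor of an importance map.

    Exact whenever S factors as X K^T with K of full column rank
    (pinv(K^T) = K (K^T K)^{-1} there); the SVD pseudoinverse keeps
    rank-deficient keys well-defined instead of raising.
    """
    s = np.asarray(values, dtype=float)
    k = np.asarray(key_act, dtype=float)
    if s.shape[1] != k.shape[0]:
        raise ValueError(
            f"importance map has {s.shape[1]} key columns but key_act has {k.shape[0]} rows"
        )
    if k.size:
        sv = np.linalg.svd(k, compute_uv=False)
        if sv[-1] > 0 and sv[0] / max(sv[-1], np.finfo(float).tiny) > CONDITION_WARN:
            logger.warning(
                "key activation matrix is ill-conditioned (cond=%.3e); "
                "pseudoinverse projection may be unstable", sv[0] / sv[-1],
            )
    return s @ np.linalg.pinv(k.T, rcond=PINV_RCOND)


def query_projection_importance(imap: ImportanceMap, key_act: np.ndarray) -> np.ndarray:
    """Project the importance map into query-feature space and score tokens.

    ReLU before the feature max keeps the result comparable with the
    intrinsic query scores (all relevances stay in the nonnegative cone).
    """
    x = project_to_query_space(imap.values, key_act)
    return np.maximum(x, 0.0).max(axis=-1)


def key_attention_importance(record: AttentionRecord) -> np.ndarray:
    """Max relevance of each key over all queries (and heads).

    Column-wise maximum of the head-averaged ReLU(dL/dA * A) map — the
    attention matrix already maps queries into key space, so no
    pseudoinverse is needed on this side.
    """
    a = np.asarray(record.attention, dtype=float)
    g = np.asarray(record.grad_attention, dtype=float)
    if a.shape != g.shape:
        raise ValueError(f"attention {a.shape} and gradient {g.shape} shapes differ")
    rel = np.maximum(g * a, 0.0).mean(axis=0)
    return rel.max(axis=0)


def combine_importance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Element-wise maximum: the strongest attribution from either source."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"cannot combine scores of shapes {a.shape} and {b.shape}")
    return np.maximum(a, b)


def layer_token_importance(record: AttentionRecord) -> Tuple[np.ndarray, np.ndarray]:
    """S(Q;A) and S(K;A) for one cross-attention record."""
    imap = attention_importance_map(record)
    w_q = intrinsic_token_importance(record.query_act, record.grad_query)
    w_a = query_projection_importance(imap, record.key_act)
    w_k = intrinsic_token_importance(record.key_act, record.grad_key)
    w_a_prime = key_attention_importance(record)
    return combine_importance(w_a, w_q), combine_importance(w_a_prime, w_k)


def aggregate_layers(
    per_layer: Dict[int, Tuple[TokenImportance, TokenImportance]],
    topology: List[LayerTopology],
) -> Dict[str, TokenImportance]:
    """Aggregate per-layer scores into one vector per input sequence.

    Walking from the output backwards: along the decoder chain the query
    sequence accumulates by element-wise product (chain rule through
    stacked blocks); branches that converge on the same key sequence from
    different decoder blocks merge by element-wise maximum (the most
    influential attribution signal wins).
    """
    order = sorted(topology, key=lambda t: t.layer_id)  # output -> input
    query_running: Dict[str, np.ndarray] = {}
    key_running: Dict[str, np.ndarray] = {}
    for topo in order:
        if topo.kind != CROSS_ATTENTION:
            continue  # self-attention layers are handled by the encoder flag
        if topo.layer_id not in per_layer:
            raise ValueError(f"missing per-layer scores for layer {topo.layer_id}")
        q_imp, k_imp = per_layer[topo.layer_id]
        q_scores = np.asarray(q_imp.scores, dtype=float)
        k_scores = np.asarray(k_imp.scores, dtype=float)
        if topo.query_source in query_running:
            prev = query_running[topo.query_source]
            if prev.shape != q_scores.shape:
                raise ValueError(
                    f"query length mismatch on sequence {topo.query_source!r} "
                    f"at layer {topo.layer_id}: {prev.shape} vs {q_scores.shape}"
                )
            query_running[topo.query_source] = prev * q_scores
        else:
            query_running[topo.query_source] = q_scores.copy()
        if topo.key_source in key_running:
            prev = key_running[topo.key_source]
            if prev.shape != k_scores.shape:
                raise ValueError(
                    f"key length mismatch on sequence {topo.key_source!r} "
                    f"at layer {topo.layer_id}: {prev.shape} vs {k_scores.shape}"
                )
            key_running[topo.key_source] = np.maximum(prev, k_scores)
        else:
            key_running[topo.key_source] = k_scores.copy()
    out: Dict[str, TokenImportance] = {}
    for name, scores in key_running.items():
        if name in query_running:
            scores = np.maximum(scores, query_running[name])
        out[name] = TokenImportance(name, scores, provenance="aggregated")
    for name, scores in query_running.items():
        if name not in out:
            out[name] = TokenImportance(name, scores, provenance="aggregated")
    return out


def _encoder_rollout_vector(run: CaptureRun, seq_name: str) -> Optional[np.ndarray]:
    """Per-token relevance propagation through a sequence's encoder stack."""
    from .baselines import rollout  # local import to avoid a cycle

    recs = [
        r for r in run.self_attention_records()
        if r.topology.query_source == seq_name
    ]
    if not recs:
        return None
    # records are output->input; rollout wants input->output
    mat = rollout(list(reversed(recs)))
    return mat.sum(axis=0)


def explain(run: CaptureRun, chain_encoders: bool = False) -> Dict[str, TokenImportance]:
    """Token-level importance scores for every input sequence of a capture.

    Composes the per-layer query/key decompositions and the cross-layer
    aggregation, then strips special-token positions. With
    ``chain_encoders=True`` key-sequence scores are additionally modulated
    by a rollout pass through that sequence's encoder self-attention
    stack; by default aggregation stops at the encoder boundary.
    """
    cross = run.cross_attention_records()
    if not cross:
        raise ValueError(
            "capture contains no cross-attention layer; QCAI does not apply — "
            "use a self-attention baseline (raw attention, rollout, GradCAM) instead"
        )
    per_layer: Dict[int, Tuple[TokenImportance, TokenImportance]] = {}
    for rec in cross:
        q, k = layer_token_importance(rec)
        per_layer[rec.topology.layer_id] = (
            TokenImportance(rec.topology.query_source, q, provenance="combined"),
            TokenImportance(rec.topology.key_source, k, provenance="combined"),
        )
    aggregated = aggregate_layers(per_layer, [r.topology for r in cross])
    if chain_encoders:
        for name, imp in aggregated.items():
            vec = _encoder_rollout_vector(run, name)
            if vec is not None and vec.shape == imp.scores.shape:
                aggregated[name] = TokenImportance(
                    name, imp.scores * vec, provenance="aggregated"
                )
    out: Dict[str, TokenImportance] = {}
    for name, imp in aggregated.items():
        tmap = run.token_maps[name]
        keep = tmap.residue_positions
        out[name] = TokenImportance(
            name,
            imp.scores[keep],
            provenance="aggregated",
            residues=tmap.residues,
        )
    return out
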