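"""Reference attribution methods: raw attention, rollout, gradient-weighted attention.

These are the simple comparators the cross-attention method is measured
against. On encoder-decoder models they are conventionally applied to the
self-attention stacks only; :func:`gradcam_attention` accepts whatever
records it is given, so it can also score a single cross-attention layer.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .adapter import AttentionRecord
from .core import TokenImportance

__all__ = ["raw_attention", "rollout", "rollout_importance", "gradcam_attention"]

#: residual mixing weight in the rollout recursion, per the method's convention.
ROLLOUT_RESIDUAL = 0.5


def _last_record_per_sequence(records: List[AttentionRecord]) -> Dict[str, AttentionRecord]:
    """First record in output->input order, per key sequence."""
    out: Dict[str, AttentionRecord] = {}
    for rec in sorted(records, key=lambda r: r.topology.layer_id):
        name = rec.topology.key_source
        if name not in out:
            out[name] = rec
    return out


def raw_attention(records: List[AttentionRecord]) -> Dict[str, TokenImportance]:
    """Last layer's head-averaged attention, summed over queries per key token."""
    if not records:
        raise ValueError("raw_attention requires at least one record")
    out = {}
    for name, rec in _last_record_per_sequence(records).items():
        a = np.asarray(rec.attention, dtype=float).mean(axis=0)
        out[name] = TokenImportance(name, a.sum(axis=0), provenance="raw_attention")
    return out


def rollout(records: List[AttentionRecord]) -> np.ndarray:
    """Attention rollout over a self-attention stack, input -> output order.

    Each layer contributes the row-normalized mixture
    0.5 * (head-averaged A + I); the product over layers traces how each
    output token mixes input tokens. Rows of the result sum to 1.
    """
    if not records:
        raise ValueError("rollout requires at least one record")
    result = None
    for rec in records:
        a = np.asarray(rec.attention, dtype=float).mean(axis=0)
        n, m = a.shape
        if n != m:
            raise ValueError(
                f"rollout requires square self-attention maps; layer "
                f"{rec.topology.layer_id} is {n}x{m}"
            )
        mixed = ROLLOUT_RESIDUAL * (a + np.eye(n))
        mixed = mixed / mixed.sum(axis=1, keepdims=True)
        result = mixed if result is None else mixed @ result
    return result


def rollout_importance(records: List[AttentionRecord]) -> Dict[str, TokenImportance]:
    """Per-token rollout scores, one vector per self-attended sequence.

    The rollout matrix's columns are summed over output tokens, giving the
    total relevance each input token carries to the stack's output.
    """
    by_seq: Dict[str, List[AttentionRecord]] = {}
    for rec in records:
        by_seq.setdefault(rec.topology.query_source, []).append(rec)
    out = {}
    for name, recs in by_seq.items():
        ordered = sorted(recs, key=lambda r: -r.topology.layer_id)  # input -> output
        mat = rollout(ordered)
        out[name] = TokenImportance(name, mat.sum(axis=0), provenance="rollout")
    return out


def gradcam_attention(records: List[AttentionRecord]) -> Dict[str, TokenImportance]:
    """Gradient-weighted attention: last layer's E_H[ReLU(dL/dA * A)], column-max.

    Equivalent to the cross-attention method's key path applied to a
    single layer, with no query decomposition, no pseudoinverse and no
    cross-layer aggregation.
    """
    if not records:
        raise ValueError("gradcam_attention requires at least one record")
    out = {}
    for name, rec in _last_record_per_sequence(records).items():
        if rec.grad_attention is None:
            raise ValueError(
                f"layer {rec.topology.layer_id} carries no attention gradients"
            )
        rel = np.maximum(
            np.asarray(rec.grad_attention, dtype=float)
            * np.asarray(rec.attention, dtype=float),
            0.0,
        ).mean(axis=0)
        out[name] = TokenImportance(name, rel.max(axis=0), provenance="gradcam")
    return out
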