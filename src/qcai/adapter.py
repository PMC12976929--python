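"""Model-capture contract.

Any encoder-decoder attention model is exposed to the attribution code
through three plain containers: :class:`LayerTopology` (where a layer sits
and which sequences feed it), :class:`AttentionRecord` (one layer's
post-softmax attention, query/key activations, and the gradients of a
scalar target loss with respect to all three), and :class:`CaptureRun`
(all records for one forward/backward pass, ordered from the output layer
backwards).

The attribution math never touches model weights; everything it needs is
in these records, so the model itself is an opaque handle that merely has
to implement :class:`CaptureModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "SELF_ATTENTION",
    "CROSS_ATTENTION",
    "LayerTopology",
    "AttentionRecord",
    "TargetSpec",
    "TokenMap",
    "CaptureRun",
    "CaptureModel",
    "run_with_capture",
    "compute_target_loss",
    "ConfigurationError",
    "AdapterError",
]

SELF_ATTENTION = "self_attention"
CROSS_ATTENTION = "cross_attention"

ROW_SUM_TOL = 1e-5


class ConfigurationError(ValueError):
    """Bad wiring: unknown sequence names, invalid topology, bad targets."""


class AdapterError(RuntimeError):
    """The model could not produce a differentiable capture."""


@dataclass(frozen=True)
class LayerTopology:
    """Position of one attention layer in the capture graph.

    ``layer_id`` counts from the output backwards (0 = closest to the
    output), so the "first cross-attention layer seen walking back from
    the output" is simply the cross-attention record with the smallest
    ``layer_id``.
    """

    layer_id: int
    kind: str
    query_source: str
    key_source: str
    upstream_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in (SELF_ATTENTION, CROSS_ATTENTION):
            raise ConfigurationError(f"unknown layer kind {self.kind!r}")
        if self.kind == SELF_ATTENTION and self.query_source != self.key_source:
            raise ConfigurationError(
                "self-attention requires query_source == key_source, got "
                f"{self.query_source!r} vs {self.key_source!r}"
            )


@dataclass
class AttentionRecord:
    """One layer's captured tensors.

    attention      [H, N, N'] post-softmax, each (head, query) row sums to 1
    query_act      [N, d]   projected queries Q
    key_act        [N', d]  projected keys K
    grad_attention [H, N, N'] dL/dA (gradient w.r.t. post-softmax attention)
    grad_query     [N, d]   dL/dQ
    grad_key       [N', d]  dL/dK
    """

    topology: LayerTopology
    attention: np.ndarray
    query_act: np.ndarray
    key_act: np.ndarray
    grad_attention: np.ndarray
    grad_query: np.ndarray
    grad_key: np.ndarray

    @property
    def n_queries(self) -> int:
        return self.attention.shape[1]

    @property
    def n_keys(self) -> int:
        return self.attention.shape[2]

    def validate(self) -> None:
        a = np.asarray(self.attention)
        if a.ndim != 3:
            raise AdapterError(
                f"layer {self.topology.layer_id}: attention must be [H,N,N'], got shape {a.shape}"
            )
        if a.min() < -ROW_SUM_TOL or a.max() > 1.0 + ROW_SUM_TOL:
            raise AdapterError(
                f"layer {self.topology.layer_id}: attention entries outside [0,1]"
            )
        row_sums = a.sum(axis=-1)
        if not np.allclose(row_sums, 1.0, atol=ROW_SUM_TOL):
            worst = float(np.abs(row_sums - 1.0).max())
            raise AdapterError(
                f"layer {self.topology.layer_id}: attention rows must sum to 1 "
                f"(worst deviation {worst:.2e})"
            )
        if self.grad_attention.shape != a.shape:
            raise AdapterError(
                f"layer {self.topology.layer_id}: grad_attention shape "
                f"{self.grad_attention.shape} != attention shape {a.shape}"
            )
        for name, act, grad in (
            ("query", self.query_act, self.grad_query),
            ("key", self.key_act, self.grad_key),
        ):
            if act.shape != grad.shape:
                raise AdapterError(
                    f"layer {self.topology.layer_id}: grad_{name} shape "
                    f"{grad.shape} != activation shape {act.shape}"
                )
        n, np_ = a.shape[1], a.shape[2]
        if self.query_act.shape[0] != n or self.key_act.shape[0] != np_:
            raise AdapterError(
                f"layer {self.topology.layer_id}: activation token counts "
                "disagree with the attention matrix"
            )


@dataclass(frozen=True)
class TargetSpec:
    """Which scalar loss is differentiated.

    kind="class": loss is the negative log-probability of ``class_id``.
    kind="positions": summed negative log-probability of ``token_ids`` at
    ``positions`` of the generated sequence (the natural scalarization of
    an autoregressive binder model's conditional likelihood).
    """

    kind: str = "class"
    class_id: int = 0
    positions: Optional[tuple] = None
    token_ids: Optional[tuple] = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("class", "positions"):
            raise ConfigurationError(f"unknown target kind {self.kind!r}")
        if self.kind == "positions":
            if not self.positions:
                raise ConfigurationError("positions target requires a non-empty position set")
            if self.token_ids is not None and len(self.token_ids) != len(self.positions):
                raise ConfigurationError("token_ids must align with positions")


@dataclass
class TokenMap:
    """Tokens of one named input sequence, with special positions flagged."""

    tokens: List[str]
    special_mask: List[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.special_mask:
            self.special_mask = [False] * len(self.tokens)
        if len(self.special_mask) != len(self.tokens):
            raise ConfigurationError("special_mask length must match tokens")

    @property
    def residue_positions(self) -> List[int]:
        return [i for i, s in enumerate(self.special_mask) if not s]

    @property
    def residues(self) -> List[str]:
        return [t for t, s in zip(self.tokens, self.special_mask) if not s]


@dataclass
class CaptureRun:
    """All records for one forward/backward pass, output -> input order."""

    records: List[AttentionRecord]
    loss_value: float
    target_spec: TargetSpec
    token_maps: Dict[str, TokenMap]

    def validate(self) -> None:
        if not self.records:
            raise AdapterError("capture produced no attention records")
        for rec in self.records:
            rec.validate()
            for name in (rec.topology.query_source, rec.topology.key_source):
                if name not in self.token_maps:
                    raise ConfigurationError(
                        f"layer {rec.topology.layer_id} references sequence "
                        f"{name!r} absent from token_maps"
                    )

    def cross_attention_records(self) -> List[AttentionRecord]:
        return [r for r in self.records if r.topology.kind == CROSS_ATTENTION]

    def self_attention_records(self) -> List[AttentionRecord]:
        return [r for r in self.records if r.topology.kind == SELF_ATTENTION]


@runtime_checkable
class CaptureModel(Protocol):
    """The only thing a model must implement to be explainable here."""

    def sequence_names(self) -> Sequence[str]: ...

    def capture(self, inputs: Dict[str, List[str]], target: TargetSpec) -> CaptureRun: ...


def run_with_capture(
    model_handle: CaptureModel,
    inputs: Dict[str, List[str]],
    target_spec: TargetSpec,
) -> CaptureRun:
    """Run one forward/backward pass and return validated capture records.

    Deterministic by contract: two calls with identical inputs on the same
    (seeded) model yield bit-identical records.
    """
    known = set(model_handle.sequence_names())
    unknown = set(inputs) - known
    if unknown:
        raise ConfigurationError(
            f"unknown sequence name(s) {sorted(unknown)}; model expects {sorted(known)}"
        )
    missing = known - set(inputs)
    if missing:
        raise ConfigurationError(f"missing input sequence(s) {sorted(missing)}")
    run = model_handle.capture(inputs, target_spec)
    run.validate()
    return run


def _log_softmax(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    m = x.max(axis=-1, keepdims=True)
    z = x - m
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def compute_target_loss(model_outputs: np.ndarray, target_spec: TargetSpec) -> float:
    """Scalar loss for a target class or target token positions.

    ``model_outputs`` is either a vector of class logits (kind="class";
    a single logit is treated as a binary sigmoid unit) or a
    [positions x vocabulary] logit matrix (kind="positions", summed
    negative log-probability of the true tokens).
    """
    out = np.asarray(model_outputs, dtype=float)
    if target_spec.kind == "class":
        logits = out.ravel()
        if logits.size == 1:
            if target_spec.class_id not in (0,):
                raise ConfigurationError("single-logit output has only class 0")
            # negative log-probability of the positive class under a sigmoid
            return float(np.logaddexp(0.0, -logits[0]))
        if not 0 <= target_spec.class_id < logits.size:
            raise ConfigurationError(
                f"class_id {target_spec.class_id} out of range for {logits.size} classes"
            )
        return float(-_log_softmax(logits)[target_spec.class_id])
    # kind == "positions"
    if out.ndim != 2:
        raise ConfigurationError("positions target requires [positions x vocab] logits")
    positions = target_spec.positions or ()
    token_ids = target_spec.token_ids
    if token_ids is None:
        raise ConfigurationError("positions target requires token_ids")
    lp = _log_softmax(out)
    total = 0.0
    for pos, tok in zip(positions, token_ids):
        if not 0 <= pos < out.shape[0]:
            raise ConfigurationError(f"target position {pos} out of range")
        if not 0 <= tok < out.shape[1]:
            raise ConfigurationError(f"target token id {tok} out of range")
        total -= float(lp[pos, tok])
    return total
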