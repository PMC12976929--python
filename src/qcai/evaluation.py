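"""Scoring importance vectors against structural ground truth.

Three families of metrics:

* **ROC-AUC sweep** — binding-site labels from a distance threshold
  (3-6 Å), importance scores as the ranking variable, residues pooled
  across samples by default (per-sample mean available).
* **Binding Region Hit Rate (BRHR)** — for a fraction t, the proportion
  of the top-t highest-scoring residues whose interaction distance lies
  within the top-t *smallest* distances (smaller distance = stronger
  interaction), averaged over samples.
* **Perturbation metrics** — LOdds (change in target log-odds after
  padding the k highest-scoring tokens; more negative = better) and AOPC
  (mean drop in target probability over nested top-k perturbations,
  k = 1..K; higher = better), computed by re-running the model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from .adapter import TargetSpec

__all__ = [
    "EvalResult",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_KS",
    "roc_auc_sweep",
    "brhr",
    "brhr_benchmark",
    "perturb_topk",
    "lodds",
    "aopc",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(np.arange(3.0, 6.0 + 1e-9, 0.5))
#: padding counts matched to the average number of binding residues per chain
DEFAULT_KS = {"cdr3a": 4, "cdr3b": 4, "peptide": 7}
PROB_EPS = 1e-12


@dataclass
class EvalResult:
    method: str
    sequence_name: str
    metric: str       # auc | brhr | lodds | aopc
    setting: float    # Å threshold, fraction t, or k
    value: float
    n_samples: int


def _pool(scores: Sequence[np.ndarray], distances: Sequence[np.ndarray]):
    if len(scores) != len(distances):
        raise ValueError("scores and distances must align per sample")
    for s, d in zip(scores, distances):
        if len(s) != len(d):
            raise ValueError("score/distance length mismatch within a sample")
    return np.concatenate([np.asarray(s, float) for s in scores]), \
        np.concatenate([np.asarray(d, float) for d in distances])


def roc_auc_sweep(
    scores: Sequence[np.ndarray],
    distances: Sequence[np.ndarray],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    method: str = "",
    sequence_name: str = "",
    pooled: bool = True,
) -> List[EvalResult]:
    """AUC of score-ranked binding labels at each distance threshold.

    A threshold under which every pooled residue falls in one class has
    no defined AUC; it is reported as NaN with a warning.
    """
    flat_s, flat_d = _pool(scores, distances)
    out = []
    for thr in thresholds:
        if pooled:
            labels = flat_d <= thr
            if labels.all() or not labels.any():
                logger.warning("AUC undefined at %.1f Å: single class", thr)
                value = math.nan
            else:
                value = float(roc_auc_score(labels, flat_s))
        else:
            per_sample = []
            for s, d in zip(scores, distances):
                lab = np.asarray(d) <= thr
                if lab.all() or not lab.any():
                    continue
                per_sample.append(roc_auc_score(lab, s))
            if not per_sample:
                logger.warning("AUC undefined at %.1f Å: single class everywhere", thr)
                value = math.nan
            else:
                value = float(np.mean(per_sample))
        out.append(EvalResult(method, sequence_name, "auc", float(thr),
                              value, len(scores)))
    return out


def brhr(scores: np.ndarray, distances: np.ndarray, t: float) -> float:
    """Hit rate of the top-t scored residues against the top-t smallest distances.

    ``ceil(t*L)`` residues are selected by score (ties broken toward the
    lower position); a selection is a hit iff its distance is within the
    ``ceil(t*L)`` smallest distances, with distance ties at the cut all
    included. Depends on score ranks only.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError(f"t must be in (0, 1], got {t}")
    s = np.asarray(scores, dtype=float)
    d = np.asarray(distances, dtype=float)
    if s.shape != d.shape or s.ndim != 1 or s.size == 0:
        raise ValueError("scores and distances must be equal-length nonempty vectors")
    n_sel = math.ceil(t * s.size)
    selected = np.argsort(-s, kind="stable")[:n_sel]
    cut = np.sort(d)[n_sel - 1]
    hits = int((d[selected] <= cut).sum())
    return hits / n_sel


def brhr_benchmark(
    scores: Sequence[np.ndarray], distances: Sequence[np.ndarray], t: float
) -> float:
    """Mean per-sample hit rate across the benchmark."""
    if not len(scores):
        raise ValueError("no samples")
    return float(np.mean([brhr(s, d, t) for s, d in zip(scores, distances)]))


def perturb_topk(
    tokens: Sequence[str], scores: np.ndarray, k: int, pad_symbol: str = "<PAD>"
) -> List[str]:
    """Replace the k highest-scoring tokens with the padding symbol.

    Ties break toward the lower position index; the input list is not
    modified; exactly min(k, len) positions are replaced.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    s = np.asarray(scores, dtype=float)
    if len(tokens) != s.size:
        raise ValueError("scores must align with tokens")
    out = list(tokens)
    for idx in np.argsort(-s, kind="stable")[: min(k, len(out))]:
        out[idx] = pad_symbol
    return out


def _clipped_proba(model_handle, inputs: Dict[str, Sequence[str]],
                   target_spec: TargetSpec) -> float:
    p = float(model_handle.predict_proba(inputs, target_spec))
    if not PROB_EPS <= p <= 1.0 - PROB_EPS:
        logger.warning("model probability %.3e clipped to (0,1)", p)
        p = min(max(p, PROB_EPS), 1.0 - PROB_EPS)
    return p


def _perturbed_inputs(inputs, sequence_name, scores, k, pad_symbol):
    new = {name: list(toks) for name, toks in inputs.items()}
    new[sequence_name] = perturb_topk(new[sequence_name], scores, k, pad_symbol)
    return new


def lodds(
    model_handle,
    inputs: Dict[str, Sequence[str]],
    sequence_name: str,
    scores: np.ndarray,
    k: int,
    target_spec: TargetSpec,
    pad_symbol: str = "<PAD>",
) -> float:
    """Change in target log-odds after padding the top-k tokens of one chain.

    log(p'/(1-p')) - log(p/(1-p)); more negative means the explanation
    found tokens the model actually relies on.
    """
    p0 = _clipped_proba(model_handle, inputs, target_spec)
    p1 = _clipped_proba(
        model_handle,
        _perturbed_inputs(inputs, sequence_name, scores, k, pad_symbol),
        target_spec,
    )
    return math.log(p1 / (1 - p1)) - math.log(p0 / (1 - p0))


def aopc(
    model_handle,
    inputs: Dict[str, Sequence[str]],
    sequence_name: str,
    scores: np.ndarray,
    k_max: int,
    target_spec: TargetSpec,
    pad_symbol: str = "<PAD>",
) -> float:
    """Average drop in target probability over nested top-k perturbations.

    (1/K) * sum_{k=1..K} (p_original - p_perturbed(k)); higher is better.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    p0 = _clipped_proba(model_handle, inputs, target_spec)
    drops = []
    for k in range(1, k_max + 1):
        pk = _clipped_proba(
            model_handle,
            _perturbed_inputs(inputs, sequence_name, scores, k, pad_symbol),
            target_spec,
        )
        drops.append(p0 - pk)
    return float(np.mean(drops))
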