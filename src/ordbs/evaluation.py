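"""Quality metrics: bad-edge fraction, ROC/AUROC over edge detection, Kendall tau.

``bad_edge_fraction`` scores an estimated weight matrix against the
generating one over all ordered off-diagonal pairs: a truly-zero edge is bad
when the estimate's magnitude exceeds an absolute threshold w0; a truly
nonzero edge is bad when the absolute relative deviation exceeds w1. The ROC
analysis removes the thresholds by sweeping a detection cutoff w2 over the
estimated magnitudes. Kendall's tau distance counts node pairs ordered
oppositely in two orderings (the bubble-sort distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

from .exceptions import MetricUndefinedError, ParameterError

__all__ = [
    "EvalThresholds",
    "EdgeEvalResult",
    "RocResult",
    "bad_edge_fraction",
    "roc_curve",
    "kendall_tau",
]


@dataclass(frozen=True)
class EvalThresholds:
    """Thresholds for edge scoring: absolute (w0), relative (w1), detection (w2 sweep)."""

    w0: float = 0.1
    w1: float = 0.5
    relative_to: str = "estimate"  # denominator of the relative deviation

    def __post_init__(self) -> None:
        if self.w0 < 0 or self.w1 < 0:
            raise ParameterError("thresholds must be non-negative")
        if self.relative_to not in ("estimate", "truth"):
            raise ParameterError("relative_to must be 'estimate' or 'truth'")


@dataclass(frozen=True)
class EdgeEvalResult:
    n_bad: float
    bad: np.ndarray  # boolean p x p indicator, diagonal always False


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


def bad_edge_fraction(
    W_true: np.ndarray, W_hat: np.ndarray, thresholds: EvalThresholds = EvalThresholds()
) -> EdgeEvalResult:
    """Fraction of badly estimated ordered edge weights.

    A pair with true weight zero is bad iff |w_hat| > w0; a pair with nonzero
    true weight is bad iff |(w - w_hat) / denom| > w1, where the denominator
    is the estimate (default) or the truth; a zero denominator with nonzero
    truth counts as bad (the limit of the ratio).
    """
    W_true = np.asarray(W_true, dtype=float)
    W_hat = np.asarray(W_hat, dtype=float)
    if W_true.shape != W_hat.shape or W_true.ndim != 2:
        raise ParameterError("weight matrices must share a square shape")
    p = W_true.shape[0]
    off = ~np.eye(p, dtype=bool)
    zero = (W_true == 0.0) & off
    nonzero = (W_true != 0.0) & off
    bad = np.zeros((p, p), dtype=bool)
    bad[zero] = np.abs(W_hat[zero]) > thresholds.w0
    denom = W_hat if thresholds.relative_to == "estimate" else W_true
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        rel = np.abs((W_true - W_hat) / denom)
    bad[nonzero] = np.where(
        denom[nonzero] == 0.0, True, rel[nonzero] > thresholds.w1
    )
    return EdgeEvalResult(n_bad=float(bad.sum() / (p * (p - 1))), bad=bad)


def roc_curve(W_true: np.ndarray, W_hat: np.ndarray, *, normalize: str = "rates") -> RocResult:
    """ROC for calling ordered pairs nonzero by thresholded estimated magnitude.

    ``normalize="rates"`` reports standard TPR/FPR (area bounded by one);
    ``normalize="p2"`` divides both counts by p^2 instead, for strict
    replication of that convention.
    """
    W_true = np.asarray(W_true, dtype=float)
    W_hat = np.asarray(W_hat, dtype=float)
    if W_true.shape != W_hat.shape or W_true.ndim != 2:
        raise ParameterError("weight matrices must share a square shape")
    p = W_true.shape[0]
    off = ~np.eye(p, dtype=bool)
    labels = (W_true[off] != 0.0).astype(int)
    scores = np.abs(W_hat[off])
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MetricUndefinedError("ROC needs at least one true nonzero and one true zero pair")
    if normalize == "rates":
        fpr, tpr, _ = _skm.roc_curve(labels, scores)
        return RocResult(fpr=fpr, tpr=tpr, auroc=float(_skm.auc(fpr, tpr)))
    if normalize == "p2":
        cuts = np.concatenate([[np.inf], np.unique(scores)[::-1], [-np.inf]])
        called = scores[None, :] >= cuts[:, None]
        npos = (called & (labels == 1)).sum(axis=1) / p**2
        nfalse = (called & (labels == 0)).sum(axis=1) / p**2
        return RocResult(fpr=nfalse, tpr=npos, auroc=float(np.trapezoid(npos, nfalse)))
    raise ParameterError("normalize must be 'rates' or 'p2'")


def kendall_tau(o: np.ndarray, o2: np.ndarray) -> int:
    """Kendall tau distance: node pairs appearing in opposite relative order.

    Symmetric; zero for identical orderings, p(p-1)/2 for a reversal.
    """
    o = np.asarray(o)
    o2 = np.asarray(o2)
    if o.shape != o2.shape or o.ndim != 1:
        raise ParameterError("orderings must be one-dimensional and of equal length")
    if not np.array_equal(np.sort(o), np.sort(o2)):
        raise ParameterError("orderings must be over the same label set")
    pos2 = {int(v): a for a, v in enumerate(o2)}
    seq = np.array([pos2[int(v)] for v in o])
    # discordant pairs: earlier in o (a < b) but later in o2 (seq[a] > seq[b])
    disc = np.triu(seq[:, None] > seq[None, :], 1)
    return int(disc.sum())
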