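"""Binary-classification metrics for per-condition ECG classifiers.

Confusion counts are the primary representation; the fractional rates
(sensitivity, specificity, ...) are derived views. ROC-AUC is computed as the
Mann-Whitney U statistic (probability that a random positive outscores a
random negative, ties counting one half), and the operating threshold is
chosen by maximizing Youden's J = TPR - FPR on the ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_auc",
    "select_threshold",
]


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


@dataclass(frozen=True)
class ConfusionCounts:
    """Integer confusion counts for one binary task.

    The per-class rates (``tp_rate`` = tp / positives etc.) are fractions of
    the relevant class and are NaN when that class is empty.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    # fractional views: each count normalized by the size of its true class
    @property
    def tp_rate(self) -> float:
        return _safe_div(self.tp, self.n_pos)

    @property
    def tn_rate(self) -> float:
        return _safe_div(self.tn, self.n_neg)

    @property
    def fn_rate(self) -> float:
        return _safe_div(self.fn, self.n_pos)

    @property
    def fp_rate(self) -> float:
        return _safe_div(self.fp, self.n_neg)


@dataclass
class MetricsReport:
    """Derived binary metrics; undefined ratios are NaN, never silently 0."""

    tpr: float
    tnr: float
    ppv: float
    npv: float
    acc: float
    f1: float
    roc_auc: float = math.nan
    threshold: float = math.nan


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Exact confusion counts from boolean truth/prediction vectors."""
    t = np.asarray(y_true, dtype=bool)
    p = np.asarray(y_pred, dtype=bool)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size < 1:
        raise ValueError("need at least one sample")
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, predictive values, accuracy and F1.

    F1 = 2*tp / (2*tp + fp + fn); when tp = 0 with errors present it is 0,
    and NaN only in the degenerate all-correct-negative case (no positives,
    no predicted positives).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    return MetricsReport(
        tpr=_safe_div(tp, tp + fn),
        tnr=_safe_div(tn, tn + fp),
        ppv=_safe_div(tp, tp + fp),
        npv=_safe_div(tn, tn + fn),
        acc=_safe_div(tp + tn, counts.n),
        f1=_safe_div(2 * tp, 2 * tp + fp + fn),
    )


def _check_two_classes(y: np.ndarray) -> None:
    if y.all() or not y.any():
        raise ValueError("both classes must be present")


def roc_auc(scores, y_true) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals (wins + 0.5*ties) / (n_pos * n_neg) over all positive/negative
    score pairs; invariant under strictly monotone transforms of the scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(y_true, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    _check_two_classes(y)
    ranks = rankdata(s)  # average ranks handle ties as half-wins
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def select_threshold(scores, y_true) -> float:
    """Operating threshold maximizing Youden's J = TPR - FPR.

    Candidate thresholds are the observed scores (prediction rule is
    ``score >= threshold``); ties in J are broken toward the lower threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(y_true, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    _check_two_classes(y)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    best_thr = math.inf
    best_j = -math.inf
    for thr in np.unique(s):  # ascending, so later candidates must beat strictly
        pred = s >= thr
        tpr = np.sum(pred & y) / n_pos
        fpr = np.sum(pred & ~y) / n_neg
        j = tpr - fpr
        if j > best_j or (j == best_j and thr < best_thr):
            best_j, best_thr = j, float(thr)
    return best_thr
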