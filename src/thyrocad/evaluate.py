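"""Confusion-matrix metrics, ROC analysis and operating-point selection.

All rates follow the standard definitions with malignant as the positive
class: accuracy (TP+TN)/M, sensitivity TP/P, specificity TN/N, precision
TP/(TP+FP), FNR = 1 - sensitivity, FPR = 1 - specificity, F1 the harmonic
mean of precision and sensitivity.  Metrics whose denominator is zero are
reported as NaN with an explicit reason rather than silently imputed.

The ROC curve sweeps the decision threshold over the unique scores in
descending order (predict positive iff score >= threshold); it starts at
(FPR, TPR) = (0, 0) and ends at (1, 1), with tied scores sharing one curve
point.  AUROC is the trapezoidal area.  The operating point minimizes the
Euclidean distance  sqrt(FPR^2 + (1 - TPR)^2)  to the ideal corner (0, 1);
ties break toward the higher TPR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_io import MALIGNANT

__all__ = [
    "ConfusionMatrix",
    "PerformanceReport",
    "ROCCurve",
    "confusion",
    "metrics",
    "roc",
    "operating_point",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts with the derived marginals."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def p(self) -> int:
        """Actual positives TP + FN."""
        return self.tp + self.fn

    @property
    def n(self) -> int:
        """Actual negatives FP + TN."""
        return self.fp + self.tn

    @property
    def m(self) -> int:
        """Total sample count."""
        return self.p + self.n


@dataclass
class PerformanceReport:
    """Every scalar metric derived from one confusion matrix.

    Undefined entries (zero denominators) are NaN, with the reason recorded
    in ``undefined``.  ``roc_distance``/``threshold``/``auroc`` are filled
    only when continuous scores are available.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    fnr: float
    fpr: float
    f1: float
    roc_distance: Optional[float] = None
    threshold: Optional[float] = None
    auroc: Optional[float] = None
    undefined: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "fnr": self.fnr,
            "fpr": self.fpr,
            "f1": self.f1,
        }
        for key in ("roc_distance", "threshold", "auroc"):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        if self.undefined:
            out["undefined"] = dict(self.undefined)
        return out


@dataclass(frozen=True)
class ROCCurve:
    """Threshold sweep: parallel arrays of (threshold, FPR, TPR)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


def confusion(predictions: Sequence, truth: Sequence, positive_class: str = MALIGNANT) -> ConfusionMatrix:
    """Count TP/FP/TN/FN for predicted vs true labels."""
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} predictions vs {true.shape} truths")
    pp = pred == positive_class
    tp = true == positive_class
    return ConfusionMatrix(
        tp=int((pp & tp).sum()),
        fp=int((pp & ~tp).sum()),
        tn=int((~pp & ~tp).sum()),
        fn=int((~pp & tp).sum()),
    )


def metrics(cm: ConfusionMatrix) -> PerformanceReport:
    """All scalar metrics from a confusion matrix; see module docstring."""
    if cm.m == 0:
        raise ValueError("empty confusion matrix")
    undefined: dict[str, str] = {}

    def ratio(num: int, den: int, name: str, reason: str) -> float:
        if den == 0:
            undefined[name] = reason
            return math.nan
        return num / den

    accuracy = (cm.tp + cm.tn) / cm.m
    sensitivity = ratio(cm.tp, cm.p, "sensitivity", "no actual positives (P = 0)")
    specificity = ratio(cm.tn, cm.n, "specificity", "no actual negatives (N = 0)")
    ppv = ratio(cm.tp, cm.tp + cm.fp, "ppv", "no positive predictions (TP + FP = 0)")
    fnr = 1.0 - sensitivity if not math.isnan(sensitivity) else math.nan
    fpr = 1.0 - specificity if not math.isnan(specificity) else math.nan
    if math.isnan(fnr):
        undefined["fnr"] = undefined["sensitivity"]
    if math.isnan(fpr):
        undefined["fpr"] = undefined["specificity"]

    if math.isnan(ppv) or math.isnan(sensitivity):
        undefined["f1"] = "precision or recall undefined"
        f1 = math.nan
    elif ppv + sensitivity == 0:
        undefined["f1"] = "precision + recall = 0"
        f1 = math.nan
    else:
        f1 = 2.0 * ppv * sensitivity / (ppv + sensitivity)

    return PerformanceReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=ppv,
        fnr=fnr,
        fpr=fpr,
        f1=f1,
        undefined=undefined,
    )


def roc(scores: Sequence[float], truth: Sequence, positive_class: str = MALIGNANT) -> ROCCurve:
    """ROC curve and trapezoidal AUROC from continuous scores."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(truth) == positive_class
    if s.shape != y.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # collapse tied scores onto a single curve point
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]

    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auroc=auroc)


def operating_point(curve: ROCCurve) -> tuple[float, float]:
    """Pick the threshold closest (Euclidean) to the ideal corner (0, 1).

    Returns (threshold, distance); ties break toward higher TPR.
    """
    if curve.thresholds.size == 0:
        raise ValueError("empty ROC curve")
    dist = np.sqrt(curve.fpr ** 2 + (1.0 - curve.tpr) ** 2)
    best = np.flatnonzero(dist == dist.min())
    pick = best[np.argmax(curve.tpr[best])]
    return float(curve.thresholds[pick]), float(dist[pick])
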