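"""Threshold-independent binary-classifier evaluation.

Four confusion-matrix statistics — sensitivity TP/(TP+FN), specificity
TN/(TN+FP), accuracy (TP+TN)/total and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

— plus ROC curves built by a threshold sweep over decision scores.  Metrics
are returned as fractions (sensitivity/specificity/accuracy in [0, 1], MCC in
[-1, 1]); use :func:`as_percent` when percentages are wanted.  MCC is defined
as 0 whenever a denominator factor vanishes; an empty positive or negative
class makes sensitivity resp. specificity NaN with a warning rather than a
silent zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    pred_labels: Sequence[int], true_labels: Sequence[int]
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN; the positive class is +1, anything else negative."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("prediction and truth must be equal-length, non-empty")
    pos_pred = pred == 1
    pos_true = true == 1
    return ConfusionCounts(
        tp=int(np.sum(pos_pred & pos_true)),
        fp=int(np.sum(pos_pred & ~pos_true)),
        tn=int(np.sum(~pos_pred & ~pos_true)),
        fn=int(np.sum(~pos_pred & pos_true)),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and MCC as fractions."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    if c.tp + c.fn > 0:
        sensitivity = c.tp / (c.tp + c.fn)
    else:
        warnings.warn("no positive examples: sensitivity undefined", stacklevel=2)
        sensitivity = math.nan
    if c.tn + c.fp > 0:
        specificity = c.tn / (c.tn + c.fp)
    else:
        warnings.warn("no negative examples: specificity undefined", stacklevel=2)
        specificity = math.nan
    accuracy = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "accuracy": accuracy,
        "mcc": mcc,
    }


def as_percent(values: dict[str, float]) -> dict[str, float]:
    """Scale the [0, 1] metrics to percentages; MCC is left on its own scale."""
    return {
        k: (v if k == "mcc" else v * 100.0) for k, v in values.items()
    }


@dataclass
class RocCurve:
    """ROC points from (0,0) to (1,1) plus trapezoidal area under the curve."""

    points: np.ndarray  # (m, 2) columns: false-positive rate, true-positive rate
    auc: float

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValueError("points must be (m, 2)")
        if np.any(np.diff(p, axis=0) < -1e-12):
            raise ValueError("ROC points must be monotone non-decreasing")
        self.points = p

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]


def roc(scores: Sequence[float], true_labels: Sequence[int]) -> RocCurve:
    """ROC curve by descending threshold sweep over distinct score values.

    Tied scores are grouped into a single point, so a constant score yields
    one segment from (0,0) to (1,1) and AUC 0.5.  AUC is the trapezoidal
    area, which equals the Mann-Whitney pair statistic with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    true = np.asarray(true_labels)
    if scores.shape != true.shape:
        raise ValueError("scores and labels must be equal length")
    n_pos = int(np.sum(true == 1))
    n_neg = int(true.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one example of each class")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    is_pos = (true[order] == 1).astype(float)
    tp_cum = np.cumsum(is_pos)
    fp_cum = np.cumsum(1.0 - is_pos)
    # keep only the last index of each tied-score run
    last_of_run = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp_cum[last_of_run] / n_pos]
    fpr = np.r_[0.0, fp_cum[last_of_run] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=np.column_stack([fpr, tpr]), auc=auc)


def plot_roc(curve: RocCurve, ax=None, label: str | None = None):
    """Plot a ROC curve (matplotlib imported lazily)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.fpr, curve.tpr, label=label or f"AUC = {curve.auc:.3f}")
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.legend(loc="lower right")
    return ax
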