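"""Classification metrics: precision/recall/F1 (as percentages) and ROC/AUC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PrecisionRecallF1", "precision_recall_f1", "roc_curve_points", "roc_auc"]


@dataclass(frozen=True)
class PrecisionRecallF1:
    """Percentages on [0, 100]; NaN marks an undefined metric.

    ``degenerate`` flags the TP == 0 boundary case where precision and
    recall are 0 and F1 is reported as 0 by convention rather than as a
    true harmonic mean.
    """

    precision: float
    recall: float
    f1: float
    degenerate: bool = False


def precision_recall_f1(tp: int, fp: int, fn: int) -> PrecisionRecallF1:
    """Precision, recall (sensitivity) and F1 from confusion counts.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = their harmonic
    mean, all scaled to percent.  An empty denominator yields NaN (an
    explicit undefined marker, never a silent zero); TP == 0 with both
    denominators positive yields (0, 0, 0) with ``degenerate=True``.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    precision = np.nan if tp + fp == 0 else 100.0 * tp / (tp + fp)
    recall = np.nan if tp + fn == 0 else 100.0 * tp / (tp + fn)
    if np.isnan(precision) or np.isnan(recall):
        return PrecisionRecallF1(precision, recall, np.nan, degenerate=True)
    if tp == 0:
        return PrecisionRecallF1(0.0, 0.0, 0.0, degenerate=True)
    f1 = 2.0 * precision * recall / (precision + recall)
    return PrecisionRecallF1(precision, recall, f1, degenerate=False)


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve by sweeping thresholds over the distinct scores.

    Returns (fpr, tpr) arrays from (0, 0) to (1, 1).  Tied scores are
    collapsed into single curve vertices, so the trapezoidal area counts
    ties as half-concordant, matching the Mann-Whitney statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    P = int(labels.sum())
    N = int((~labels).sum())
    if P == 0 or N == 0:
        raise ValueError("ROC requires at least one sample of each class")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # keep only the last index of each tied-score block
    last = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tpr = np.r_[0.0, tps[last] / P]
    fpr = np.r_[0.0, fps[last] / N]
    return fpr, tpr


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and trapezoidal AUC.

    Returns ``(fpr, tpr, auc)``.  The trapezoidal area over the swept
    curve equals the probability that a random positive outscores a
    random negative (ties counted one half).
    """
    fpr, tpr = roc_curve_points(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc
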