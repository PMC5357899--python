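"""Regression and classification metrics for efficacy predictors.

Regression quality is the Pearson correlation (PCC) between predicted and
observed efficacies. Classification mode binarizes observed efficacy at the
70% knockdown threshold and sweeps a decision threshold over the predicted
scores, yielding sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), the ROC
curve and its area (ties get half-concordance credit, i.e. the Mann-Whitney
convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve


@dataclass(frozen=True)
class EvaluationReport:
    pcc: float
    roc_points: tuple[tuple[float, float], ...]
    auc: float
    operating_points: tuple[tuple[float, float, float], ...]

    def to_dict(self) -> dict:
        return {
            "pcc": self.pcc,
            "auc": self.auc,
            "roc_points": [list(p) for p in self.roc_points],
            "operating_points": [
                {"specificity": s, "sensitivity": t, "threshold": th}
                for s, t, th in self.operating_points
            ],
        }


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; errors (not NaN) on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and the same length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[bool], threshold: float
) -> tuple[tuple[int, int, int, int], tuple[float, float]]:
    """(TP, FP, TN, FN) and (sensitivity, specificity), predicting active at
    score >= threshold. A rate whose class is absent is NaN, never 0."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pred = s >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    sens = tp / (tp + fn) if (tp + fn) else math.nan
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    return (tp, fp, tn, fn), (sens, spec)


def roc_and_auc(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[tuple[tuple[float, float], ...], float]:
    """ROC points (fpr, tpr) over the unique-score threshold sweep, and the
    trapezoidal AUC. Requires both classes present."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    area = float(np.trapezoid(tpr, fpr))
    return tuple(zip(fpr.tolist(), tpr.tolist())), area


def sensitivity_at_specificity(
    scores: Sequence[float],
    labels: Sequence[bool],
    spec_targets: Sequence[float],
) -> list[tuple[float, float, float]]:
    """For each specificity target, the (specificity, sensitivity, threshold)
    at the threshold whose specificity is the smallest one >= target.

    When even the strictest threshold cannot reach the target, the maximum
    achievable operating point is reported instead (flagged by its
    specificity falling short of the target).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    thresholds = np.unique(s)
    # candidate thresholds: each unique score, plus one above the maximum
    candidates = np.concatenate([thresholds, [thresholds[-1] + 1.0]])
    points = []
    for th in candidates:
        _, (sens, spec) = confusion_at_threshold(s, y, th)
        points.append((spec, sens, float(th)))
    out = []
    for target in spec_targets:
        reachable = [p for p in points if not math.isnan(p[0]) and p[0] >= target]
        if reachable:
            chosen = min(reachable, key=lambda p: (p[0], -p[1]))
        else:
            chosen = max(
                (p for p in points if not math.isnan(p[0])), key=lambda p: p[0]
            )
        out.append(chosen)
    return out


def evaluate_predictions(
    predicted: Sequence[float],
    observed: Sequence[float],
    spec_targets: Sequence[float] = (0.907, 0.969, 0.99),
    activity_threshold: float = 70.0,
) -> EvaluationReport:
    """Full report: PCC plus classification metrics at the activity threshold."""
    from .feature_selection import binarize_labels

    pcc = pearson(predicted, observed)
    labels = np.asarray(observed, dtype=float) >= activity_threshold
    roc_points, area = roc_and_auc(predicted, labels)
    ops = sensitivity_at_specificity(predicted, labels, spec_targets)
    return EvaluationReport(
        pcc=pcc,
        roc_points=roc_points,
        auc=area,
        operating_points=tuple(ops),
    )
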