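"""Classifier performance surfaces: confusion counts, threshold metrics,
ROC/PR areas, calibration, decision-curve net benefit, threshold sweeps.

Conventions: a sample is predicted positive when its score is >= the
threshold; ROC handles tied scores by grouping them into single threshold
steps, so the trapezoidal area equals the Mann-Whitney U statistic divided
by n1*n0; metrics with a zero denominator (e.g. precision with no predicted
positives) are reported as NaN rather than coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_auc_score

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_at",
    "metrics_from",
    "roc_auc",
    "pr_auc",
    "calibration_curve",
    "decision_curve",
    "threshold_sweep",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float = 0.5

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check(probabilities, labels):
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} scores vs {y.shape} labels")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return p, y


def confusion_at(probabilities, labels, threshold: float = 0.5) -> ConfusionMatrix:
    """Tally the confusion matrix with positives called at score >= threshold."""
    p, y = _check(probabilities, labels)
    pred = p >= threshold
    pos = y == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        threshold=float(threshold),
    )


def roc_auc(probabilities, labels) -> float:
    """Trapezoidal ROC area over unique-score thresholds (ties grouped).

    Numerically identical to the Mann-Whitney U statistic scaled by the
    product of class sizes.
    """
    p, y = _check(probabilities, labels)
    return float(roc_auc_score(y, p))


def pr_auc(probabilities, labels) -> float:
    """Trapezoidal area under the precision-recall curve."""
    p, y = _check(probabilities, labels)
    precision, recall, _ = precision_recall_curve(y, p)
    # precision_recall_curve returns points with decreasing recall
    return float(-np.trapezoid(precision, recall))


@dataclass(frozen=True)
class MetricsReport:
    """Point metrics at one threshold plus threshold-free areas.

    Undefined ratios are NaN: precision with no predicted positives, recall
    with no true positives in the sample, etc.
    """

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    roc_auc: float
    pr_auc: float
    threshold: float

    def as_dict(self) -> dict:
        return asdict(self)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from(cm: ConfusionMatrix, probabilities=None, labels=None) -> MetricsReport:
    """Closed-form metrics from a confusion matrix; AUCs from the scores.

    ``probabilities``/``labels`` may be omitted when only the threshold
    metrics are wanted (the areas are then NaN).
    """
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    accuracy = _ratio(cm.tp + cm.tn, cm.n)
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    if probabilities is not None and labels is not None:
        auc = roc_auc(probabilities, labels)
        prauc = pr_auc(probabilities, labels)
    else:
        auc = prauc = float("nan")
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        roc_auc=auc,
        pr_auc=prauc,
        threshold=cm.threshold,
    )


def calibration_curve(probabilities, labels, n_bins: int = 10) -> pd.DataFrame:
    """Reliability points: mean predicted vs observed fraction per bin.

    Equal-width bins on [0, 1]; empty bins are omitted. Scores equal to a
    bin's right edge fall in that bin only at 1.0 (right-closed last bin).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    p, y = _check(probabilities, labels)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin": b,
                "bin_left": edges[b],
                "bin_right": edges[b + 1],
                "mean_predicted": float(p[mask].mean()),
                "observed_fraction": float(np.mean(y[mask] == 1)),
                "count": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def decision_curve(probabilities, labels, thresholds) -> pd.DataFrame:
    """Net benefit across threshold probabilities, with reference strategies.

    At threshold probability p_t the model's net benefit is
    TP/n - (FP/n) * p_t / (1 - p_t) with positives called at score >= p_t.
    ``treat_all`` calls everyone positive; ``treat_none`` is identically 0.
    """
    p, y = _check(probabilities, labels)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prevalence = float(np.mean(y == 1))
    rows = []
    for pt in thresholds:
        cm = confusion_at(p, y, pt)
        odds = pt / (1.0 - pt)
        rows.append(
            {
                "threshold": float(pt),
                "net_benefit": cm.tp / n - (cm.fp / n) * odds,
                "treat_all": prevalence - (1.0 - prevalence) * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


def threshold_sweep(probabilities, labels, grid) -> pd.DataFrame:
    """Point metrics at every threshold on the grid (one row per threshold)."""
    p, y = _check(probabilities, labels)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("grid thresholds must lie in [0, 1]")
    rows = []
    for th in grid:
        report = metrics_from(confusion_at(p, y, th), p, y)
        rows.append(report.as_dict())
    return pd.DataFrame(rows)
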