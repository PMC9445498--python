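"""Classification metrics: confusion counts, the five closed-form indices, ROC.

A pair is called positive when its predicted probability reaches the
threshold (prob >= t).  The five indices are

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)          (recall)
    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

A metric whose denominator is zero is reported as NaN ("NA"), never as 0.
AUROC is the rank-based area under the ROC curve (equivalently the
normalised Mann-Whitney U statistic, ties counted half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .constants import DEFAULT_THRESHOLD
from .errors import NoDataError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five indices (NaN where undefined) plus optional AUROC."""

    accuracy: float
    sensitivity: float
    precision: float
    specificity: float
    f1: float
    auroc: float = math.nan

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "precision": self.precision, "specificity": self.specificity,
            "f1": self.f1, "auroc": self.auroc,
        }


def _labels_probs(pairs) -> tuple[np.ndarray, np.ndarray]:
    labels, probs = [], []
    for p in pairs:
        if isinstance(p, tuple):
            label, prob = p
        else:
            label, prob = p.label, p.prob
        if label is None or prob is None:
            raise NoDataError("every pair needs a true label and a probability")
        labels.append(int(label))
        probs.append(float(prob))
    if not labels:
        raise NoDataError("no pairs to evaluate")
    return np.array(labels), np.array(probs)


def confusion(pairs, threshold: float = DEFAULT_THRESHOLD) -> ConfusionCounts:
    """Tally TP/TN/FP/FN at a probability threshold (predicted positive: prob >= t).

    ``pairs`` is an iterable of (label, prob) tuples or objects with ``label``
    and ``prob`` attributes.
    """
    labels, probs = _labels_probs(pairs)
    predicted = probs >= threshold
    tp = int(np.sum(predicted & (labels == 1)))
    tn = int(np.sum(~predicted & (labels == 0)))
    fp = int(np.sum(predicted & (labels == 0)))
    fn = int(np.sum(~predicted & (labels == 1)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def compute_metrics(c: ConfusionCounts, auroc: float = math.nan) -> MetricsReport:
    """Evaluate the five closed forms from confusion counts."""
    if c.total == 0:
        raise NoDataError("all confusion counts are zero")
    sens = _ratio(c.tp, c.tp + c.fn)
    prec = _ratio(c.tp, c.tp + c.fp)
    if math.isnan(sens) or math.isnan(prec) or (prec + sens) == 0:
        f1 = math.nan
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=sens,
        precision=prec,
        specificity=_ratio(c.tn, c.tn + c.fp),
        f1=f1,
        auroc=auroc,
    )


def roc_auc(pairs) -> tuple[float, np.ndarray]:
    """AUROC plus the ROC points as an array of (fpr, tpr) rows.

    Requires both classes to be present.
    """
    labels, probs = _labels_probs(pairs)
    if len(set(labels)) < 2:
        raise NoDataError("ROC needs both positive and negative pairs")
    auroc = float(roc_auc_score(labels, probs))
    fpr, tpr, _ = roc_curve(labels, probs)
    return auroc, np.column_stack([fpr, tpr])


def evaluate(pairs, threshold: float = DEFAULT_THRESHOLD) -> MetricsReport:
    """Confusion + metrics + AUROC in one call (AUROC NaN if single-class)."""
    c = confusion(pairs, threshold)
    try:
        auroc, _ = roc_auc(pairs)
    except NoDataError:
        auroc = math.nan
    return compute_metrics(c, auroc=auroc)


def threshold_sweep(pairs, grid=(0.5, 0.6, 0.7, 0.8, 0.9, 1.0)) -> dict[float, MetricsReport]:
    """Metrics at each threshold of the grid, as {threshold: MetricsReport}."""
    pairs = list(pairs)
    return {t: evaluate(pairs, threshold=t) for t in grid}
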