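"""Multiclass classification metrics: confusion matrix, precision/recall,
F1, and one-vs-rest ROC/AUC.

Conventions
-----------
* Confusion-matrix rows are the true class, columns the predicted class.
* Per-class precision/recall/F1 come from the one-vs-rest reduction:
  precision = TP/(TP+FP), recall (sensitivity) = TP/(TP+FN),
  F1 = 2PR/(P+R), the harmonic mean.  A zero denominator yields
  ``None`` (undefined), never a silent 0.
* The overall F1 is the macro average: the unweighted mean of per-class
  F1 over classes where it is defined.
* ROC curves are built by sweeping a threshold over the unique scores
  (equal scores grouped at one threshold) and AUC is the trapezoidal
  area, which equals the tie-corrected normalized Mann–Whitney U
  statistic.
* Percentages are formatted to one decimal, rounding halves up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "MetricsError",
    "confusion",
    "per_class",
    "accuracy",
    "f1",
    "macro_f1",
    "roc_and_auc",
    "multiclass_roc",
    "format_percent",
    "metrics_table",
]


class MetricsError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    """K×K counts; ``counts[i, j]`` = samples of true class i predicted j."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise MetricsError(f"counts shape {self.counts.shape} != ({k}, {k})")
        if (self.counts < 0).any():
            raise MetricsError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def num_classes(self) -> int:
        return len(self.class_names)


@dataclass
class RocCurve:
    """Step ROC curve from (0,0) to (1,1); FPR non-decreasing."""

    fpr: np.ndarray
    tpr: np.ndarray
    positive_class: int


def confusion(y_true, y_pred, num_classes: int,
              class_names: list[str] | None = None) -> ConfusionMatrix:
    """Tally a confusion matrix from integer label vectors."""
    y_true = np.asarray(y_true, np.int64)
    y_pred = np.asarray(y_pred, np.int64)
    if y_true.shape != y_pred.shape:
        raise MetricsError("y_true and y_pred length mismatch")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise MetricsError(f"{name} contains labels outside [0, {num_classes})")
    counts = np.zeros((num_classes, num_classes), np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    if class_names is None:
        class_names = [str(k) for k in range(num_classes)]
    return ConfusionMatrix(counts, class_names)


def per_class(cm: ConfusionMatrix, k: int) -> dict:
    """One-vs-rest counts and precision/recall for class ``k``.

    Undefined ratios (zero denominator) are returned as ``None`` with
    the ``"undefined"`` entry naming them.
    """
    if not 0 <= k < cm.num_classes:
        raise MetricsError(f"class {k} out of range")
    c = cm.counts
    tp = int(c[k, k])
    fn = int(c[k].sum() - tp)
    fp = int(c[:, k].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    undefined = []
    precision = tp / (tp + fp) if tp + fp > 0 else None
    if precision is None:
        undefined.append("precision")
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if recall is None:
        undefined.append("recall")
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "precision": precision, "recall": recall, "undefined": undefined}


def accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total: (TP+TN)/(TP+TN+FP+FN) in the one-vs-rest sense."""
    if cm.total == 0:
        raise MetricsError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def f1(precision: float | None, recall: float | None) -> float | None:
    """Harmonic mean 2PR/(P+R); ``None`` when undefined."""
    if precision is None or recall is None or precision + recall == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class F1 over classes where it is defined."""
    values = []
    for k in range(cm.num_classes):
        stats = per_class(cm, k)
        v = f1(stats["precision"], stats["recall"])
        if v is not None:
            values.append(v)
    if not values:
        raise MetricsError("F1 undefined for every class")
    return float(np.mean(values))


def roc_and_auc(scores, labels) -> tuple[RocCurve, float]:
    """Binary ROC by threshold sweep and trapezoidal AUC.

    ``labels`` are 0/1 with the positive class 1.  Ties in ``scores``
    are grouped at a single threshold, so the curve takes a diagonal
    step through tied groups and the trapezoidal area reproduces the
    tie-corrected Mann–Whitney statistic.
    """
    scores = np.asarray(scores, np.float64)
    labels = np.asarray(labels, np.int64)
    if scores.shape != labels.shape:
        raise MetricsError("scores and labels length mismatch")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricsError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # indices where the score strictly drops: one curve point per tie group
    distinct = np.flatnonzero(np.diff(s) != 0)
    cut = np.concatenate([distinct, [len(s) - 1]])
    tps = np.cumsum(y)[cut]
    fps = np.cumsum(1 - y)[cut]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr, tpr, positive_class=1), auc


def multiclass_roc(probs: np.ndarray, y_true) -> list[tuple[RocCurve, float]]:
    """One-vs-rest ROC/AUC per class from a softmax score matrix."""
    probs = np.asarray(probs, np.float64)
    y_true = np.asarray(y_true, np.int64)
    out = []
    for k in range(probs.shape[1]):
        curve, auc = roc_and_auc(probs[:, k], (y_true == k).astype(np.int64))
        out.append((RocCurve(curve.fpr, curve.tpr, positive_class=k), auc))
    return out


def format_percent(fraction: float | None, decimals: int = 1) -> str:
    """Format a fraction as a percentage, one decimal, half-up rounding."""
    if fraction is None:
        return "undefined"
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(repr(float(fraction))) * 100).quantize(q, rounding=ROUND_HALF_UP)
    return f"{value}%"


def metrics_table(cm: ConfusionMatrix, probs: np.ndarray | None = None,
                  y_true=None):
    """Per-class metrics as a DataFrame (plus AUC when scores are given)."""
    import pandas as pd

    rows = []
    aucs = None
    if probs is not None and y_true is not None:
        aucs = [auc for _, auc in multiclass_roc(probs, y_true)]
    for k, name in enumerate(cm.class_names):
        stats = per_class(cm, k)
        row = {"class": name, **{key: stats[key] for key in ("tp", "fp", "fn", "tn")},
               "precision": stats["precision"], "recall": stats["recall"],
               "f1": f1(stats["precision"], stats["recall"])}
        if aucs is not None:
            row["auc"] = aucs[k]
        rows.append(row)
    return pd.DataFrame(rows)
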