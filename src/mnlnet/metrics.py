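"""Confusion-count bookkeeping and the five performance metrics.

accuracy = (TP+TN)/(TP+TN+FP+FN), precision = TP/(TP+FP),
sensitivity = TP/(TP+FN), specificity = TN/(FP+TN),
F1 = 2*precision*sensitivity/(precision+sensitivity).

Multi-class tasks report overall accuracy plus the unweighted (macro) mean
of the one-vs-rest values of the other four metrics.  Ratios with a zero
denominator evaluate to 0 with a logged warning, so a degenerate fold never
aborts a cross-validation run.  Per-class values are always available so
any other averaging convention can be recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "confusion_counts", "score", "multiclass_score",
           "METRIC_NAMES"]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true, y_pred, positive_class: int) -> ConfusionCounts:
    """One-vs-rest confusion counts against the given positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator in %s; returning 0", what)
        return 0.0
    return num / den


def score(counts: ConfusionCounts) -> dict[str, float]:
    """The five metrics from one confusion table, each in [0, 1]."""
    if counts.total == 0:
        raise ValueError("no evaluated segments")
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    if precision + sensitivity > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        f1 = 0.0
    return {
        "accuracy": (counts.tp + counts.tn) / counts.total,
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": _ratio(counts.tn, counts.fp + counts.tn, "specificity"),
        "f1": f1,
    }


def multiclass_score(y_true, y_pred, n_classes: int) -> dict[str, float]:
    """Overall accuracy + macro one-vs-rest mean of the other four metrics.

    For the binary case with positive class 1 this coincides exactly with
    ``score(confusion_counts(y_true, y_pred, 1))`` except that the macro
    metrics average the two one-vs-rest views; use ``score`` directly when
    the single-positive-class (seizure vs rest) convention is wanted.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    per_class = {}
    for cls in range(n_classes):
        if not np.any(y_true == cls):
            logger.warning("class %d absent from y_true", cls)
        per_class[cls] = score(confusion_counts(y_true, y_pred, cls))
    out = {"accuracy": float(np.mean(y_true == y_pred))}
    for m in ("precision", "sensitivity", "specificity", "f1"):
        out[m] = float(np.mean([per_class[c][m] for c in range(n_classes)]))
    out["per_class"] = per_class
    return out


def task_score(y_true, y_pred, n_classes: int) -> dict[str, float]:
    """Metric set used in cross-validation reports.

    Binary tasks use the seizure class (index ``n_classes - 1``) as the
    positive/abnormal class; multi-class tasks use macro averaging.
    """
    if n_classes == 2:
        return score(confusion_counts(y_true, y_pred, positive_class=1))
    out = multiclass_score(y_true, y_pred, n_classes)
    out.pop("per_class")
    return out
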