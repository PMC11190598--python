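"""Confusion matrices and accuracy / sensitivity / specificity reporting.

Multi-class results reduce to per-class binary counts one-vs-rest: for
class i, TP is the diagonal cell, FN the rest of its row, FP the rest of
its column and TN everything else.  The three reported rates are

    Accuracy    = (TP + TN) / (TP + TN + FP + FN)
    Sensitivity =  TP / (TP + FN)
    Specificity =  TN / (TN + FP)

Macro averages are unweighted means over classes; a class with a zero
denominator (e.g. absent from the evaluation set) yields NaN with a
warning and is excluded from the macro average rather than silently
counted as zero.  Overall accuracy is trace / total.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k counts; rows are true labels, columns predicted."""

    counts: np.ndarray
    vocabulary: tuple[str, ...]

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "vocabulary", tuple(self.vocabulary))
        k = len(self.vocabulary)
        if counts.shape != (k, k):
            raise ValidationError(f"counts shape {counts.shape} does not match {k} labels")
        if np.any(counts < 0):
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.vocabulary), columns=list(self.vocabulary))


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and aggregate rates; NaN marks an undefined metric."""

    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    overall_accuracy: float

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "macro": self.macro,
            "overall_accuracy": self.overall_accuracy,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def confusion_matrix(y_true, y_pred, vocabulary) -> ConfusionMatrix:
    """Tally counts[i][j] = #(true = label i, predicted = label j)."""
    vocabulary = tuple(vocabulary)
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValidationError("true and predicted label lists differ in length")
    index = {label: i for i, label in enumerate(vocabulary)}
    counts = np.zeros((len(vocabulary), len(vocabulary)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValidationError(f"label pair ({t!r}, {p!r}) not in vocabulary")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, vocabulary=vocabulary)


def binary_reduce(cm: ConfusionMatrix, class_index: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, TN, FP, FN) for one class."""
    k = len(cm.vocabulary)
    if not 0 <= class_index < k:
        raise ValidationError(f"class index {class_index} out of range 0..{k - 1}")
    c = cm.counts
    tp = int(c[class_index, class_index])
    fn = int(c[class_index].sum()) - tp
    fp = int(c[:, class_index].sum()) - tp
    tn = cm.total - tp - fn - fp
    return tp, tn, fp, fn


def _rate(num: int, den: int, name: str, label: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined for class {label!r} (zero denominator)", stacklevel=3)
        return float("nan")
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class one-vs-rest rates, macro averages and overall accuracy."""
    if cm.total == 0:
        raise ValidationError("cannot compute metrics of an empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    for i, label in enumerate(cm.vocabulary):
        tp, tn, fp, fn = binary_reduce(cm, i)
        per_class[label] = {
            "accuracy": _rate(tp + tn, tp + tn + fp + fn, "accuracy", label),
            "sensitivity": _rate(tp, tp + fn, "sensitivity", label),
            "specificity": _rate(tn, tn + fp, "specificity", label),
        }
    macro = {}
    for name in ("accuracy", "sensitivity", "specificity"):
        values = np.array([per_class[l][name] for l in cm.vocabulary])
        defined = values[~np.isnan(values)]
        macro[name] = float(defined.mean()) if defined.size else float("nan")
    overall = float(np.trace(cm.counts) / cm.total)
    return MetricsReport(per_class=per_class, macro=macro, overall_accuracy=overall)
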