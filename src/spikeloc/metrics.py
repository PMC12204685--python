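"""Performance metrics: balanced accuracy, multi-class MCC, confusion tables.

Balanced accuracy is the macro average of per-class recall (true positive
rate); chance level is 1/k for k classes.  The multi-class Matthews
correlation coefficient is computed from the confusion-matrix marginals

    MCC = (c*s - sum_n p_n*t_n) /
          sqrt((s^2 - sum_n p_n^2) * (s^2 - sum_n t_n^2))

where rows of C are true labels and columns predictions, ``t_n``/``p_n``
are the true/predicted class totals, ``c`` the trace and ``s`` the sample
count.  It ranges from -1 (total disagreement) through 0 (chance) to +1
(perfect prediction) and is robust to class imbalance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "balanced_accuracy",
    "multiclass_mcc",
    "chance_level",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = true labels, columns = predicted labels."""

    counts: np.ndarray
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        C = np.asarray(self.counts, dtype=float)
        n = len(self.class_labels)
        if C.shape != (n, n):
            raise ValueError("confusion matrix must be square over class_labels")
        if (C < 0).any():
            raise ValueError("negative counts")
        object.__setattr__(self, "counts", C)

    @property
    def t_n(self) -> np.ndarray:
        """Occurrences of each class in the actual data (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def p_n(self) -> np.ndarray:
        """Occurrences of each class in the predictions (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def c(self) -> float:
        return float(np.trace(self.counts))

    @property
    def s(self) -> float:
        return float(self.counts.sum())

    def row_proportions(self) -> np.ndarray:
        """Rows normalized to sum to 1 (rows with no samples stay zero)."""
        t = self.t_n
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(t[:, None] > 0, self.counts / t[:, None], 0.0)
        return out

    def per_class_sensitivity(self) -> np.ndarray:
        """Recall (true positive rate) per class; NaN for empty classes."""
        t = self.t_n
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(t > 0, np.diag(self.counts) / t, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_labels),
                            columns=list(self.class_labels))


def confusion(y_true, y_pred, class_order=None) -> ConfusionMatrix:
    """Tally a confusion matrix over ``class_order`` (default: sorted union)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if class_order is None:
        class_order = sorted(set(y_true) | set(y_pred))
    labels = [str(c) for c in class_order]
    pos = {c: i for i, c in enumerate(labels)}
    unknown = (set(map(str, y_true)) | set(map(str, y_pred))) - set(labels)
    if unknown:
        raise ValueError(f"labels outside class_order: {sorted(unknown)}")
    C = np.zeros((len(labels), len(labels)))
    for t, p in zip(y_true, y_pred):
        C[pos[str(t)], pos[str(p)]] += 1
    return ConfusionMatrix(C, tuple(labels))


def balanced_accuracy(y_true, y_pred, class_order=None) -> float:
    """Macro average of per-class recall over classes present in ``y_true``.

    With an explicit ``class_order``, classes that have no true samples are
    excluded with a warning.
    """
    cm = confusion(y_true, y_pred, class_order)
    sens = cm.per_class_sensitivity()
    present = ~np.isnan(sens)
    if class_order is not None and not present.all():
        warnings.warn("classes with no true samples excluded from balanced accuracy")
    if not present.any():
        raise ValueError("no true samples")
    return float(np.mean(sens[present]))


def multiclass_mcc(cm: ConfusionMatrix | np.ndarray) -> float:
    """Multi-class Matthews correlation coefficient of a confusion matrix.

    An undefined denominator (all mass in one true or one predicted class)
    is returned as 0 with a warning.
    """
    if not isinstance(cm, ConfusionMatrix):
        C = np.asarray(cm, dtype=float)
        cm = ConfusionMatrix(C, tuple(str(i) for i in range(C.shape[0])))
    if cm.s <= 0:
        raise ValueError("empty confusion matrix")
    t, p, c, s = cm.t_n, cm.p_n, cm.c, cm.s
    denom2 = (s**2 - np.sum(p**2)) * (s**2 - np.sum(t**2))
    if denom2 <= 0:
        warnings.warn("MCC denominator is 0 (single observed or predicted class); "
                      "returning 0")
        return 0.0
    return float((c * s - np.sum(p * t)) / np.sqrt(denom2))


def chance_level(k: int) -> float:
    """Chance balanced accuracy for a k-class task: 1/k."""
    if k < 2:
        raise ValueError("need at least 2 classes")
    return 1.0 / k


@dataclass(frozen=True)
class EvalReport:
    """Scores of one prediction set: confusion, balanced accuracy, MCC."""

    confusion: ConfusionMatrix
    balanced_accuracy: float
    mcc: float
    chance: float
    per_class_sensitivity: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_labels": list(self.confusion.class_labels),
            "confusion": self.confusion.counts.tolist(),
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
            "chance": self.chance,
            "per_class_sensitivity": self.per_class_sensitivity,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate(y_true, y_pred, class_order=None) -> EvalReport:
    """Full evaluation report for one prediction set."""
    cm = confusion(y_true, y_pred, class_order)
    sens = cm.per_class_sensitivity()
    present = ~np.isnan(sens)
    return EvalReport(
        confusion=cm,
        balanced_accuracy=float(np.mean(sens[present])),
        mcc=multiclass_mcc(cm),
        chance=chance_level(max(2, int(present.sum()))),
        per_class_sensitivity={
            c: (None if np.isnan(v) else float(v))
            for c, v in zip(cm.class_labels, sens)
        },
    )
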