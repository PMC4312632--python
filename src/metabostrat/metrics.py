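"""Classification performance statistics for the imbalanced two-class setting.

Class 1 (excess, minority) is the positive class throughout.  The balanced
accuracy defined here — the arithmetic mean of sensitivity and specificity —
is the single shared definition: the GA's balanced prediction error is
``1 - balanced_accuracy``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionSummary",
    "ConfusionMetrics",
    "ModelReport",
    "confusion_summary",
    "confusion_metrics",
    "balanced_error",
    "auc",
    "auc_ci",
]


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


class ConfusionMetrics(NamedTuple):
    sensitivity: float
    specificity: float
    total_accuracy: float
    balanced_accuracy: float


def _check_binary(y, name):
    y = np.asarray(y)
    if not np.isin(y, [0, 1]).all():
        raise ValueError(f"{name} must be coded 0/1")
    return y.astype(int)


def confusion_summary(y_true, y_pred) -> ConfusionSummary:
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return ConfusionSummary(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def confusion_metrics(y_true, y_pred) -> ConfusionMetrics:
    """Sensitivity, specificity, total and balanced accuracy.

    Requires both classes present in ``y_true`` (sensitivity and specificity
    are otherwise undefined).
    """
    cs = confusion_summary(y_true, y_pred)
    pos, neg = cs.tp + cs.fn, cs.tn + cs.fp
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present in y_true")
    sens = cs.tp / pos
    spec = cs.tn / neg
    return ConfusionMetrics(
        sensitivity=sens,
        specificity=spec,
        total_accuracy=(cs.tp + cs.tn) / (pos + neg),
        balanced_accuracy=0.5 * (sens + spec),
    )


def balanced_error(y_true, y_pred) -> float:
    """1 - balanced accuracy; the quantity minimized by the GA fitness."""
    return 1.0 - confusion_metrics(y_true, y_pred).balanced_accuracy


def auc(y_true, scores) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formula, ties 1/2."""
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=float)
    n1 = int(y_true.sum())
    n0 = y_true.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_components(pos_scores, neg_scores):
    """Per-observation placement values V10 (positives) and V01 (negatives)."""
    m, n = len(pos_scores), len(neg_scores)
    all_scores = np.concatenate([pos_scores, neg_scores])
    ranks_all = stats.rankdata(all_scores)
    ranks_pos = stats.rankdata(pos_scores)
    ranks_neg = stats.rankdata(neg_scores)
    v10 = (ranks_all[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    return v10, v01


def auc_ci(y_true, scores, level: float = 0.95):
    """DeLong variance-based confidence interval for the AUC, clipped to [0, 1].

    With fewer than two observations in either class the variance is not
    estimable; the interval widens to [0, 1].
    """
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=float)
    point = auc(y_true, scores)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if len(pos) < 2 or len(neg) < 2:
        import warnings

        warnings.warn("too few observations for a DeLong variance; returning [0, 1]")
        return 0.0, 1.0
    v10, v01 = _delong_components(pos, neg)
    var = np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(np.clip(point - half, 0.0, 1.0)), float(np.clip(point + half, 0.0, 1.0))


@dataclass
class ModelReport:
    """Headline statistics of a fitted classifier, one row of the report table."""

    sigma: float
    ao: int
    accv: float
    r2x: float
    r2y: float
    q2y: float
    total_accuracy: float
    balanced_accuracy: float
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_row(self) -> str:
        d = self.to_dict()
        cols = list(d)
        return "\t".join(cols) + "\n" + "\t".join(
            f"{d[c]:.4g}" if isinstance(d[c], float) else str(d[c]) for c in cols
        )
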