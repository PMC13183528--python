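"""Confusion-matrix metrics, rank AUC and the imbalance-robust suite.

The malignant class is the positive class throughout, matching the clinical
framing (a false negative is a missed melanoma).  Metrics whose denominator
vanishes (0/0) are reported as ``None`` — an explicit undefined marker —
rather than silently substituted with 0 or 1.

Provided metrics: precision, sensitivity (recall), specificity, F1, accuracy,
rank-statistic AUC, and for imbalanced data balanced accuracy, the geometric
mean of sensitivity and specificity (G-mean), Matthews correlation
coefficient (MCC) and Cohen's kappa.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "basic_metrics",
    "imbalance_metrics",
    "auc",
    "full_report",
]

POSITIVE_CLASS = "malignant"


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with the malignant class as positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("need at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """All derived performance metrics; ``None`` marks an undefined entry."""

    precision: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    f1: float | None = None
    accuracy: float | None = None
    auc: float | None = None
    balanced_accuracy: float | None = None
    g_mean: float | None = None
    mcc: float | None = None
    kappa: float | None = None

    def to_dict(self, percent: bool = False) -> dict:
        """Plain dict; with ``percent=True`` the [0, 1] rates are scaled x100
        (MCC and kappa keep their natural [-1, 1] scale)."""
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if percent and v is not None and f.name not in ("mcc", "kappa"):
                v = 100.0 * v
            out[f.name] = v
        return out

    def merge(self, other: "MetricsReport") -> "MetricsReport":
        for f in fields(self):
            v = getattr(other, f.name)
            if v is not None:
                setattr(self, f.name, v)
        return self


def confusion(pred_labels, true_labels, positive: str = POSITIVE_CLASS
              ) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary labels.

    All labels (predicted and true) must come from at most two distinct
    values including ``positive``; anything else is an input error.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("predictions and truths must be equal-length, non-empty")
    values = set(np.unique(pred)) | set(np.unique(true))
    others = values - {positive}
    if len(others) > 1:
        raise ValueError(f"unknown labels {sorted(others)}; expected "
                         f"{positive!r} and one negative label")
    p = pred == positive
    t = true == positive
    return ConfusionCounts(tp=int((p & t).sum()), tn=int((~p & ~t).sum()),
                           fp=int((p & ~t).sum()), fn=int((~p & t).sum()))


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def basic_metrics(c: ConfusionCounts) -> MetricsReport:
    """Precision, sensitivity, specificity, F1 and accuracy from counts."""
    precision = _ratio(c.tp, c.tp + c.fp)
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(precision=precision, sensitivity=sensitivity,
                         specificity=specificity, f1=f1,
                         accuracy=(c.tp + c.tn) / c.total)


def imbalance_metrics(c: ConfusionCounts) -> MetricsReport:
    """Balanced accuracy, G-mean, MCC and Cohen's kappa from counts.

    MCC is undefined (None) when any marginal is zero; kappa is undefined
    when the chance agreement is exactly 1.
    """
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    if sens is None or spec is None:
        bal, gmean = None, None
    else:
        bal = (sens + spec) / 2.0
        gmean = math.sqrt(sens * spec)
    den = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = None if den == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(den)
    n = c.total
    po = (c.tp + c.tn) / n
    pe = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / (n * n)
    kappa = None if pe == 1.0 else (po - pe) / (1.0 - pe)
    return MetricsReport(balanced_accuracy=bal, g_mean=gmean, mcc=mcc,
                         kappa=kappa)


def auc(scores, true_labels, positive: str = POSITIVE_CLASS) -> float | None:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    ``scores`` are positive-class probabilities (or any monotone score); tied
    scores contribute 1/2 through mid-ranks.  Returns None when only one
    class is present.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(true_labels) == positive
    if s.shape != t.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)
    u = ranks[t].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def full_report(pred_labels, true_labels, scores=None,
                positive: str = POSITIVE_CLASS) -> MetricsReport:
    """Complete metrics report from hard labels and optional scores."""
    c = confusion(pred_labels, true_labels, positive)
    report = basic_metrics(c).merge(imbalance_metrics(c))
    if scores is not None:
        report.auc = auc(scores, true_labels, positive)
    return report
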