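"""Classification metrics on (possibly fractional) confusion matrices.

Confusion matrices follow the rows-are-actual, columns-are-predicted
convention.  Counts may be fractional: a matrix averaged over repeated
cross-validation runs and stored as row percentages converts back to
fractional counts via the class sizes.

Undefined ratios (e.g. precision with an empty predicted-positive column)
are reported as ``None`` rather than silently coerced to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "from_percentages",
    "per_class_metrics",
    "combined_positive_metrics",
    "overall_accuracy",
    "build_report",
    "load_reference_confusion",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.725 -> 0.73), for report display only."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 (or KxK) fractional counts with actual classes on rows."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if len(self.labels) != c.shape[0]:
            raise ValueError("label count does not match matrix size")
        if (c < 0).any():
            raise ValueError("confusion counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown class label {label!r}") from None

    @property
    def class_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class ClassMetrics:
    label: str
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    balanced_accuracy: float | None


@dataclass(frozen=True)
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    combined_positive: ClassMetrics
    overall_accuracy: float
    labels: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        def cm_dict(m: ClassMetrics) -> dict:
            return {
                "precision": m.precision,
                "recall": m.recall,
                "specificity": m.specificity,
                "f1": m.f1,
                "balanced_accuracy": m.balanced_accuracy,
            }

        return {
            "per_class": {k: cm_dict(v) for k, v in self.per_class.items()},
            "combined_positive": cm_dict(self.combined_positive),
            "overall_accuracy": self.overall_accuracy,
        }

    def format_table(self, ndigits: int = 2) -> str:
        """Plain-text table: one row per class, five metric columns."""
        cols = ["Balanced Accuracy", "Sensitivity (Recall)", "Specificity",
                "Precision", "F1-Score"]
        lines = ["Actual\t" + "\t".join(cols)]

        def fmt(v: float | None) -> str:
            return "n/a" if v is None else f"{round_half_up(v, ndigits):.{ndigits}f}"

        for lab, m in self.per_class.items():
            lines.append("\t".join([lab, fmt(m.balanced_accuracy), fmt(m.recall),
                                    fmt(m.specificity), fmt(m.precision), fmt(m.f1)]))
        m = self.combined_positive
        lines.append("\t".join([m.label, fmt(m.balanced_accuracy), fmt(m.recall),
                                fmt(m.specificity), fmt(m.precision), fmt(m.f1)]))
        lines.append(f"Overall accuracy\t{fmt(self.overall_accuracy)}")
        return "\n".join(lines)


def from_percentages(row_pcts: Sequence[Sequence[float]],
                     class_sizes: Sequence[float],
                     labels: Sequence[str]) -> ConfusionMatrix:
    """Convert mean row-percentages back to fractional counts.

    counts[i, j] = class_sizes[i] * row_pcts[i, j] / 100.  Rows need not sum
    to exactly 100 (iteration-averaged matrices usually do not).
    """
    p = np.asarray(row_pcts, dtype=float)
    sizes = np.asarray(class_sizes, dtype=float)
    if (p < 0).any():
        raise ValueError("percentages must be nonnegative")
    if (sizes <= 0).any():
        raise ValueError("class sizes must be positive")
    if p.shape != (len(sizes), len(sizes)):
        raise ValueError("percentage matrix shape does not match class sizes")
    return ConfusionMatrix(p * sizes[:, None] / 100.0, tuple(labels))


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def _f1(precision: float | None, recall: float | None) -> float | None:
    if precision is None or recall is None or (precision + recall) == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def per_class_metrics(cm: ConfusionMatrix, positive: str) -> ClassMetrics:
    """One-vs-rest metrics for a single positive class."""
    i = cm.index(positive)
    c = cm.counts
    tp = c[i, i]
    fp = c[:, i].sum() - tp
    fn = c[i, :].sum() - tp
    tn = cm.total - tp - fp - fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    bal = None if recall is None or specificity is None else (recall + specificity) / 2
    return ClassMetrics(positive, precision, recall, specificity,
                        _f1(precision, recall), bal)


def combined_positive_metrics(cm: ConfusionMatrix,
                              positives: Sequence[str]) -> ClassMetrics:
    """Micro-aggregated metrics with a pool of positive classes.

    TP, FP and FN are summed one-vs-rest over the positive classes, so a
    confusion between two pooled classes counts as both an FP and an FN.
    """
    pos = tuple(positives)
    if set(pos) >= set(cm.labels):
        raise ValueError("positive pool must be a strict subset of classes")
    c = cm.counts
    tp = fp = fn = 0.0
    for lab in pos:
        i = cm.index(lab)
        tp += c[i, i]
        fp += c[:, i].sum() - c[i, i]
        fn += c[i, :].sum() - c[i, i]
    tn = cm.total - tp - fp - fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    bal = None if recall is None or specificity is None else (recall + specificity) / 2
    return ClassMetrics("+".join(pos), precision, recall, specificity,
                        _f1(precision, recall), bal)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def build_report(cm: ConfusionMatrix,
                 positive_pool: Sequence[str] = ("EOA", "DCD")) -> MetricsReport:
    per_class = {lab: per_class_metrics(cm, lab) for lab in cm.labels}
    return MetricsReport(
        per_class=per_class,
        combined_positive=combined_positive_metrics(cm, positive_pool),
        overall_accuracy=overall_accuracy(cm),
        labels=cm.labels,
    )


def load_reference_confusion() -> tuple[ConfusionMatrix, dict]:
    """Bundled reference confusion matrix (mean row percentages over 100
    repeated runs of the published three-class protocol, class sizes
    18/13/29).  Returns the fractional-count matrix and the raw fixture."""
    raw = json.loads(
        resources.files("coordgait.data").joinpath("reference_confusion.json").read_text()
    )
    cm = from_percentages(raw["row_percentages"], raw["class_sizes"], raw["labels"])
    return cm, raw
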