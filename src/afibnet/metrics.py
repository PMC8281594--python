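"""Confusion-matrix bookkeeping and the five evaluation metrics.

Per class c (one-vs-rest): TP = predicted c and truly c, FP = predicted
c but not c, FN = truly c but predicted otherwise, TN = the rest.

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)          (recall, true-positive rate)
    specificity = TN / (TN + FP)          (true-negative rate)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

A ratio with a zero denominator is reported as NaN (not-a-value),
never silently as 0.  For a binary report the headline metrics are
those of the positive (AF) class; for three classes they are
unweighted macro-averages.  Fold averaging is the plain arithmetic
mean of per-fold metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClassCounts", "MetricsReport", "compute_metrics", "fold_average", "report_frame"]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1", "precision")


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def _ratio(self, num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def f1(self) -> float:
        p, s = self.precision, self.sensitivity
        if math.isnan(p) or math.isnan(s) or (p + s) == 0:
            return float("nan")
        return 2 * p * s / (p + s)

    def metric(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class MetricsReport:
    """Per-class confusion counts plus derived metrics for one
    evaluation (e.g. one fold's validation split)."""

    classes: tuple[str, ...]
    counts: dict[str, ClassCounts]
    n: int

    @property
    def overall_accuracy(self) -> float:
        """Fraction of episodes assigned their true label."""
        correct = sum(self.counts[c].tp for c in self.classes)
        return correct / self.n if self.n else float("nan")

    def per_class(self, name: str) -> dict[str, float]:
        return {c: self.counts[c].metric(name) for c in self.classes}

    def macro(self, name: str) -> float:
        return float(np.mean([self.counts[c].metric(name) for c in self.classes]))

    def summary(self) -> dict[str, float]:
        """The headline five metrics.

        Binary (N, AF): metrics of the AF (positive) class, with
        accuracy the overall accuracy.  Three-class: overall accuracy
        plus macro-averages of the other four.
        """
        if len(self.classes) == 2:
            pos = self.counts[self.classes[1]]
            return {
                "accuracy": self.overall_accuracy,
                "sensitivity": pos.sensitivity,
                "specificity": pos.specificity,
                "f1": pos.f1,
                "precision": pos.precision,
            }
        out = {"accuracy": self.overall_accuracy}
        for name in METRIC_NAMES[1:]:
            out[name] = self.macro(name)
        return out


def compute_metrics(y_true, y_pred, classes: tuple[str, ...]) -> MetricsReport:
    """Build the full report from parallel label sequences."""
    y_true, y_pred = list(y_true), list(y_pred)
    if not y_true:
        raise ValueError("cannot evaluate an empty label set")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    n = len(y_true)
    counts: dict[str, ClassCounts] = {}
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        counts[c] = ClassCounts(tp=tp, fp=fp, fn=fn, tn=n - tp - fp - fn)
    return MetricsReport(classes=tuple(classes), counts=counts, n=n)


def fold_average(summaries: list[dict[str, float]]) -> dict[str, float]:
    """Unweighted arithmetic mean of per-fold headline metrics."""
    if not summaries:
        raise ValueError("no fold summaries to average")
    return {
        name: float(np.mean([s[name] for s in summaries]))
        for name in METRIC_NAMES
    }


def report_frame(summaries: list[dict[str, float]], average: dict[str, float]) -> pd.DataFrame:
    """Tabulate per-fold metrics plus the average row, as percentages
    rounded to 2 decimals (one row per fold, columns = five metrics)."""
    rows = []
    for i, s in enumerate(summaries, start=1):
        rows.append({"fold": str(i), **{k: round(100 * v, 2) for k, v in s.items()}})
    rows.append({"fold": "Average", **{k: round(100 * v, 2) for k, v in average.items()}})
    return pd.DataFrame(rows, columns=["fold", *METRIC_NAMES])
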