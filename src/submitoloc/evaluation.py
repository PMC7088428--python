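"""One-vs-rest evaluation metrics: sensitivity, specificity, accuracy, MCC, AUC.

For a four-class problem each class k is scored against the rest, giving
TP/FP/TN/FN counts from the 4x4 confusion matrix:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

A metric whose denominator vanishes is *undefined* and reported as NaN,
never silently as 0 -- with a handful of samples in the rarest compartment,
degenerate folds are a realistic occurrence and must stay visible.

AUC is the area under the ROC curve (true-positive rate against
false-positive rate over all score thresholds), computed by the rank-based
Mann-Whitney formulation, which counts tied scores as half-concordant and
equals trapezoidal integration of the empirical curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata


@dataclass
class ConfusionCounts:
    """A multi-class confusion matrix with one-vs-rest count views."""

    classes: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)  # matrix[i, j] = true i, predicted j

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        k = len(self.classes)
        if self.matrix.shape != (k, k):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {k} classes"
            )
        if np.any(self.matrix < 0):
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(
        cls,
        y_true: Sequence[str],
        y_pred: Sequence[str],
        classes: Sequence[str],
    ) -> "ConfusionCounts":
        index = {c: i for i, c in enumerate(classes)}
        matrix = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred, strict=True):
            matrix[index[t], index[p]] += 1
        return cls(classes=tuple(classes), matrix=matrix)

    def one_vs_rest(self, cls_name: str) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for one class against the rest."""
        k = self.classes.index(cls_name)
        tp = int(self.matrix[k, k])
        fp = int(self.matrix[:, k].sum() - tp)
        fn = int(self.matrix[k, :].sum() - tp)
        tn = int(self.matrix.sum() - tp - fp - fn)
        return tp, fp, tn, fn

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def overall_accuracy(self) -> float:
        """trace(M) / sum(M): the fraction of correctly classified samples."""
        if self.total == 0:
            return math.nan
        return float(np.trace(self.matrix)) / self.total

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if self.classes != other.classes:
            raise ValueError("cannot add confusion counts over different classes")
        return ConfusionCounts(classes=self.classes, matrix=self.matrix + other.matrix)


def _check_counts(*counts: int) -> None:
    for c in counts:
        if c < 0:
            raise ValueError("confusion counts must be non-negative")


def sensitivity(tp: int, fn: int) -> float:
    """TP / (TP + FN); NaN when the class has no positives."""
    _check_counts(tp, fn)
    if tp + fn == 0:
        return math.nan
    return tp / (tp + fn)


def specificity(tn: int, fp: int) -> float:
    """TN / (TN + FP); NaN when the class has no negatives."""
    _check_counts(tn, fp)
    if tn + fp == 0:
        return math.nan
    return tn / (tn + fp)


def accuracy(tp: int, fp: int, tn: int, fn: int) -> float:
    """(TP + TN) / all; NaN on an empty sample."""
    _check_counts(tp, fp, tn, fn)
    total = tp + fp + tn + fn
    if total == 0:
        return math.nan
    return (tp + tn) / total


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; NaN when a denominator factor is 0."""
    _check_counts(tp, fp, tn, fn)
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom == 0:
        return math.nan
    return (tp * tn - fp * fn) / math.sqrt(denom)


def roc_auc(
    scores: Sequence[float],
    truth: Sequence[int],
) -> tuple[float, np.ndarray]:
    """AUC and ROC curve points for binary one-vs-rest truth.

    Returns ``(auc, points)`` where ``points`` is an (m, 2) array of
    (false-positive rate, true-positive rate) pairs over all distinct
    thresholds, endpoints included.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth differ in length")
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both positive and negative samples")

    # Mann-Whitney with midranks: ties count half.
    ranks = rankdata(scores)
    auc = (ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # Empirical curve, thresholds descending; ties collapse to one point.
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    tps = np.cumsum(truth[order])
    fps = np.cumsum(1 - truth[order])
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    points = np.column_stack(
        [np.r_[0.0, fps[distinct] / n_neg], np.r_[0.0, tps[distinct] / n_pos]]
    )
    return float(auc), points


def summarize(
    confusion: ConfusionCounts,
    decision_scores: Mapping[str, np.ndarray] | None = None,
    truth_labels: Sequence[str] | None = None,
) -> dict:
    """Per-class and macro metrics from a confusion matrix (+ optional ROC).

    ``decision_scores`` maps class name to per-sample one-vs-rest decision
    values aligned with ``truth_labels``; when supplied, per-class and
    macro AUC are included. NaN marks metrics with empty denominators;
    macro averages skip NaN entries.
    """
    per_class: dict[str, dict[str, float]] = {}
    for cls_name in confusion.classes:
        tp, fp, tn, fn = confusion.one_vs_rest(cls_name)
        entry = {
            "tp": tp,
            "fp": fp,
            "tn": tn,
            "fn": fn,
            "sensitivity": sensitivity(tp, fn),
            "specificity": specificity(tn, fp),
            "mcc": mcc(tp, fp, tn, fn),
        }
        if decision_scores is not None and truth_labels is not None:
            truth = np.array([1 if t == cls_name else 0 for t in truth_labels])
            if truth.any() and not truth.all():
                entry["auc"], _ = roc_auc(decision_scores[cls_name], truth)
            else:
                entry["auc"] = math.nan
        per_class[cls_name] = entry

    def _macro(key: str) -> float:
        vals = [v[key] for v in per_class.values() if key in v and not math.isnan(v[key])]
        return float(np.mean(vals)) if vals else math.nan

    report = {
        "per_class": per_class,
        "overall_accuracy": confusion.overall_accuracy(),
        "macro_sensitivity": _macro("sensitivity"),
        "macro_specificity": _macro("specificity"),
        "macro_mcc": _macro("mcc"),
    }
    if decision_scores is not None:
        report["macro_auc"] = _macro("auc")
    return report


def format_class_table(report: dict) -> str:
    """Render per-class sensitivity/specificity as a plain-text table."""
    lines = [f"{'class':<22}{'sensitivity (%)':>18}{'specificity (%)':>18}"]
    for cls_name, entry in report["per_class"].items():
        sens = entry["sensitivity"] * 100
        spec = entry["specificity"] * 100
        lines.append(f"{cls_name:<22}{sens:>18.2f}{spec:>18.2f}")
    lines.append(f"overall accuracy: {report['overall_accuracy'] * 100:.2f}%")
    return "\n".join(lines)
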