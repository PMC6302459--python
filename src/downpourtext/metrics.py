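"""Multiclass evaluation: confusion matrices, per-class P/R/F1, micro/macro F1.

Zero-division convention: precision, recall and F1 are defined as 0 when
their denominators vanish (a class never predicted and never present scores
0.00 across the board), so no NaNs escape.  Macro averaging includes every
class in the class set by default — the conservative reading of "equal
weight to each class" — with an option to restrict to classes that carry
support in the evaluated set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "ClassReport", "confusion", "report", "normalize_by_support"]


@dataclass
class ConfusionMatrix:
    """K x K integer counts; rows are actual classes, columns predicted."""

    counts: np.ndarray
    class_set: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_set)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K = len(class_set)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_set != other.class_set:
            raise ValueError("cannot add confusion matrices over different class sets")
        return ConfusionMatrix(self.counts + other.counts, list(self.class_set))


def confusion(y_true, y_pred, class_set) -> ConfusionMatrix:
    """Count actual/predicted label pairs over an equal-length pair of sequences."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences differ in length")
    index = {label: i for i, label in enumerate(class_set)}
    k = len(class_set)
    counts = np.zeros((k, k), dtype=np.int64)
    for a, p in zip(y_true, y_pred):
        if a not in index:
            raise ValueError(f"unknown actual label {a!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_set=list(class_set))


@dataclass
class ClassReport:
    """Per-class precision/recall/F1 with supports, plus micro and macro F1."""

    class_set: list
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    micro_f1: float
    macro_f1: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.class_set,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def report(cm: ConfusionMatrix, include_zero_support: bool = True) -> ClassReport:
    """Precision/recall/F1 per class and pooled micro / unweighted macro F1.

    Micro-F1 pools true/false positives over all decisions (for single-label
    multiclass data it equals accuracy); macro-F1 is the unweighted mean of
    per-class F1, over all classes or only supported ones.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm.counts).astype(float)
    predicted = cm.counts.sum(axis=0).astype(float)
    actual = cm.counts.sum(axis=1).astype(float)
    precision = _safe_div(tp, predicted)
    recall = _safe_div(tp, actual)
    f1 = _safe_div(2 * precision * recall, precision + recall)

    pooled_tp = tp.sum()
    pooled_fp = (predicted - tp).sum()
    pooled_fn = (actual - tp).sum()
    micro_p = pooled_tp / (pooled_tp + pooled_fp) if pooled_tp + pooled_fp > 0 else 0.0
    micro_r = pooled_tp / (pooled_tp + pooled_fn) if pooled_tp + pooled_fn > 0 else 0.0
    micro_f1 = (
        2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r > 0 else 0.0
    )
    mask = np.ones(len(cm.class_set), dtype=bool) if include_zero_support else actual > 0
    macro_f1 = float(f1[mask].mean()) if mask.any() else 0.0
    return ClassReport(
        class_set=list(cm.class_set),
        precision=precision,
        recall=recall,
        f1=f1,
        support=actual.astype(np.int64),
        micro_f1=float(micro_f1),
        macro_f1=macro_f1,
    )


def normalize_by_support(cm: ConfusionMatrix) -> np.ndarray:
    """Divide each row by its support; zero-support rows stay all-zero."""
    counts = cm.counts.astype(float)
    sup = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sup > 0, counts / np.where(sup > 0, sup, 1.0), 0.0)
    return out
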