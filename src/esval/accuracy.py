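"""Thematic-map accuracy assessment: confusion matrix, overall accuracy,
Cohen's kappa, and per-class producer/user accuracies.

Orientation follows the remote-sensing convention: **rows are the map
labels** (user's perspective), **columns are the reference labels**
(producer's perspective). Producer accuracy for a class is the diagonal
count over its column total (omission-error complement); user accuracy is
the diagonal over its row total (commission-error complement).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReferencePointSet",
    "ConfusionMatrix",
    "build_confusion",
    "overall_accuracy",
    "kappa",
    "producers_accuracy",
    "users_accuracy",
    "accuracy_report",
]


@dataclass
class ReferencePointSet:
    """Labelled validation points: (row, col, true_class, mapped_class) records."""

    records: pd.DataFrame

    REQUIRED = ("row", "col", "true_class", "mapped_class")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"reference point set missing columns {missing}")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferencePointSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class ConfusionMatrix:
    """Square map-vs-reference count matrix over an ordered class list."""

    classes: list[int]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts shape {self.counts.shape} not square of order {k}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def build_confusion(points: ReferencePointSet, class_order: Sequence[int]) -> ConfusionMatrix:
    """Tally points into a confusion matrix (rows = map, columns = reference)."""
    class_order = [int(c) for c in class_order]
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for mapped, true in zip(points.records["mapped_class"], points.records["true_class"]):
        mapped, true = int(mapped), int(true)
        if mapped not in index:
            raise ValueError(f"mapped class {mapped} not in class order {class_order}")
        if true not in index:
            raise ValueError(f"reference class {true} not in class order {class_order}")
        counts[index[mapped], index[true]] += 1
    return ConfusionMatrix(classes=class_order, counts=counts)


def _check_nonempty(cm: ConfusionMatrix) -> None:
    if cm.total == 0:
        raise ValueError("confusion matrix is empty; metrics undefined")


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total: the fraction of points whose map label matches the reference."""
    _check_nonempty(cm)
    return float(np.trace(cm.counts) / cm.total)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement (p_o - p_e)/(1 - p_e).

    p_o is the observed agreement (trace/total); p_e the agreement expected
    from the row and column marginals alone. Degenerate matrices with
    p_e = 1 (all mass in a single row-and-column) are undefined.
    """
    _check_nonempty(cm)
    total = cm.total
    p_o = np.trace(cm.counts) / total
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    p_e = float((row @ col) / total**2)
    if abs(1.0 - p_e) < 1e-15:
        raise ValueError("expected agreement is 1; kappa undefined for this matrix")
    return float((p_o - p_e) / (1.0 - p_e))


def producers_accuracy(cm: ConfusionMatrix) -> dict[int, float]:
    """Diagonal over column (reference) totals; NaN where a class has no reference points."""
    _check_nonempty(cm)
    col = cm.counts.sum(axis=0)
    diag = np.diag(cm.counts)
    return {
        c: (float(diag[i] / col[i]) if col[i] > 0 else float("nan"))
        for i, c in enumerate(cm.classes)
    }


def users_accuracy(cm: ConfusionMatrix) -> dict[int, float]:
    """Diagonal over row (map) totals; NaN where a class was never mapped."""
    _check_nonempty(cm)
    row = cm.counts.sum(axis=1)
    diag = np.diag(cm.counts)
    return {
        c: (float(diag[i] / row[i]) if row[i] > 0 else float("nan"))
        for i, c in enumerate(cm.classes)
    }


def accuracy_report(cm: ConfusionMatrix, class_names: dict[int, str] | None = None) -> pd.DataFrame:
    """Per-class producer/user accuracy table with overall accuracy and kappa attached."""
    pa = producers_accuracy(cm)
    ua = users_accuracy(cm)
    names = class_names or {}
    df = pd.DataFrame(
        {
            "class_code": cm.classes,
            "class_name": [names.get(c, f"class_{c}") for c in cm.classes],
            "producer_accuracy": [pa[c] for c in cm.classes],
            "user_accuracy": [ua[c] for c in cm.classes],
        }
    )
    df.attrs["overall_accuracy"] = overall_accuracy(cm)
    df.attrs["kappa"] = kappa(cm)
    return df
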