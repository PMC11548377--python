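"""Confusion-matrix accuracy assessment.

Rows are the reference labels, columns the predicted labels (the choice is
documentation-only: overall accuracy and Cohen's kappa are both invariant
under transposition).  Overall accuracy is trace/total; kappa is the
chance-corrected agreement

    kappa = (p_o - p_e) / (1 - p_e),
    p_o   = trace / n,
    p_e   = sum_i rowsum_i * colsum_i / n**2.

Per-class producer's accuracy (recall, diagonal/rowsum) and user's accuracy
(precision, diagonal/colsum) are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .raster import CLASS_NAMES, CODE_TO_CLASS, ClassMap

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "build_confusion",
    "overall_accuracy",
    "cohen_kappa",
    "assess",
    "sample_classmap",
]


@dataclass
class ConfusionMatrix:
    """Square count matrix; ``counts[i, j]`` = reference class i, predicted j."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts must be {k}x{k} for class order {self.class_order}, "
                f"got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class AccuracyReport:
    overall_accuracy: float
    kappa: float
    producers_accuracy: dict[str, float]
    users_accuracy: dict[str, float]
    n: int
    matrix: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        d = {
            "overall_accuracy": self.overall_accuracy,
            "kappa": self.kappa,
            "producers_accuracy": self.producers_accuracy,
            "users_accuracy": self.users_accuracy,
            "n": self.n,
        }
        if self.matrix is not None:
            d["class_order"] = list(self.matrix.class_order)
            d["counts"] = self.matrix.counts.tolist()
        return d


def build_confusion(
    reference: Sequence[str],
    predicted: Sequence[str],
    class_order: Sequence[str] = CLASS_NAMES,
) -> ConfusionMatrix:
    """Count (reference, predicted) label pairs into a square matrix."""
    if len(reference) != len(predicted):
        raise ValueError(
            f"reference ({len(reference)}) and predicted ({len(predicted)}) "
            "label lists differ in length"
        )
    order = tuple(class_order)
    idx = {c: i for i, c in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=np.int64)
    for r, p in zip(reference, predicted):
        if r not in idx:
            raise ValueError(f"unknown reference label {r!r}; classes are {order}")
        if p not in idx:
            raise ValueError(f"unknown predicted label {p!r}; classes are {order}")
        counts[idx[r], idx[p]] += 1
    return ConfusionMatrix(counts, order)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples, trace/total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement; undefined when expected agreement is 1."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / n
    p_e = float(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)) / n**2
    if p_e >= 1.0:
        raise ValueError(
            "kappa is undefined: expected agreement is 1 "
            "(all samples in a single class on both axes)"
        )
    return float((p_o - p_e) / (1.0 - p_e))


def assess(cm: ConfusionMatrix) -> AccuracyReport:
    """Full accuracy report from a confusion matrix."""
    diag = np.diag(cm.counts).astype(float)
    rowsum = cm.counts.sum(axis=1).astype(float)
    colsum = cm.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prod = np.where(rowsum > 0, diag / rowsum, np.nan)
        user = np.where(colsum > 0, diag / colsum, np.nan)
    return AccuracyReport(
        overall_accuracy=overall_accuracy(cm),
        kappa=cohen_kappa(cm),
        producers_accuracy=dict(zip(cm.class_order, prod.tolist())),
        users_accuracy=dict(zip(cm.class_order, user.tolist())),
        n=cm.total,
        matrix=cm,
    )


def sample_classmap(
    classmap: ClassMap, x: np.ndarray, y: np.ndarray
) -> list[str | None]:
    """Predicted class at each ground point, by nearest pixel center.

    Points outside the grid or on nodata pixels yield ``None``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    rows, cols = classmap.georef.rowcol_of(x, y)
    nr, nc = classmap.shape
    out: list[str | None] = []
    for r, c in zip(rows, cols):
        if 0 <= r < nr and 0 <= c < nc:
            name = CODE_TO_CLASS[int(classmap.labels[r, c])]
            out.append(None if name == "nodata" else name)
        else:
            out.append(None)
    return out
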