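"""Confusion-matrix metrics and per-class spectral statistics.

Overall accuracy (OA) is the share of test pixels classified correctly.
Producer accuracy (PA) is defined here as the diagonal count of a class
divided by the total number of pixels *classified to* that class — a
column normalization.  Note that this column-based quantity is what most
remote-sensing texts call user's accuracy (precision); the name PA is
kept for consistency with the benchmark protocol this package follows,
and the discrepancy is deliberate and documented.

Unlabeled (label 0) pixels are excluded from every metric; they appear
only in rendered maps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .hsi_io import GroundTruth, HSICube

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "overall_accuracy",
    "producer_accuracy",
    "class_spectral_stats",
]


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, M: int) -> np.ndarray:
    """M×M count matrix; entry (i, j) = pixels of true class i+1 predicted j+1."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label arrays differ in length")
    if y_true.size == 0:
        return np.zeros((M, M), dtype=int)
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        if arr.min() < 1 or arr.max() > M:
            raise ValueError(f"{name} labels must lie in 1..{M}")
    return _sk_confusion(y_true, y_pred, labels=np.arange(1, M + 1))


def overall_accuracy(confusion: np.ndarray) -> float:
    """Correctly classified pixels over all scored pixels (trace / total)."""
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(confusion) / total)


def producer_accuracy(confusion: np.ndarray) -> np.ndarray:
    """Per-class diagonal over column sum; an empty column yields 0 with a warning."""
    confusion = np.asarray(confusion, dtype=float)
    col = confusion.sum(axis=0)
    empty = col == 0
    if np.any(empty):
        classes = (np.nonzero(empty)[0] + 1).tolist()
        warnings.warn(
            f"no pixel was classified to class(es) {classes}; their producer accuracy is reported as 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(empty, 0.0, np.diag(confusion) / np.where(empty, 1.0, col))
    return pa


@dataclass
class EvalReport:
    """Confusion matrix with OA and per-class PA, serializable to JSON/CSV."""

    confusion: np.ndarray
    class_names: list[str]
    oa: float = field(init=False)
    pa: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion)
        if self.confusion.ndim != 2 or self.confusion.shape[0] != self.confusion.shape[1]:
            raise ValueError("confusion matrix must be square")
        if len(self.class_names) != self.confusion.shape[0]:
            raise ValueError("class_names length must match the confusion matrix")
        self.oa = overall_accuracy(self.confusion)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.pa = producer_accuracy(self.confusion)

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray, class_names: Sequence[str]
    ) -> "EvalReport":
        conf = confusion_matrix(y_true, y_pred, len(class_names))
        return cls(conf, list(class_names))

    @property
    def n_test(self) -> int:
        return int(self.confusion.sum())

    def to_frame(self) -> pd.DataFrame:
        """One row per class (name, n, PA), in the layout of the PA tables."""
        return pd.DataFrame(
            {
                "class": self.class_names,
                "n_true": self.confusion.sum(axis=1),
                "n_predicted": self.confusion.sum(axis=0),
                "producer_accuracy": self.pa,
            }
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "overall_accuracy": self.oa,
            "n_test": self.n_test,
            "class_names": self.class_names,
            "producer_accuracy": self.pa.tolist(),
            "confusion": self.confusion.tolist(),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        frame = self.to_frame()
        with open(path, "w") as fh:
            frame.to_csv(fh, index=False)
            fh.write(f"# overall_accuracy,{self.oa}\n")
        return path


def class_spectral_stats(
    cube: HSICube, gt: GroundTruth
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class per-band mean and population standard deviation.

    Returns (means, stds), each of shape (M, bands).  A class with no
    labeled pixel is skipped with a warning; its rows are NaN.
    """
    if gt.labels.shape != (cube.rows, cube.cols):
        raise ValueError("ground truth shape does not match the cube")
    M = gt.n_classes
    means = np.full((M, cube.n_bands), np.nan)
    stds = np.full((M, cube.n_bands), np.nan)
    for cls in range(1, M + 1):
        rr, cc = np.nonzero(gt.labels == cls)
        if rr.size == 0:
            warnings.warn(f"class {cls} has no labeled pixels; skipped", stacklevel=2)
            continue
        spectra = cube.values[rr, cc, :].astype(float)
        means[cls - 1] = spectra.mean(axis=0)
        stds[cls - 1] = spectra.std(axis=0)
    return means, stds
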