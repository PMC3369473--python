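"""Shared classifier plumbing: labeled samples, dataset stacking and
train-fold standardization."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "LabeledSample",
    "DegenerateTrainingError",
    "Standardizer",
    "stack_dataset",
    "check_two_classes",
]

LABELS = (-1, 1)


class DegenerateTrainingError(ValueError):
    """Training data contained fewer than two classes."""


@dataclass
class LabeledSample:
    """A feature vector paired with a binary label (+1/-1) under a named
    labeling scheme."""

    x: np.ndarray
    y: int
    scheme: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.y not in LABELS:
            raise ValueError(f"label must be -1 or +1, got {self.y!r}")


def stack_dataset(
    data: Iterable[LabeledSample],
) -> Tuple[np.ndarray, np.ndarray]:
    """Stack samples into ``(X, y)`` arrays."""
    samples = list(data)
    if not samples:
        raise ValueError("empty dataset")
    X = np.vstack([s.x for s in samples])
    y = np.array([s.y for s in samples], dtype=np.int64)
    return X, y


def check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError(
            "training data must contain both classes")


@dataclass
class Standardizer:
    """Per-feature affine map to zero mean / unit variance, fitted on
    training data.  Constant features are left centered only."""

    mean: Optional[np.ndarray] = None
    scale: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.scale = np.where(sd == 0, 1.0, sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("standardizer not fitted")
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.scale

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(
            mean=np.asarray(d["mean"], dtype=np.float64),
            scale=np.asarray(d["scale"], dtype=np.float64),
        )
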