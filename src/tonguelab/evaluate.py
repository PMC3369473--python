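"""Evaluation metrics and 3-fold cross-validation.

Class +1 (C1) is the positive class for confusion counts.  The headline
metrics are classification accuracy (CA, percent) and the class-size
weighted average F-measure.  Cross-validation uses stratified folds with
a fixed seed; fold confusion counts are pooled per class before the
weighted F is computed, and per-fold reports are kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import predict as _dispatch_predict

__all__ = [
    "FoldResult",
    "EvaluationReport",
    "StratificationError",
    "confusion_counts",
    "precision",
    "recall",
    "f_measure",
    "weighted_f_measure",
    "classification_accuracy",
    "report_from_predictions",
    "cross_validate",
]


class StratificationError(ValueError):
    """A class has too few members for the requested number of folds."""


def confusion_counts(predicted: Sequence[int], truth: Sequence[int]):
    """(tp, tn, fp, fn) with +1 as the positive class."""
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predicted/truth must be equal-length, non-empty")
    tp = int(np.sum((p == 1) & (t == 1)))
    tn = int(np.sum((p == -1) & (t == -1)))
    fp = int(np.sum((p == 1) & (t == -1)))
    fn = int(np.sum((p == -1) & (t == 1)))
    return tp, tn, fp, fn


def precision(tp: int, fp: int) -> float:
    return tp / (tp + fp) if (tp + fp) > 0 else 0.0


def recall(tp: int, fn: int) -> float:
    return tp / (tp + fn) if (tp + fn) > 0 else 0.0


def f_measure(tp: int, fp: int, fn: int) -> float:
    """Harmonic mean of precision and recall; 0 on any 0/0."""
    p = precision(tp, fp)
    r = recall(tp, fn)
    return 2.0 * r * p / (r + p) if (r + p) > 0 else 0.0


def weighted_f_measure(
    f_c1: float, f_c2: float, n_c1: int, n_c2: int
) -> float:
    """Class-size weighted average of the two per-class F-measures."""
    total = n_c1 + n_c2
    if total < 1:
        raise ValueError("need at least one instance")
    return (n_c1 * f_c1 + n_c2 * f_c2) / total


def classification_accuracy(tp: int, tn: int, n: int) -> float:
    """Percentage of correctly classified instances."""
    return 100.0 * (tp + tn) / n


@dataclass
class FoldResult:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_c1(self) -> int:
        return self.tp + self.fn

    @property
    def n_c2(self) -> int:
        return self.tn + self.fp

    @property
    def f_c1(self) -> float:
        return f_measure(self.tp, self.fp, self.fn)

    @property
    def f_c2(self) -> float:
        # C2 as the positive class: swap the roles of the counts
        return f_measure(self.tn, self.fn, self.fp)

    @property
    def weighted_f(self) -> float:
        return weighted_f_measure(
            self.f_c1, self.f_c2, self.n_c1, self.n_c2)

    @property
    def ca(self) -> float:
        return classification_accuracy(self.tp, self.tn, self.n)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "precision_c1": precision(self.tp, self.fp),
            "recall_c1": recall(self.tp, self.fn),
            "f_c1": self.f_c1, "f_c2": self.f_c2,
            "weighted_f": self.weighted_f, "ca": self.ca,
        }


@dataclass
class EvaluationReport:
    """Pooled confusion counts plus per-fold breakdowns."""

    pooled: FoldResult
    per_fold: List[FoldResult] = field(default_factory=list)

    @property
    def weighted_f(self) -> float:
        return self.pooled.weighted_f

    @property
    def ca(self) -> float:
        return self.pooled.ca

    @property
    def mean_fold_ca(self) -> float:
        return float(np.mean([f.ca for f in self.per_fold])) \
            if self.per_fold else self.ca

    def to_dict(self) -> dict:
        return {
            "pooled": self.pooled.to_dict(),
            "weighted_f": self.weighted_f,
            "ca": self.ca,
            "mean_fold_ca": self.mean_fold_ca,
            "per_fold": [f.to_dict() for f in self.per_fold],
        }


def report_from_predictions(predicted, truth) -> EvaluationReport:
    tp, tn, fp, fn = confusion_counts(predicted, truth)
    return EvaluationReport(pooled=FoldResult(tp, tn, fp, fn))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    trainer: Callable[[np.ndarray, np.ndarray], object],
    n_folds: int = 3,
    seed: int = 0,
    predict_fn: Optional[Callable] = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation.

    Each fold is tested once with the remaining folds as training data.
    ``trainer`` maps ``(X_train, y_train)`` to a model; ``predict_fn``
    (default: type-dispatched package predictor) maps ``(model, X_test)``
    to labels.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if predict_fn is None:
        predict_fn = _dispatch_predict
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < n_folds:
        raise StratificationError(
            f"every class needs >= {n_folds} members for "
            f"{n_folds}-fold stratified CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds: List[FoldResult] = []
    for train_idx, test_idx in skf.split(X, y):
        model = trainer(X[train_idx], y[train_idx])
        pred = predict_fn(model, X[test_idx])
        tp, tn, fp, fn = confusion_counts(pred, y[test_idx])
        folds.append(FoldResult(tp, tn, fp, fn))
    pooled = FoldResult(
        tp=sum(f.tp for f in folds),
        tn=sum(f.tn for f in folds),
        fp=sum(f.fp for f in folds),
        fn=sum(f.fn for f in folds),
    )
    return EvaluationReport(pooled=pooled, per_fold=folds)
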