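"""Binary classifiers: boosted trees, SMO-trained SVM, and an MLP."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Tuple

import numpy as np

from .base import (
    DegenerateTrainingError,
    LabeledSample,
    Standardizer,
    check_two_classes,
    stack_dataset,
)
from .adaboost import AdaBoostModel, predict_adaboost, train_adaboost
from .mlp import DivergenceError, MlpModel, predict_mlp, train_mlp
from .svm import SvmModel, poly_kernel, predict_svm, train_svm
from .tree import DecisionTree, fit_tree

__all__ = [
    "LabeledSample", "Standardizer", "stack_dataset", "check_two_classes",
    "DegenerateTrainingError", "DivergenceError",
    "AdaBoostModel", "train_adaboost", "predict_adaboost",
    "SvmModel", "train_svm", "predict_svm", "poly_kernel",
    "MlpModel", "train_mlp", "predict_mlp",
    "DecisionTree", "fit_tree",
    "CLASSIFIER_NAMES", "make_trainer", "predict",
    "save_model", "load_model",
]

CLASSIFIER_NAMES = ("adaboost", "svm", "mlp")

_PREDICTORS = {
    AdaBoostModel: predict_adaboost,
    SvmModel: predict_svm,
    MlpModel: predict_mlp,
}


def predict(model, X: np.ndarray) -> np.ndarray:
    """Dispatch prediction on the model type."""
    for klass, fn in _PREDICTORS.items():
        if isinstance(model, klass):
            return fn(model, X)
    raise TypeError(f"unknown model type {type(model).__name__}")


def make_trainer(
    name: str, seed: int = 0, **hyper
) -> Callable[[np.ndarray, np.ndarray], object]:
    """A ``(X, y) -> model`` callable for one of the named classifiers,
    suitable for cross-validation."""
    if name == "adaboost":
        return lambda X, y: train_adaboost(X, y, seed=seed, **hyper)
    if name == "svm":
        return lambda X, y: train_svm(X, y, seed=seed, **hyper)
    if name == "mlp":
        return lambda X, y: train_mlp(X, y, seed=seed, **hyper)
    raise ValueError(
        f"unknown classifier {name!r}; expected one of {CLASSIFIER_NAMES}")


def save_model(model, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path):
    d = json.loads(Path(path).read_text())
    fmt = d.get("format", "")
    if fmt.startswith("tonguelab-adaboost/"):
        return AdaBoostModel.from_dict(d)
    if fmt.startswith("tonguelab-svm/"):
        return SvmModel.from_dict(d)
    if fmt.startswith("tonguelab-mlp/"):
        return MlpModel.from_dict(d)
    raise ValueError(f"unrecognized model document format {fmt!r}")
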