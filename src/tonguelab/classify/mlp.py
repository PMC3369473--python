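"""Single-hidden-layer perceptron with sigmoid hidden units and a
two-unit softmax output, trained by full-batch backpropagation on the
cross-entropy loss.

Output unit 0 corresponds to class +1 and unit 1 to class -1; prediction
is the argmax with ties broken to +1.  Training is deterministic given
the seed (initialization is the only source of randomness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .base import Standardizer, check_two_classes

__all__ = ["MlpModel", "train_mlp", "predict_mlp"]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss; reduce the learning rate."""


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class MlpModel:
    W1: np.ndarray  # (d, h)
    b1: np.ndarray  # (h,)
    W2: np.ndarray  # (h, 2)
    b2: np.ndarray  # (2,)
    lr: float
    epochs: int
    seed: int
    standardizer: Optional[Standardizer] = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities (columns: +1, -1); rows sum to 1."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.W1.shape[0]:
            raise ValueError(
                f"expected {self.W1.shape[0]} features, got {X.shape[1]}")
        if self.standardizer is not None:
            X = self.standardizer.transform(X)
        hidden = _sigmoid(X @ self.W1 + self.b1)
        return _softmax(hidden @ self.W2 + self.b2)

    def to_dict(self) -> dict:
        return {
            "format": "tonguelab-mlp/1",
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "lr": self.lr, "epochs": self.epochs, "seed": self.seed,
            "standardizer": (
                self.standardizer.to_dict() if self.standardizer else None),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MlpModel":
        return cls(
            W1=np.asarray(d["W1"]), b1=np.asarray(d["b1"]),
            W2=np.asarray(d["W2"]), b2=np.asarray(d["b2"]),
            lr=d["lr"], epochs=d["epochs"], seed=d["seed"],
            standardizer=(
                Standardizer.from_dict(d["standardizer"])
                if d["standardizer"] else None),
        )


def default_hidden_units(n_features: int) -> int:
    return math.ceil((n_features + 2) / 2)


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    hidden_units: Optional[int] = None,
    lr: float = 0.01,
    epochs: int = 500,
    seed: int = 0,
    momentum: float = 0.9,
    standardize: bool = True,
) -> MlpModel:
    """Full-batch gradient descent (with classical momentum) on the mean
    cross-entropy of the softmax outputs."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    check_two_classes(y)
    if hidden_units is None:
        hidden_units = default_hidden_units(X.shape[1])
    if hidden_units < 1:
        raise ValueError("hidden_units must be >= 1")

    std = None
    if standardize:
        std = Standardizer().fit(X)
        X = std.transform(X)

    n, d = X.shape
    # one-hot targets, column 0 <-> +1
    T = np.column_stack([(y == 1).astype(float), (y == -1).astype(float)])

    rng = np.random.default_rng(seed)
    W1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, hidden_units))
    b1 = np.zeros(hidden_units)
    W2 = rng.normal(0.0, 1.0 / np.sqrt(hidden_units),
                    size=(hidden_units, 2))
    b2 = np.zeros(2)
    vel = [np.zeros_like(p) for p in (W1, b1, W2, b2)]

    for _ in range(epochs):
        hidden = _sigmoid(X @ W1 + b1)
        probs = _softmax(hidden @ W2 + b2)
        loss = -np.mean(np.sum(T * np.log(probs + 1e-300), axis=1))
        if not np.isfinite(loss):
            raise DivergenceError(
                "non-finite training loss; try a smaller learning rate")
        delta2 = (probs - T) / n
        gW2 = hidden.T @ delta2
        gb2 = delta2.sum(axis=0)
        delta1 = (delta2 @ W2.T) * hidden * (1.0 - hidden)
        gW1 = X.T @ delta1
        gb1 = delta1.sum(axis=0)
        for p, v, g in zip((W1, b1, W2, b2), vel, (gW1, gb1, gW2, gb2)):
            v *= momentum
            v -= lr * g
            p += v

    return MlpModel(W1=W1, b1=b1, W2=W2, b2=b2, lr=lr, epochs=epochs,
                    seed=seed, standardizer=std)


def predict_mlp(model: MlpModel, X: np.ndarray) -> np.ndarray:
    """argmax of the softmax outputs; exact ties break to +1."""
    probs = model.forward(X)
    return np.where(probs[:, 0] >= probs[:, 1], 1, -1).astype(np.int64)
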