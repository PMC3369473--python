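"""Polynomial-kernel support vector machine trained with sequential
minimal optimization (pairwise coordinate ascent on the dual).

The decision value of an instance is
``f(x) = sum_i y_i alpha_i k(x_i, x) + b`` with
``k(x, z) = (x . z + coef)^degree``.  Labels are the sign of f (0 breaks
to +1).  Features are standardized on the training fold by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .base import Standardizer, check_two_classes

__all__ = ["SvmModel", "train_svm", "predict_svm", "poly_kernel"]


def poly_kernel(
    A: np.ndarray, B: np.ndarray, degree: int = 1, coef: float = 1.0
) -> np.ndarray:
    """Gram matrix (x . z + coef)^degree between row sets A and B."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    return (A @ B.T + coef) ** degree


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class SvmModel:
    X: np.ndarray          # training inputs (standardized if enabled)
    y: np.ndarray
    alpha: np.ndarray      # Lagrange multipliers, 0 <= alpha_i <= C
    b: float
    C: float
    degree: int
    coef: float
    tol: float
    standardizer: Optional[Standardizer] = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.X.shape[1]:
            raise ValueError(
                f"expected {self.X.shape[1]} features, got {X.shape[1]}")
        if self.standardizer is not None:
            X = self.standardizer.transform(X)
        sv = self.alpha > 0
        if not sv.any():
            return np.full(X.shape[0], self.b)
        K = poly_kernel(X, self.X[sv], self.degree, self.coef)
        return K @ (self.y[sv] * self.alpha[sv]) + self.b

    def to_dict(self) -> dict:
        return {
            "format": "tonguelab-svm/1",
            "X": self.X.tolist(),
            "y": self.y.tolist(),
            "alpha": self.alpha.tolist(),
            "b": float(self.b),
            "C": float(self.C),
            "degree": int(self.degree),
            "coef": float(self.coef),
            "tol": float(self.tol),
            "standardizer": (
                self.standardizer.to_dict() if self.standardizer else None),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SvmModel":
        return cls(
            X=np.asarray(d["X"], dtype=np.float64),
            y=np.asarray(d["y"], dtype=np.int64),
            alpha=np.asarray(d["alpha"], dtype=np.float64),
            b=d["b"], C=d["C"], degree=d["degree"], coef=d["coef"],
            tol=d["tol"],
            standardizer=(
                Standardizer.from_dict(d["standardizer"])
                if d["standardizer"] else None),
        )


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    degree: int = 1,
    coef: float = 1.0,
    tol: float = 1e-3,
    max_passes: int = 10,
    max_iter: int = 2000,
    seed: int = 0,
    standardize: bool = True,
) -> SvmModel:
    """Simplified SMO: sweep samples, pick KKT violators, optimize each
    against a random partner analytically; stop after ``max_passes``
    consecutive sweeps without an update.

    Emits a :class:`ConvergenceWarning` and returns the best iterate if
    ``max_iter`` sweeps elapse first.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    check_two_classes(y)
    rng = np.random.default_rng(seed)

    std = None
    if standardize:
        std = Standardizer().fit(X)
        X = std.transform(X)

    n = len(y)
    K = poly_kernel(X, X, degree, coef)
    alpha = np.zeros(n)
    b = 0.0

    def f(i: int) -> float:
        return float((alpha * y) @ K[:, i] + b)

    passes = 0
    sweeps = 0
    while passes < max_passes:
        if sweeps >= max_iter:
            warnings.warn(
                f"SMO did not converge within {max_iter} sweeps; "
                "returning best iterate", ConvergenceWarning)
            break
        sweeps += 1
        changed = 0
        for i in range(n):
            Ei = f(i) - y[i]
            if not ((y[i] * Ei < -tol and alpha[i] < C)
                    or (y[i] * Ei > tol and alpha[i] > 0)):
                continue
            j = int(rng.integers(n - 1))
            if j >= i:
                j += 1
            Ej = f(j) - y[j]
            ai_old, aj_old = alpha[i], alpha[j]
            if y[i] != y[j]:
                L = max(0.0, aj_old - ai_old)
                H = min(C, C + aj_old - ai_old)
            else:
                L = max(0.0, ai_old + aj_old - C)
                H = min(C, ai_old + aj_old)
            if L >= H:
                continue
            eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
            if eta >= 0:
                continue
            aj = aj_old - y[j] * (Ei - Ej) / eta
            aj = min(H, max(L, aj))
            if abs(aj - aj_old) < 1e-7:
                continue
            ai = ai_old + y[i] * y[j] * (aj_old - aj)
            alpha[i], alpha[j] = ai, aj
            b1 = b - Ei - y[i] * (ai - ai_old) * K[i, i] \
                - y[j] * (aj - aj_old) * K[i, j]
            b2 = b - Ej - y[i] * (ai - ai_old) * K[i, j] \
                - y[j] * (aj - aj_old) * K[j, j]
            if 0 < ai < C:
                b = b1
            elif 0 < aj < C:
                b = b2
            else:
                b = 0.5 * (b1 + b2)
            changed += 1
        passes = passes + 1 if changed == 0 else 0

    return SvmModel(X=X, y=y, alpha=alpha, b=b, C=C, degree=degree,
                    coef=coef, tol=tol, standardizer=std)


def predict_svm(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """sign(f(x)); zero decision value breaks to +1."""
    return np.where(
        model.decision_function(X) >= 0, 1, -1).astype(np.int64)
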