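"""Adaptive boosting of depth-limited decision trees.

Training keeps a distribution D_t over samples (initially uniform), fits
a weak tree on it each round, weights the tree by
``alpha_t = 0.5 * ln((1 - eps_t) / eps_t)`` and re-weights samples
multiplicatively (up for mistakes, down for hits), renormalizing by Z_t.
Rounds with weighted error >= 1/2 terminate training unstored; a perfect
round (eps = 0) is stored with eps clamped to 1e-10 and then terminates
training.  The ensemble predicts ``sign(sum_t alpha_t h_t(x))`` with 0
mapped to +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .base import DegenerateTrainingError, check_two_classes
from .tree import DecisionTree, fit_tree

__all__ = ["AdaBoostModel", "train_adaboost", "predict_adaboost"]

_EPS_CLAMP = 1e-10


@dataclass
class AdaBoostModel:
    rounds: List[Tuple[DecisionTree, float]]
    T: int
    depth: int
    n_features: int
    #: normalization factor of each stored round (sum of unnormalized
    #: updated weights); prod(zs) bounds the training error
    zs: List[float] = field(default_factory=list)
    #: D_t snapshots (one per stored round, pre-update), kept for
    #: diagnostics; small relative to the data
    weight_history: List[np.ndarray] = field(default_factory=list)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}")
        score = np.zeros(X.shape[0])
        for tree, alpha in self.rounds:
            score += alpha * tree.predict(X)
        return score

    def to_dict(self) -> dict:
        return {
            "format": "tonguelab-adaboost/1",
            "T": self.T,
            "depth": self.depth,
            "n_features": self.n_features,
            "zs": [float(z) for z in self.zs],
            "rounds": [
                {"alpha": float(a), "tree": t.to_dict()}
                for t, a in self.rounds
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AdaBoostModel":
        return cls(
            rounds=[
                (DecisionTree.from_dict(r["tree"]), r["alpha"])
                for r in d["rounds"]
            ],
            T=d["T"],
            depth=d["depth"],
            n_features=d["n_features"],
            zs=list(d["zs"]),
        )


def train_adaboost(
    X: np.ndarray,
    y: np.ndarray,
    T: int = 50,
    depth: int = 1,
    seed: int = 0,
) -> AdaBoostModel:
    """Boost up to ``T`` weak trees.  ``seed`` is accepted for interface
    uniformity; the procedure is fully deterministic."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if T < 1:
        raise ValueError("T must be >= 1")
    check_two_classes(y)
    n = len(y)
    D = np.full(n, 1.0 / n)
    model = AdaBoostModel(rounds=[], T=T, depth=depth,
                          n_features=X.shape[1])
    for _ in range(T):
        tree = fit_tree(X, y, D, depth=depth)
        pred = tree.predict(X)
        eps = float(np.sum(D[pred != y]))
        if eps >= 0.5:
            break
        perfect = eps <= 0.0
        eps = max(eps, _EPS_CLAMP)
        alpha = 0.5 * np.log((1.0 - eps) / eps)
        model.weight_history.append(D.copy())
        unnorm = D * np.exp(-alpha * y * pred)
        z = float(unnorm.sum())
        model.rounds.append((tree, alpha))
        model.zs.append(z)
        if perfect:
            break
        D = unnorm / z
    if not model.rounds:
        # first weak learner already at chance: keep it with zero weight?
        # No -- signal that boosting could not start.
        raise DegenerateTrainingError(
            "first weak hypothesis had weighted error >= 1/2")
    return model


def predict_adaboost(model: AdaBoostModel, X: np.ndarray) -> np.ndarray:
    """Weighted-majority label; a zero score breaks to +1."""
    score = model.decision_scores(X)
    return np.where(score >= 0, 1, -1).astype(np.int64)
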