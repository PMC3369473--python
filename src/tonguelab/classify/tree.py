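"""Depth-limited weighted decision tree, the boosting base learner.

Self-contained so that fitted trees serialize exactly to JSON.  Splits
minimize weighted Gini impurity; leaves predict the weighted-majority
label with ties broken to +1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["DecisionTree", "fit_tree"]


@dataclass
class _Node:
    label: int = 1
    feature: Optional[int] = None
    threshold: float = 0.0
    left: Optional["_Node"] = None
    right: Optional["_Node"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"label": int(self.label)}
        return {
            "feature": int(self.feature),
            "threshold": float(self.threshold),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Node":
        if "feature" not in d:
            return cls(label=d["label"])
        return cls(
            feature=d["feature"],
            threshold=d["threshold"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


def _leaf(y: np.ndarray, w: np.ndarray) -> _Node:
    score = float(np.sum(w * y))
    return _Node(label=1 if score >= 0 else -1)


def _best_split(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Return (impurity, feature, threshold) of the best weighted-Gini
    split, or None when no feature admits one."""
    total_pos = float(np.sum(w[y == 1]))
    total_neg = float(np.sum(w[y == -1]))
    best = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        boundaries = np.flatnonzero(np.diff(xs) > 0)
        if boundaries.size == 0:
            continue
        wp = np.cumsum(w[order] * (y[order] == 1))[boundaries]
        wn = np.cumsum(w[order] * (y[order] == -1))[boundaries]
        wl = wp + wn
        wr = (total_pos + total_neg) - wl
        with np.errstate(invalid="ignore", divide="ignore"):
            gl = 1.0 - (wp / wl) ** 2 - (wn / wl) ** 2
            gr = 1.0 - ((total_pos - wp) / wr) ** 2 \
                - ((total_neg - wn) / wr) ** 2
        imp = np.where((wl > 0) & (wr > 0), wl * gl + wr * gr, np.inf)
        k = int(np.argmin(imp))
        if best is None or imp[k] < best[0] - 1e-15:
            thr = 0.5 * (xs[boundaries[k]] + xs[boundaries[k] + 1])
            best = (float(imp[k]), j, thr)
    return best


def _grow(X, y, w, depth) -> _Node:
    if depth == 0 or len(np.unique(y)) < 2:
        return _leaf(y, w)
    split = _best_split(X, y, w)
    if split is None:
        return _leaf(y, w)
    _, j, thr = split
    mask = X[:, j] <= thr
    node = _Node(feature=j, threshold=thr)
    node.left = _grow(X[mask], y[mask], w[mask], depth - 1)
    node.right = _grow(X[~mask], y[~mask], w[~mask], depth - 1)
    return node


@dataclass
class DecisionTree:
    root: _Node
    depth: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        out = np.empty(X.shape[0], dtype=np.int64)
        idx = np.arange(X.shape[0])
        stack = [(self.root, idx)]
        while stack:
            node, rows = stack.pop()
            if rows.size == 0:
                continue
            if node.is_leaf:
                out[rows] = node.label
                continue
            mask = X[rows, node.feature] <= node.threshold
            stack.append((node.left, rows[mask]))
            stack.append((node.right, rows[~mask]))
        return out

    def to_dict(self) -> dict:
        return {"depth": self.depth, "root": self.root.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        return cls(root=_Node.from_dict(d["root"]), depth=d["depth"])


def fit_tree(
    X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray, depth: int = 1
) -> DecisionTree:
    """Fit a depth-limited weighted tree.  Deterministic: no randomness is
    used anywhere in the split search."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    w = np.asarray(sample_weight, dtype=np.float64)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return DecisionTree(root=_grow(X, y, w, depth), depth=depth)
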