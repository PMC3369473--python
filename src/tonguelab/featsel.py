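"""Feature ranking by information gain and subset selection by
best-first search.

Continuous features are discretized per feature with MDL-guided
recursive binary splitting (cut points maximize class-entropy gain; a
split is kept only when the gain clears the minimum-description-length
cost).  Information gain is then H(labels) - H(labels | bins).

Subset search is forward best-first: expand the best unexpanded subset
by single-feature additions, keep every scored subset on a priority
list, and stop after ``stale_limit`` consecutive expansions that fail to
improve the best merit.  The default subset evaluator is the
correlation-based merit ``k * r_cf / sqrt(k + k(k-1) * r_ff)``; any
callable mapping an index tuple to a score can be substituted (e.g. a
cross-validation wrapper).
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FeatureRanking",
    "SelectedSubset",
    "entropy",
    "mdl_cut_points",
    "information_gain",
    "information_gain_rank",
    "cfs_merit",
    "best_first_select",
    "exhaustive_select",
]


def entropy(y: np.ndarray) -> float:
    """Shannon entropy (bits) of a label sequence."""
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _split_gain(y: np.ndarray, left: np.ndarray):
    n = len(y)
    n1 = int(left.sum())
    n2 = n - n1
    e = entropy(y)
    e1 = entropy(y[left])
    e2 = entropy(y[~left])
    gain = e - (n1 / n) * e1 - (n2 / n) * e2
    return gain, e, e1, e2


def _mdl_accepts(y, left, gain, e, e1, e2) -> bool:
    n = len(y)
    k = len(np.unique(y))
    k1 = len(np.unique(y[left]))
    k2 = len(np.unique(y[~left]))
    delta = np.log2(3.0 ** k - 2.0) - (k * e - k1 * e1 - k2 * e2)
    return gain > (np.log2(n - 1) + delta) / n


def _recurse_cuts(x: np.ndarray, y: np.ndarray, cuts: List[float]) -> None:
    n = len(y)
    if n < 2 or len(np.unique(y)) < 2:
        return
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    boundaries = np.flatnonzero(np.diff(xs) > 0)
    if boundaries.size == 0:
        return
    best = None
    for b in boundaries:
        left = np.zeros(n, dtype=bool)
        left[order[: b + 1]] = True
        gain, e, e1, e2 = _split_gain(y, left)
        if best is None or gain > best[0] + 1e-12:
            best = (gain, b, left, e, e1, e2)
    gain, b, left, e, e1, e2 = best
    if not _mdl_accepts(y, left, gain, e, e1, e2):
        return
    cut = 0.5 * (xs[b] + xs[b + 1])
    cuts.append(float(cut))
    _recurse_cuts(x[left], y[left], cuts)
    _recurse_cuts(x[~left], y[~left], cuts)


def mdl_cut_points(x: np.ndarray, y: np.ndarray) -> List[float]:
    """Sorted MDL-accepted binary cut points for one feature."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    cuts: List[float] = []
    _recurse_cuts(x, y, cuts)
    return sorted(cuts)


def information_gain(x: np.ndarray, y: np.ndarray) -> float:
    """H(y) - H(y | MDL-discretized x); 0 when no cut point survives."""
    cuts = mdl_cut_points(x, y)
    if not cuts:
        return 0.0
    bins = np.digitize(np.asarray(x, dtype=np.float64), cuts)
    n = len(y)
    cond = 0.0
    for b in np.unique(bins):
        sel = bins == b
        cond += (sel.sum() / n) * entropy(np.asarray(y)[sel])
    return float(entropy(y) - cond)


@dataclass
class FeatureRanking:
    """Per-feature information-gain scores and the descending order."""

    scores: np.ndarray
    order: np.ndarray

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


def information_gain_rank(X: np.ndarray, y: np.ndarray) -> FeatureRanking:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        warnings.warn("labels are constant; all information gains are 0")
        scores = np.zeros(X.shape[1])
    else:
        scores = np.array(
            [information_gain(X[:, j], y) for j in range(X.shape[1])])
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(scores=scores, order=order)


# ---------------------------------------------------------------------------
# Subset selection

def _abs_pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def cfs_merit(
    X: np.ndarray, y: np.ndarray, subset: Sequence[int]
) -> float:
    """Correlation-based subset merit: high mean feature-label
    correlation, low mean feature-feature correlation."""
    subset = list(subset)
    if not subset:
        return 0.0
    X = np.asarray(X, dtype=np.float64)
    yf = np.asarray(y, dtype=np.float64)
    k = len(subset)
    r_cf = float(np.mean([_abs_pearson(X[:, j], yf) for j in subset]))
    if k == 1:
        r_ff = 0.0
    else:
        pairs = [
            _abs_pearson(X[:, a], X[:, b])
            for a, b in itertools.combinations(subset, 2)
        ]
        r_ff = float(np.mean(pairs))
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


@dataclass
class SelectedSubset:
    indices: Tuple[int, ...]
    merit: float
    #: every evaluated subset and its score, in evaluation order
    trace: List[Tuple[Tuple[int, ...], float]] = field(default_factory=list)


def best_first_select(
    X: np.ndarray,
    y: np.ndarray,
    evaluator: Optional[Callable[[Sequence[int]], float]] = None,
    stale_limit: int = 5,
) -> SelectedSubset:
    """Forward best-first search over feature subsets."""
    X = np.asarray(X, dtype=np.float64)
    n_features = X.shape[1]
    if n_features < 2:
        raise ValueError("need at least 2 features to search over")
    if evaluator is None:
        evaluator = lambda subset: cfs_merit(X, y, subset)

    trace: List[Tuple[Tuple[int, ...], float]] = []
    scored: Dict[Tuple[int, ...], float] = {}

    def score(subset: Tuple[int, ...]) -> float:
        if subset not in scored:
            value = float(evaluator(subset))
            scored[subset] = value
            trace.append((subset, value))
        return scored[subset]

    start: Tuple[int, ...] = ()
    best_subset, best_merit = start, score(start)
    counter = itertools.count()
    open_heap = [(-best_merit, next(counter), start)]
    expanded = set()
    stale = 0

    while open_heap and stale <= stale_limit:
        _, _, subset = heapq.heappop(open_heap)
        if subset in expanded:
            continue
        expanded.add(subset)
        improved = False
        for j in range(n_features):
            if j in subset:
                continue
            child = tuple(sorted(subset + (j,)))
            if child in expanded:
                continue
            m = score(child)
            heapq.heappush(open_heap, (-m, next(counter), child))
            if m > best_merit + 1e-10:
                best_subset, best_merit = child, m
                improved = True
        stale = 0 if improved else stale + 1

    return SelectedSubset(
        indices=best_subset, merit=best_merit, trace=trace)


def exhaustive_select(
    X: np.ndarray,
    y: np.ndarray,
    evaluator: Optional[Callable[[Sequence[int]], float]] = None,
) -> SelectedSubset:
    """Brute-force optimum over all non-empty subsets (oracle for small
    feature counts)."""
    X = np.asarray(X, dtype=np.float64)
    n_features = X.shape[1]
    if n_features > 16:
        raise ValueError("exhaustive search limited to <= 16 features")
    if evaluator is None:
        evaluator = lambda subset: cfs_merit(X, y, subset)
    best_subset, best_merit = (), -np.inf
    trace = []
    for k in range(1, n_features + 1):
        for subset in itertools.combinations(range(n_features), k):
            m = float(evaluator(subset))
            trace.append((subset, m))
            if m > best_merit:
                best_subset, best_merit = subset, m
    return SelectedSubset(
        indices=best_subset, merit=best_merit, trace=trace)
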