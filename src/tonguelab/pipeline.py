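"""End-to-end experiment protocol: extract -> aggregate ->
cross-validate -> report, plus ranking and best-first selection.

An *experiment grid* evaluates every configured feature-vector variant
against every classifier for each region, reporting the weighted
F-measure and classification accuracy per cell, exactly the shape of a
results table.  The best cell maximizes weighted F with ties broken
toward SVM, then MLP, then AdaBoost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .aggregate import VARIANTS, aggregate_mean, aggregate_median, \
    aggregate_std
from .classify import CLASSIFIER_NAMES, make_trainer
from .colorspace import pixel_features
from .evaluate import EvaluationReport, cross_validate
from .featsel import best_first_select, information_gain_rank
from .region import DEFAULT_MIDDLE_FRACTIONS, RegionSpec, TongueImage, \
    region_pixels

__all__ = [
    "ExperimentConfig",
    "compute_aggregates",
    "variant_matrix",
    "run_experiment",
    "best_cell",
    "run_selection_comparison",
]

_TIE_ORDER = {"svm": 0, "mlp": 1, "adaboost": 2}


@dataclass
class ExperimentConfig:
    """The experiment grid and all knobs needed to reproduce a run."""

    region_kinds: Tuple[str, ...] = ("entire", "middle")
    variants: Tuple[str, ...] = VARIANTS
    classifiers: Tuple[str, ...] = CLASSIFIER_NAMES
    classifier_params: Dict[str, dict] = field(default_factory=dict)
    folds: int = 3
    seed: int = 0
    scheme: str = "zheng_hot_cold"
    feature_selection: bool = False
    stale_limit: int = 5
    middle_fractions: Tuple[float, float, float, float] = \
        DEFAULT_MIDDLE_FRACTIONS

    def __post_init__(self) -> None:
        for v in self.variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown variant {v!r}")
        for c in self.classifiers:
            if c not in CLASSIFIER_NAMES:
                raise ValueError(f"unknown classifier {c!r}")
        for r in self.region_kinds:
            if r not in ("entire", "middle"):
                raise ValueError(f"unknown region kind {r!r}")


def compute_aggregates(
    images: Sequence[TongueImage],
    region_kind: str,
    middle_fractions=DEFAULT_MIDDLE_FRACTIONS,
) -> Dict[str, np.ndarray]:
    """Per-image mean/median/std statistics of the 25 pixel features over
    one region; returns arrays of shape (n_images, 25)."""
    spec = RegionSpec(region_kind=region_kind,
                      middle_fractions=tuple(middle_fractions))
    means, medians, stds = [], [], []
    for img in images:
        feats = pixel_features(region_pixels(img, spec))
        means.append(aggregate_mean(feats))
        medians.append(aggregate_median(feats))
        stds.append(aggregate_std(feats))
    return {
        "mean": np.vstack(means),
        "median": np.vstack(medians),
        "std": np.vstack(stds),
    }


def variant_matrix(stats: Dict[str, np.ndarray], variant: str) -> np.ndarray:
    """Assemble the design matrix of one variant from precomputed stats."""
    if variant in ("mean", "median", "std"):
        return stats[variant]
    if variant == "mean_std":
        return np.hstack([stats["mean"], stats["std"]])
    if variant == "median_std":
        return np.hstack([stats["median"], stats["std"]])
    raise ValueError(f"unknown variant {variant!r}")


def _evaluate_cell(
    X: np.ndarray, y: np.ndarray, classifier: str, config: ExperimentConfig,
    feature_idx: Optional[Sequence[int]] = None,
) -> EvaluationReport:
    if feature_idx is not None:
        X = X[:, list(feature_idx)]
    trainer = make_trainer(
        classifier, seed=config.seed,
        **config.classifier_params.get(classifier, {}))
    return cross_validate(X, y, trainer, n_folds=config.folds,
                          seed=config.seed)


def run_experiment(
    images: Sequence[TongueImage],
    labels: Sequence[int],
    config: ExperimentConfig,
) -> pd.DataFrame:
    """Evaluate the full variant x classifier x region grid.

    Returns one row per cell with columns ``region``, ``variant``,
    ``classifier``, ``weighted_f``, ``ca``.  Deterministic per config
    seed.
    """
    y = np.asarray(labels, dtype=np.int64)
    rows = []
    for region in config.region_kinds:
        stats = compute_aggregates(images, region, config.middle_fractions)
        for variant in config.variants:
            X = variant_matrix(stats, variant)
            if config.feature_selection:
                subset = best_first_select(
                    X, y, stale_limit=config.stale_limit).indices
                idx = list(subset) if subset else None
            else:
                idx = None
            for classifier in config.classifiers:
                report = _evaluate_cell(X, y, classifier, config,
                                        feature_idx=idx)
                rows.append({
                    "region": region,
                    "variant": variant,
                    "classifier": classifier,
                    "weighted_f": report.weighted_f,
                    "ca": report.ca,
                })
    return pd.DataFrame(rows)


def best_cell(grid: pd.DataFrame) -> pd.Series:
    """Max weighted F; ties toward SVM, then MLP, then AdaBoost."""
    g = grid.copy()
    g["_tie"] = g["classifier"].map(_TIE_ORDER)
    g = g.sort_values(["weighted_f", "_tie"],
                      ascending=[False, True], kind="stable")
    return grid.loc[g.index[0]]


def run_selection_comparison(
    images: Sequence[TongueImage],
    labels: Sequence[int],
    config: ExperimentConfig,
) -> pd.Series:
    """Best grid cell with and without best-first feature selection,
    mirroring a selected-versus-whole-feature-set comparison row."""
    whole = best_cell(run_experiment(
        images, labels,
        ExperimentConfig(**{**config.__dict__, "feature_selection": False})))
    if config.feature_selection:
        selected = best_cell(run_experiment(images, labels, config))
    else:
        selected = whole
    return pd.Series({
        "scheme": config.scheme,
        "selected_weighted_f": selected["weighted_f"],
        "selected_ca": selected["ca"],
        "whole_weighted_f": whole["weighted_f"],
        "whole_ca": whole["ca"],
    })


def rank_features(X: np.ndarray, y: np.ndarray, names: Sequence[str]):
    """Information-gain ranking as a tidy frame (descending score)."""
    ranking = information_gain_rank(X, y)
    return pd.DataFrame({
        "feature_index": ranking.order,
        "feature_name": [names[i] for i in ranking.order],
        "score": ranking.scores[ranking.order],
    })
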