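"""Collapse per-pixel feature vectors over a region into one composite
vector per image.

Five variants: ``mean``, ``median``, ``std`` (25 components each) and the
concatenations ``mean_std`` and ``median_std`` (50 components, statistic
first, then the standard deviations).  The standard deviation is the
population form (1/N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .colorspace import FEATURE_NAMES, pixel_features
from .region import EmptyRegionError, RegionSpec, TongueImage, region_pixels

__all__ = [
    "VARIANTS",
    "AggregateFeatureVector",
    "aggregate_mean",
    "aggregate_median",
    "aggregate_std",
    "aggregate",
    "build_feature_vector",
    "variant_feature_names",
]

VARIANTS = ("mean", "median", "std", "mean_std", "median_std")

_STAT_PREFIX = {"mean": "mu", "median": "med", "std": "sigma"}


@dataclass
class AggregateFeatureVector:
    """One image/region's composite feature vector."""

    variant: str
    values: np.ndarray
    region_kind: str = "entire"
    sample_id: str = ""

    def __len__(self) -> int:
        return len(self.values)


def _check(features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2:
        raise ValueError("expected an (N, n_features) array")
    if features.shape[0] == 0:
        raise EmptyRegionError("cannot aggregate over zero pixels")
    return features


def aggregate_mean(features: np.ndarray) -> np.ndarray:
    """Component-wise arithmetic mean over pixels."""
    return _check(features).mean(axis=0)


def aggregate_median(features: np.ndarray) -> np.ndarray:
    """Component-wise median (even N: mean of the two central order
    statistics)."""
    return np.median(_check(features), axis=0)


def aggregate_std(features: np.ndarray) -> np.ndarray:
    """Component-wise population standard deviation sqrt(sum((f-mu)^2)/N)."""
    return _check(features).std(axis=0, ddof=0)


def aggregate(features: np.ndarray, variant: str) -> np.ndarray:
    if variant == "mean":
        return aggregate_mean(features)
    if variant == "median":
        return aggregate_median(features)
    if variant == "std":
        return aggregate_std(features)
    if variant == "mean_std":
        return np.concatenate(
            [aggregate_mean(features), aggregate_std(features)])
    if variant == "median_std":
        return np.concatenate(
            [aggregate_median(features), aggregate_std(features)])
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def build_feature_vector(
    img: TongueImage, spec: RegionSpec, variant: str
) -> AggregateFeatureVector:
    """Extract per-pixel features over the region and aggregate them."""
    feats = pixel_features(region_pixels(img, spec))
    return AggregateFeatureVector(
        variant=variant,
        values=aggregate(feats, variant),
        region_kind=spec.region_kind,
        sample_id=img.id,
    )


def variant_feature_names(variant: str) -> List[str]:
    """Column names like ``mu_F1_R`` / ``sigma_F9_YIQ_Q`` for a variant."""
    def block(stat: str) -> List[str]:
        prefix = _STAT_PREFIX[stat]
        return [
            f"{prefix}_F{i + 1}_{name}"
            for i, name in enumerate(FEATURE_NAMES)
        ]

    if variant in ("mean", "median", "std"):
        return block(variant)
    if variant == "mean_std":
        return block("mean") + block("std")
    if variant == "median_std":
        return block("median") + block("std")
    raise ValueError(f"unknown variant {variant!r}")
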