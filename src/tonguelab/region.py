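"""Analysis regions: the whole tongue foreground and a middle rectangle.

The middle rectangle approximates the central tongue area and is defined
by fractional coordinates of the foreground bounding box (half-open
integer ranges, ``floor(fraction * extent)`` offset from the box origin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Tuple

import numpy as np

__all__ = [
    "TongueImage",
    "RegionSpec",
    "EmptyRegionError",
    "bounding_box",
    "region_mask",
    "region_pixels",
]

RegionKind = Literal["entire", "middle"]

#: Default middle rectangle: central 30% of rows, central 40% of columns
#: of the foreground bounding box.
DEFAULT_MIDDLE_FRACTIONS = (0.35, 0.65, 0.30, 0.70)


class EmptyRegionError(ValueError):
    """A region specification selected no foreground pixels."""


@dataclass
class TongueImage:
    """An 8-bit RGB raster plus a binary foreground mask."""

    pixels: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray    # (H, W) bool
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError("pixels must have shape (H, W, 3)")
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask shape must match pixel grid")


@dataclass(frozen=True)
class RegionSpec:
    """Which pixels of a :class:`TongueImage` feed feature aggregation."""

    region_kind: RegionKind = "entire"
    middle_fractions: Tuple[float, float, float, float] = field(
        default=DEFAULT_MIDDLE_FRACTIONS)

    def __post_init__(self) -> None:
        if self.region_kind not in ("entire", "middle"):
            raise ValueError(f"unknown region kind {self.region_kind!r}")
        rlo, rhi, clo, chi = self.middle_fractions
        if not (0 <= rlo < rhi <= 1 and 0 <= clo < chi <= 1):
            raise ValueError(
                "middle fractions must satisfy 0 <= lo < hi <= 1 per axis")


def bounding_box(mask: np.ndarray) -> Tuple[int, int, int, int]:
    """Tight box over foreground pixels as half-open
    ``(row_min, row_max, col_min, col_max)``."""
    mask = np.asarray(mask).astype(bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyRegionError("mask has no foreground pixels")
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def middle_box(mask: np.ndarray, fractions=DEFAULT_MIDDLE_FRACTIONS):
    """Half-open sub-box of the foreground bounding box given fractional
    row/column limits."""
    r0, r1, c0, c1 = bounding_box(mask)
    h, w = r1 - r0, c1 - c0
    rlo, rhi, clo, chi = fractions
    return (
        r0 + int(np.floor(rlo * h)),
        r0 + int(np.floor(rhi * h)),
        c0 + int(np.floor(clo * w)),
        c0 + int(np.floor(chi * w)),
    )


def region_mask(img: TongueImage, spec: RegionSpec) -> np.ndarray:
    """Boolean mask of the pixels belonging to the requested region."""
    out = img.mask.copy()
    if spec.region_kind == "middle":
        r0, r1, c0, c1 = middle_box(img.mask, spec.middle_fractions)
        keep = np.zeros_like(out)
        keep[r0:r1, c0:c1] = True
        out &= keep
    if not out.any():
        raise EmptyRegionError(
            f"region {spec.region_kind!r} selected no pixels "
            f"for image {img.id!r}")
    return out


def region_pixels(img: TongueImage, spec: RegionSpec) -> np.ndarray:
    """The region's RGB values as an ``(N, 3)`` array (row-major order)."""
    return img.pixels[region_mask(img, spec)]
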