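"""Synthetic labeled tongue-image cohorts.

Images are elliptical tongue shapes on a fixed dark background with
class-conditional body color, class-conditional coating color rendered
as elliptical blobs concentrated in the middle region, and i.i.d.
Gaussian channel noise.  Only the color statistics matter downstream, so
no photorealism is attempted.  Everything is deterministic per seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .region import DEFAULT_MIDDLE_FRACTIONS, TongueImage, middle_box

__all__ = [
    "BACKGROUND_COLOR",
    "ClassAppearance",
    "CohortConfig",
    "generate_tongue",
    "generate_cohort",
    "mask_from_background",
]

#: Fixed background so a naive mask (non-background) is exact.
BACKGROUND_COLOR = (16, 16, 16)


@dataclass(frozen=True)
class ClassAppearance:
    """Mean colors of a class's tongue body and coating."""

    body_color: Tuple[int, int, int]
    coating_color: Tuple[int, int, int]

    def __post_init__(self) -> None:
        for c in (*self.body_color, *self.coating_color):
            if not (0 <= c <= 255):
                raise ValueError("colors must lie in [0, 255]")


#: Hot-like class: red body, yellowish coating.
HOT_APPEARANCE = ClassAppearance(
    body_color=(185, 75, 80), coating_color=(205, 180, 90))
#: Cold-like class: pale-red body, whitish coating.
COLD_APPEARANCE = ClassAppearance(
    body_color=(225, 155, 160), coating_color=(235, 230, 225))


@dataclass(frozen=True)
class CohortConfig:
    """Cohort shape and appearance (defaults mimic a 132/68 class split)."""

    scheme: str = "zheng_hot_cold"
    n_per_class: Dict[int, int] = field(
        default_factory=lambda: {1: 132, -1: 68})
    image_size: Tuple[int, int] = (64, 64)
    appearance: Dict[int, ClassAppearance] = field(
        default_factory=lambda: {1: HOT_APPEARANCE, -1: COLD_APPEARANCE})
    body_spread: float = 6.0
    coating_fraction: float = 0.35
    middle_fractions: Tuple[float, float, float, float] = \
        DEFAULT_MIDDLE_FRACTIONS
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_class.values()):
            raise ValueError("class counts must be >= 1")
        if not (0.0 <= self.coating_fraction <= 1.0):
            raise ValueError("coating_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def mask_from_background(pixels: np.ndarray) -> np.ndarray:
    """Foreground mask for synthetic images: any non-background pixel."""
    return np.any(pixels != np.array(BACKGROUND_COLOR), axis=-1)


def _ellipse_mask(h, w, cy, cx, ry, rx):
    yy, xx = np.ogrid[:h, :w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_tongue(
    config: CohortConfig, class_label: int, seed: int
) -> TongueImage:
    """One synthetic tongue image for a class, deterministic per seed."""
    h, w = config.image_size
    ry, rx = 0.42 * h, 0.44 * w
    if ry < 1.5 or rx < 1.5:
        raise ValueError(f"image size {config.image_size} too small "
                         "for a non-degenerate ellipse")
    rng = np.random.default_rng(seed)
    look = config.appearance[class_label]

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = BACKGROUND_COLOR
    tongue = _ellipse_mask(h, w, h / 2.0, w / 2.0, ry, rx)

    # per-image body tint jitter + flat body fill
    body = np.asarray(look.body_color, dtype=np.float64)
    body = body + rng.normal(0.0, config.body_spread, size=3)
    img[tongue] = body

    # coating blobs inside the middle rectangle until coverage is reached
    if config.coating_fraction > 0:
        r0, r1, c0, c1 = middle_box(tongue, config.middle_fractions)
        mid = np.zeros_like(tongue)
        mid[r0:r1, c0:c1] = True
        mid &= tongue
        target = config.coating_fraction * mid.sum()
        coat = np.asarray(look.coating_color, dtype=np.float64)
        coated = np.zeros_like(tongue)
        for _ in range(200):
            if (coated & mid).sum() >= target:
                break
            cy = rng.uniform(r0, r1)
            cx = rng.uniform(c0, c1)
            bry = rng.uniform(0.06, 0.18) * (r1 - r0) + 1.0
            brx = rng.uniform(0.06, 0.18) * (c1 - c0) + 1.0
            blob = _ellipse_mask(h, w, cy, cx, bry, brx) & tongue
            jitter = coat + rng.normal(0.0, config.body_spread, size=3)
            img[blob] = jitter
            coated |= blob

    if config.noise_sd > 0:
        img[tongue] += rng.normal(
            0.0, config.noise_sd, size=(int(tongue.sum()), 3))

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    # clipping/rounding could collide a tongue pixel with the background
    # color; force it off-background to keep the naive mask exact
    collide = tongue & ~mask_from_background(pixels)
    if collide.any():
        pixels[collide] = np.array(BACKGROUND_COLOR, dtype=np.uint8) + 1
    return TongueImage(pixels=pixels, mask=tongue, id=f"s{seed}")


def _sample_seed(master_seed: int, scheme: str, label: int, index: int) -> int:
    ss = np.random.SeedSequence(
        [master_seed, zlib.crc32(scheme.encode()), label % (2 ** 31), index])
    return int(ss.generate_state(1)[0])


def generate_cohort(
    config: CohortConfig,
) -> List[Tuple[TongueImage, int]]:
    """All images of a cohort with their labels, counts per the config."""
    out: List[Tuple[TongueImage, int]] = []
    for label in sorted(config.n_per_class, reverse=True):
        for index in range(config.n_per_class[label]):
            seed = _sample_seed(config.seed, config.scheme, label, index)
            img = generate_tongue(config, label, seed)
            img.id = f"{config.scheme}_{'pos' if label == 1 else 'neg'}_{index:04d}"
            out.append((img, label))
    return out
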