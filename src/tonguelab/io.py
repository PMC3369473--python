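"""Reading and writing images, masks, manifests and feature tables."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image

from .aggregate import AggregateFeatureVector, variant_feature_names
from .region import TongueImage

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "load_tongue_image",
    "write_manifest",
    "read_manifest",
    "feature_table",
    "write_feature_table",
]


def read_image(path) -> np.ndarray:
    """Decode a PNG/JPEG/BMP file to an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path, pixels: np.ndarray) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), "RGB").save(path)


def read_mask(path) -> np.ndarray:
    """Single-channel mask PNG: 0 background, nonzero foreground."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 0


def write_mask(path, mask: np.ndarray) -> None:
    Image.fromarray(
        (np.asarray(mask, dtype=bool) * np.uint8(255)), "L").save(path)


def load_tongue_image(image_path, mask_path=None, sample_id="") -> TongueImage:
    pixels = read_image(image_path)
    if mask_path is not None:
        mask = read_mask(mask_path)
    else:
        mask = np.ones(pixels.shape[:2], dtype=bool)
    return TongueImage(pixels=pixels, mask=mask,
                       id=sample_id or Path(image_path).stem)


MANIFEST_COLUMNS = ("sample_id", "scheme", "label", "image", "mask", "seed")


def write_manifest(path, rows: Sequence[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def feature_table(vectors: Sequence[AggregateFeatureVector]) -> pd.DataFrame:
    """One row per (sample, region, variant), deterministic column order."""
    if not vectors:
        raise ValueError("no feature vectors")
    variant = vectors[0].variant
    names = variant_feature_names(variant)
    rows = []
    for v in vectors:
        if v.variant != variant:
            raise ValueError("mixed variants in one table")
        rows.append(
            {"sample_id": v.sample_id, "region": v.region_kind,
             "variant": v.variant,
             **dict(zip(names, map(float, v.values)))})
    return pd.DataFrame(rows, columns=["sample_id", "region", "variant"]
                        + names)


def write_feature_table(path, vectors) -> None:
    feature_table(vectors).to_csv(path, index=False)
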