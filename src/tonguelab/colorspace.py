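"""Per-pixel color-space features.

Each 8-bit RGB pixel is expanded into 25 normalized features drawn from
eight color models: RGB, HSV, YIQ, Y'CbCr, XYZ, L*a*b*, CIE Luv and CMYK.
All features are mapped onto [0, 1].

Two APIs are provided: scalar helpers operating on a single
:class:`PixelColor` (``rgb_features`` ... ``cmyk_features``,
``extract_pixel_features``) and a vectorized :func:`pixel_features` that
maps an ``(..., 3)`` uint8 array to an ``(..., 25)`` float64 array.  The
scalar helpers are thin wrappers over the vectorized core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PixelColor",
    "FEATURE_NAMES",
    "N_FEATURES",
    "GAMMA_A",
    "D65",
    "LUV_K1",
    "LUV_K2",
    "RGB2YIQ",
    "RGB2YCBCR",
    "RGB2XYZ",
    "NORMALIZATION_BOUNDS",
    "rgb_features",
    "hsv_features",
    "yiq_features",
    "ycbcr_features",
    "xyz_features",
    "lab_features",
    "luv_features",
    "cmyk_features",
    "extract_pixel_features",
    "pixel_features",
]

#: Fixed feature order: f1..f25.
FEATURE_NAMES = (
    "R", "G", "B",
    "H", "S", "V",
    "YIQ_Y", "YIQ_I", "YIQ_Q",
    "YCbCr_Y", "YCbCr_Cb", "YCbCr_Cr",
    "XYZ_X", "XYZ_Y", "XYZ_Z",
    "Lab_L", "Lab_a", "Lab_b",
    "Luv_L", "Luv_u", "Luv_v",
    "CMYK_C", "CMYK_M", "CMYK_Y", "CMYK_K",
)
N_FEATURES = len(FEATURE_NAMES)

#: Offset constant of the gamma-correction curve applied before XYZ.
GAMMA_A = 0.055

#: D65 reference white (X, Y, Z).
D65 = (0.950456, 1.0, 1.088754)

#: Chromaticity offsets of the Luv transform as used here.
LUV_K1 = 0.2009
LUV_K2 = 0.4610

RGB2YIQ = np.array([
    [0.299, 0.587, 0.114],
    [0.596, -0.274, -0.322],
    [0.211, -0.523, 0.312],
])

#: Applied to raw (unnormalized) R, G, B.
RGB2YCBCR = np.array([
    [0.299, 0.587, 0.114],
    [-0.169, -0.331, 0.500],
    [0.500, -0.419, -0.081],
])

RGB2XYZ = np.array([
    [0.4124, 0.3576, 0.1805],
    [0.2126, 0.7152, 0.0722],
    [0.0193, 0.1192, 0.9505],
])

_PHI_THRESHOLD = (6.0 / 29.0) ** 3

# Extrema of the raw Lab a/b and Luv u/v components over the full 8-bit RGB
# cube under the exact transforms in this module, frozen from a brute-force
# scan of all 256^3 colors.  All four extrema pairs are attained on cube
# edges (two channels at 0 or 255), which the test suite exploits.
_A_BOUNDS = (-86.182864231234, 98.256316290866)
_B_BOUNDS = (-107.868128516164, 94.480145106044)
_U_BOUNDS = (-86.570130928346, 172.935310470657)
_V_BOUNDS = (-130.425817798623, 116.053383987880)

#: (min, max) used to map each raw component onto [0, 1].  Components that
#: are already in [0, 1] (RGB, HSV, CMYK) use the identity bounds.
NORMALIZATION_BOUNDS = {
    "R": (0.0, 1.0), "G": (0.0, 1.0), "B": (0.0, 1.0),
    "H": (0.0, 1.0), "S": (0.0, 1.0), "V": (0.0, 1.0),
    "YIQ_Y": (0.0, 1.0),
    "YIQ_I": (-0.596, 0.596),
    "YIQ_Q": (-0.523, 0.523),
    "YCbCr_Y": (0.0, 255.0),
    "YCbCr_Cb": (-127.5, 127.5),
    "YCbCr_Cr": (-127.5, 127.5),
    "XYZ_X": (0.0, 0.9505),
    "XYZ_Y": (0.0, 1.0),
    "XYZ_Z": (0.0, 1.0890),
    "Lab_L": (0.0, 100.0),
    "Lab_a": _A_BOUNDS,
    "Lab_b": _B_BOUNDS,
    "Luv_L": (0.0, 100.0),
    "Luv_u": _U_BOUNDS,
    "Luv_v": _V_BOUNDS,
    "CMYK_C": (0.0, 1.0), "CMYK_M": (0.0, 1.0),
    "CMYK_Y": (0.0, 1.0), "CMYK_K": (0.0, 1.0),
}


class ChannelRangeError(ValueError):
    """An RGB channel fell outside [0, 255]."""


@dataclass(frozen=True)
class PixelColor:
    """One pixel's raw 8-bit RGB channels.

    Normalized intensities ``r``, ``g``, ``b`` (channel / 255) are exposed
    as properties.
    """

    R: int
    G: int
    B: int

    def __post_init__(self) -> None:
        for name in ("R", "G", "B"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ChannelRangeError(
                    f"channel {name}={v!r} outside [0, 255]")

    @property
    def r(self) -> float:
        return self.R / 255.0

    @property
    def g(self) -> float:
        return self.G / 255.0

    @property
    def b(self) -> float:
        return self.B / 255.0


# ---------------------------------------------------------------------------
# Raw (unnormalized) component transforms, vectorized over (..., 3) arrays.

def _split_norm(rgb: np.ndarray):
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[-1] != 3:
        raise ValueError("expected trailing axis of length 3")
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise ChannelRangeError("RGB values must lie in [0, 255]")
    n = rgb / 255.0
    return rgb, n


def gamma_correct(t: np.ndarray) -> np.ndarray:
    """Nonlinear expansion applied to normalized channels before XYZ."""
    t = np.asarray(t, dtype=np.float64)
    return np.where(
        t <= 0.04045,
        t / 12.92,
        ((t + GAMMA_A) / (1.0 + GAMMA_A)) ** 2.4,
    )


def lab_phi(t: np.ndarray) -> np.ndarray:
    """Cube-root companding of the Lab transform (linear below threshold)."""
    t = np.asarray(t, dtype=np.float64)
    return np.where(
        t > _PHI_THRESHOLD,
        np.cbrt(t),
        (1.0 / 3.0) * (29.0 / 6.0) ** 2 * t + 4.0 / 29.0,
    )


def raw_hsv(rgb: np.ndarray) -> np.ndarray:
    _, n = _split_norm(rgb)
    r, g, b = n[..., 0], n[..., 1], n[..., 2]
    mx = np.max(n, axis=-1)
    mn = np.min(n, axis=-1)
    delta = mx - mn

    v = mx
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(mx == 0, 0.0, delta / np.where(mx == 0, 1.0, mx))
        d = np.where(delta == 0, 1.0, delta)
        h_r = (g - b) / (6.0 * d)
        h_g = ((b - r) / d + 2.0) / 6.0
        h_b = ((r - g) / d + 4.0) / 6.0
    # branch order r, g, b breaks ties when the max is attained twice
    h = np.select(
        [delta == 0, mx == r, mx == g, mx == b],
        [np.zeros_like(v), h_r, h_g, h_b],
    )
    h = np.where(h < 0, h + 1.0, h)
    return np.stack([h, s, v], axis=-1)


def raw_yiq(rgb: np.ndarray) -> np.ndarray:
    _, n = _split_norm(rgb)
    return n @ RGB2YIQ.T


def raw_ycbcr(rgb: np.ndarray) -> np.ndarray:
    raw, _ = _split_norm(rgb)
    return raw @ RGB2YCBCR.T


def raw_xyz(rgb: np.ndarray) -> np.ndarray:
    _, n = _split_norm(rgb)
    return gamma_correct(n) @ RGB2XYZ.T


def raw_lab(rgb: np.ndarray) -> np.ndarray:
    xyz = raw_xyz(rgb)
    fx = lab_phi(xyz[..., 0] / D65[0])
    fy = lab_phi(xyz[..., 1] / D65[1])
    fz = lab_phi(xyz[..., 2] / D65[2])
    lstar = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([lstar, a, b], axis=-1)


def raw_luv(rgb: np.ndarray) -> np.ndarray:
    xyz = raw_xyz(rgb)
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    t = y / D65[1]
    lpp = np.where(
        t <= _PHI_THRESHOLD,
        (29.0 / 3.0) ** 3 * t,
        116.0 * np.cbrt(t) - 16.0,
    )
    denom = x + 15.0 * y + 3.0 * z
    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.where(denom == 0, 1.0, denom)
        u = 13.0 * lpp * (4.0 * x / safe - LUV_K1)
        v = 13.0 * lpp * (9.0 * y / safe - LUV_K2)
    u = np.where(denom == 0, 0.0, u)
    v = np.where(denom == 0, 0.0, v)
    return np.stack([lpp, u, v], axis=-1)


def raw_cmyk(rgb: np.ndarray) -> np.ndarray:
    _, n = _split_norm(rgb)
    mx = np.max(n, axis=-1)
    k = 1.0 - mx
    safe = np.where(mx == 0, 1.0, mx)
    # at black (mx == 0) the ink ratios are 0/0; defined as 0 by convention
    c = np.where(mx == 0, 0.0, (mx - n[..., 0]) / safe)
    m = np.where(mx == 0, 0.0, (mx - n[..., 1]) / safe)
    ystar = np.where(mx == 0, 0.0, (mx - n[..., 2]) / safe)
    return np.stack([c, m, ystar, k], axis=-1)


def _normalize(raw: np.ndarray, names) -> np.ndarray:
    out = np.empty_like(raw)
    for j, name in enumerate(names):
        lo, hi = NORMALIZATION_BOUNDS[name]
        out[..., j] = np.clip((raw[..., j] - lo) / (hi - lo), 0.0, 1.0)
    return out


def pixel_features(rgb: np.ndarray) -> np.ndarray:
    """Map an ``(..., 3)`` array of 8-bit RGB values to ``(..., 25)``
    normalized features in the fixed :data:`FEATURE_NAMES` order."""
    raw, n = _split_norm(rgb)
    blocks = [
        n,
        raw_hsv(rgb),
        _normalize(raw_yiq(rgb), FEATURE_NAMES[6:9]),
        _normalize(raw_ycbcr(rgb), FEATURE_NAMES[9:12]),
        _normalize(raw_xyz(rgb), FEATURE_NAMES[12:15]),
        _normalize(raw_lab(rgb), FEATURE_NAMES[15:18]),
        _normalize(raw_luv(rgb), FEATURE_NAMES[18:21]),
        raw_cmyk(rgb),
    ]
    return np.concatenate(blocks, axis=-1)


# ---------------------------------------------------------------------------
# Scalar API

def _as_array(p: PixelColor) -> np.ndarray:
    return np.array([p.R, p.G, p.B], dtype=np.float64)


def rgb_features(p: PixelColor):
    """f1..f3: normalized R, G, B."""
    return (p.r, p.g, p.b)


def hsv_features(p: PixelColor):
    """f4..f6: hue (wrapped into [0, 1)), saturation, value."""
    h, s, v = raw_hsv(_as_array(p))
    return (float(h), float(s), float(v))


def yiq_features(p: PixelColor):
    """f7..f9: normalized YIQ."""
    out = _normalize(raw_yiq(_as_array(p)), FEATURE_NAMES[6:9])
    return tuple(float(x) for x in out)


def ycbcr_features(p: PixelColor):
    """f10..f12: normalized Y'CbCr (computed from raw 8-bit channels)."""
    out = _normalize(raw_ycbcr(_as_array(p)), FEATURE_NAMES[9:12])
    return tuple(float(x) for x in out)


def xyz_features(p: PixelColor):
    """f13..f15: normalized gamma-corrected XYZ."""
    out = _normalize(raw_xyz(_as_array(p)), FEATURE_NAMES[12:15])
    return tuple(float(x) for x in out)


def lab_features(p: PixelColor):
    """f16..f18: normalized L*, a, b under the D65 white point."""
    out = _normalize(raw_lab(_as_array(p)), FEATURE_NAMES[15:18])
    return tuple(float(x) for x in out)


def luv_features(p: PixelColor):
    """f19..f21: normalized Luv (as printed, with the k1/k2 offsets)."""
    out = _normalize(raw_luv(_as_array(p)), FEATURE_NAMES[18:21])
    return tuple(float(x) for x in out)


def cmyk_features(p: PixelColor):
    """f22..f25: cyan, magenta, yellow, black inks."""
    out = raw_cmyk(_as_array(p))
    return tuple(float(x) for x in out)


def extract_pixel_features(p: PixelColor) -> np.ndarray:
    """All 25 features of one pixel, in fixed order."""
    return pixel_features(_as_array(p))
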