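"""Independent straight-line scalar transcription of the color-feature
definitions, used as a double-transcription oracle.  Deliberately avoids
numpy and any import from the package under test."""

import math

GAMMA_A = 0.055
D65 = (0.950456, 1.0, 1.088754)
K1 = 0.2009
K2 = 0.4610
PHI_T = (6.0 / 29.0) ** 3

# (min, max) normalization bounds, restated literally
BOUNDS = {
    "yiq": [(0.0, 1.0), (-0.596, 0.596), (-0.523, 0.523)],
    "ycbcr": [(0.0, 255.0), (-127.5, 127.5), (-127.5, 127.5)],
    "xyz": [(0.0, 0.9505), (0.0, 1.0), (0.0, 1.0890)],
    "lab": [(0.0, 100.0),
            (-86.182864231234, 98.256316290866),
            (-107.868128516164, 94.480145106044)],
    "luv": [(0.0, 100.0),
            (-86.570130928346, 172.935310470657),
            (-130.425817798623, 116.053383987880)],
}


def norm(value, lo, hi):
    x = (value - lo) / (hi - lo)
    return min(1.0, max(0.0, x))


def gamma(t):
    if t <= 0.04045:
        return t / 12.92
    return ((t + GAMMA_A) / (1.0 + GAMMA_A)) ** 2.4


def phi(t):
    if t > PHI_T:
        return t ** (1.0 / 3.0)
    return (1.0 / 3.0) * (29.0 / 6.0) ** 2 * t + 4.0 / 29.0


def xyz_raw(R, G, B):
    gr, gg, gb = gamma(R / 255.0), gamma(G / 255.0), gamma(B / 255.0)
    x = 0.4124 * gr + 0.3576 * gg + 0.1805 * gb
    y = 0.2126 * gr + 0.7152 * gg + 0.0722 * gb
    z = 0.0193 * gr + 0.1192 * gg + 0.9505 * gb
    return x, y, z


def lab_raw(R, G, B):
    x, y, z = xyz_raw(R, G, B)
    fx, fy, fz = phi(x / D65[0]), phi(y / D65[1]), phi(z / D65[2])
    return 116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)


def luv_raw(R, G, B):
    x, y, z = xyz_raw(R, G, B)
    t = y / D65[1]
    if t <= PHI_T:
        lpp = (29.0 / 3.0) ** 3 * t
    else:
        lpp = 116.0 * t ** (1.0 / 3.0) - 16.0
    d = x + 15.0 * y + 3.0 * z
    if d == 0.0:
        return lpp, 0.0, 0.0
    u = 13.0 * lpp * (4.0 * x / d - K1)
    v = 13.0 * lpp * (9.0 * y / d - K2)
    return lpp, u, v


def features(R, G, B):
    """All 25 features of one 8-bit pixel, literal transcription."""
    r, g, b = R / 255.0, G / 255.0, B / 255.0
    out = [r, g, b]

    mx = max(r, g, b)
    mn = min(r, g, b)
    delta = mx - mn
    v = mx
    s = 0.0 if mx == 0 else delta / mx
    if delta == 0:
        h = 0.0
    elif mx == r:
        h = (g - b) / (6.0 * delta)
    elif mx == g:
        h = ((b - r) / delta + 2.0) / 6.0
    else:
        h = ((r - g) / delta + 4.0) / 6.0
    if h < 0:
        h += 1.0
    out += [h, s, v]

    yiq = (
        0.299 * r + 0.587 * g + 0.114 * b,
        0.596 * r - 0.274 * g - 0.322 * b,
        0.211 * r - 0.523 * g + 0.312 * b,
    )
    out += [norm(val, *bd) for val, bd in zip(yiq, BOUNDS["yiq"])]

    ycbcr = (
        0.299 * R + 0.587 * G + 0.114 * B,
        -0.169 * R - 0.331 * G + 0.500 * B,
        0.500 * R - 0.419 * G - 0.081 * B,
    )
    out += [norm(val, *bd) for val, bd in zip(ycbcr, BOUNDS["ycbcr"])]

    out += [norm(val, *bd)
            for val, bd in zip(xyz_raw(R, G, B), BOUNDS["xyz"])]
    out += [norm(val, *bd)
            for val, bd in zip(lab_raw(R, G, B), BOUNDS["lab"])]
    out += [norm(val, *bd)
            for val, bd in zip(luv_raw(R, G, B), BOUNDS["luv"])]

    k = 1.0 - mx
    if mx == 0:
        c = m = ystar = 0.0
    else:
        c = (mx - r) / mx
        m = (mx - g) / mx
        ystar = (mx - b) / mx
    out += [c, m, ystar, k]
    return out
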