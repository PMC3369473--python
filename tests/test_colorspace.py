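import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tonguelab.colorspace import (
    FEATURE_NAMES,
    NORMALIZATION_BOUNDS,
    PixelColor,
    ChannelRangeError,
    cmyk_features,
    extract_pixel_features,
    gamma_correct,
    hsv_features,
    lab_features,
    lab_phi,
    luv_features,
    pixel_features,
    raw_lab,
    raw_luv,
    raw_xyz,
    raw_ycbcr,
    raw_yiq,
    rgb_features,
    xyz_features,
    ycbcr_features,
    yiq_features,
)

from _oracle import features as oracle_features

channel = st.integers(min_value=0, max_value=255)


class TestPixelColor:
    def test_normalized_channels(self):
        p = PixelColor(128, 64, 32)
        assert (p.r, p.g, p.b) == (128 / 255, 64 / 255, 32 / 255)

    @pytest.mark.parametrize("bad", [(-1, 0, 0), (0, 256, 0), (0, 0, 300)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ChannelRangeError):
            PixelColor(*bad)

    def test_array_input_range_checked(self):
        with pytest.raises(ChannelRangeError):
            pixel_features(np.array([[300.0, 0.0, 0.0]]))


class TestRgb:
    def test_full_scale_red(self):
        assert rgb_features(PixelColor(255, 0, 0)) == (1.0, 0.0, 0.0)

    def test_black(self):
        assert rgb_features(PixelColor(0, 0, 0)) == (0.0, 0.0, 0.0)


class TestHsv:
    def test_pure_red(self):
        assert hsv_features(PixelColor(255, 0, 0)) == (0.0, 1.0, 1.0)

    def test_gray_branch(self):
        h, s, v = hsv_features(PixelColor(128, 128, 128))
        assert (h, s) == (0.0, 0.0)
        assert v == 128 / 255

    def test_green_branch(self):
        # hand evaluation: max = g, H = ((b - r)/delta + 2)/6 = 2/6
        h, s, v = hsv_features(PixelColor(0, 255, 0))
        assert h == pytest.approx(2 / 6, abs=1e-15)
        assert (s, v) == (1.0, 1.0)

    def test_negative_hue_wraps(self):
        # max = r with b > g gives a negative raw hue
        h, _, _ = hsv_features(PixelColor(255, 0, 100))
        assert 0.5 < h < 1.0


class TestYiq:
    def test_white_row_sums(self):
        y, i, q = raw_yiq(np.array([255.0, 255.0, 255.0]))
        assert y == pytest.approx(1.0, abs=1e-12)
        assert i == pytest.approx(0.0, abs=1e-12)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_black_maps_to_bound_midpoints(self):
        assert yiq_features(PixelColor(0, 0, 0)) == (0.0, 0.5, 0.5)

    def test_red_column(self):
        y, i, q = raw_yiq(np.array([255.0, 0.0, 0.0]))
        assert (y, i, q) == pytest.approx((0.299, 0.596, 0.211), abs=1e-12)


class TestYcbcr:
    def test_white_chroma_rows_sum_to_zero(self):
        yp, cb, cr = raw_ycbcr(np.array([255.0, 255.0, 255.0]))
        assert yp == pytest.approx(255.0, abs=1e-9)
        assert cb == pytest.approx(0.0, abs=1e-9)
        assert cr == pytest.approx(0.0, abs=1e-9)

    def test_black(self):
        assert ycbcr_features(PixelColor(0, 0, 0)) == (0.0, 0.5, 0.5)

    def test_blue_column_cb(self):
        _, cb, _ = raw_ycbcr(np.array([0.0, 0.0, 255.0]))
        assert cb == pytest.approx(0.5 * 255, abs=1e-12)


class TestXyz:
    def test_white_row_sums(self):
        x, y, z = raw_xyz(np.array([255.0, 255.0, 255.0]))
        assert (x, y, z) == pytest.approx((0.9505, 1.0, 1.0890), abs=1e-12)

    def test_black(self):
        assert raw_xyz(np.array([0.0, 0.0, 0.0]))[1] == 0.0

    def test_gamma_branch_continuity(self):
        # branch mismatch of the printed constants is ~2.33e-9
        t = 0.04045
        lo = t / 12.92
        hi = ((t + 0.055) / 1.055) ** 2.4
        assert abs(lo - hi) < 5e-9
        assert gamma_correct(np.array(t)) == pytest.approx(lo, abs=1e-15)


class TestLab:
    def test_black_lightness_zero(self):
        lstar, _, _ = raw_lab(np.array([0.0, 0.0, 0.0]))
        assert lstar == pytest.approx(116 * (4 / 29) - 16, abs=1e-12)
        assert lstar == pytest.approx(0.0, abs=1e-12)

    def test_white_point(self):
        lstar, a, b = raw_lab(np.array([255.0, 255.0, 255.0]))
        assert lstar == pytest.approx(100.0, abs=0.2)
        assert a == pytest.approx(0.0, abs=0.1)
        assert b == pytest.approx(0.1, abs=0.2)

    def test_phi_branch_continuity(self):
        t = (6 / 29) ** 3
        cube = t ** (1 / 3)
        lin = (1 / 3) * (29 / 6) ** 2 * t + 4 / 29
        assert abs(cube - lin) < 1e-9
        assert lab_phi(np.array(t)) == pytest.approx(lin, abs=1e-15)


class TestLuv:
    def test_black_forced_zero(self):
        lpp, u, v = raw_luv(np.array([0.0, 0.0, 0.0]))
        assert (lpp, u, v) == (0.0, 0.0, 0.0)

    def test_white_point_hand_evaluation(self):
        x, y, z = raw_xyz(np.array([255.0, 255.0, 255.0]))
        d = x + 15 * y + 3 * z
        lpp, u, v = raw_luv(np.array([255.0, 255.0, 255.0]))
        assert lpp == pytest.approx(116 * y ** (1 / 3) - 16, abs=1e-9)
        assert u == pytest.approx(13 * lpp * (4 * x / d - 0.2009), abs=1e-9)
        assert v == pytest.approx(13 * lpp * (9 * y / d - 0.4610), abs=1e-9)

    def test_lightness_branch_continuity(self):
        t = (6 / 29) ** 3
        lo = (29 / 3) ** 3 * t
        hi = 116 * t ** (1 / 3) - 16
        assert abs(lo - hi) < 1e-9


class TestCmyk:
    def test_white(self):
        assert cmyk_features(PixelColor(255, 255, 255)) == (0, 0, 0, 0)

    def test_black_degenerate_case(self):
        assert cmyk_features(PixelColor(0, 0, 0)) == (0.0, 0.0, 0.0, 1.0)

    def test_red_hand_evaluation(self):
        assert cmyk_features(PixelColor(255, 0, 0)) == (0.0, 1.0, 1.0, 0.0)


class TestFullVector:
    def test_length_and_order(self):
        f = extract_pixel_features(PixelColor(200, 150, 100))
        assert f.shape == (25,)
        assert len(FEATURE_NAMES) == 25

    def test_white_vector(self):
        f = extract_pixel_features(PixelColor(255, 255, 255))
        assert tuple(f[:3]) == (1.0, 1.0, 1.0)
        assert f[24] == 0.0  # K

    @given(v=channel)
    @settings(max_examples=30, deadline=None)
    def test_achromatic_identities(self, v):
        f = extract_pixel_features(PixelColor(v, v, v))
        assert f[3] == 0.0 and f[4] == 0.0          # H, S
        assert tuple(f[21:24]) == (0.0, 0.0, 0.0)   # C, M, Y*
        raw = np.array([float(v)] * 3)
        assert np.allclose(raw_yiq(raw)[1:], 0.0, atol=1e-12)
        assert np.allclose(raw_ycbcr(raw)[1:], 0.0, atol=1e-10)

    def test_oracle_agreement_on_named_pixel(self):
        f = extract_pixel_features(PixelColor(200, 150, 100))
        expected = oracle_features(200, 150, 100)
        assert np.allclose(f, expected, atol=1e-12)

    def test_oracle_agreement_random(self, random_pixels):
        got = pixel_features(random_pixels)
        want = np.array(
            [oracle_features(*map(int, p)) for p in random_pixels])
        assert np.max(np.abs(got - want)) < 1e-12

    def test_unit_interval_on_grid(self):
        grid = np.linspace(0, 255, 17)
        r, g, b = np.meshgrid(grid, grid, grid, indexing="ij")
        rgb = np.stack([r, g, b], axis=-1).reshape(-1, 3)
        f = pixel_features(rgb)
        assert f.min() >= 0.0 and f.max() <= 1.0

    @given(R=channel, G=channel, B=channel)
    @settings(max_examples=200, deadline=None)
    def test_unit_interval_property(self, R, G, B):
        f = extract_pixel_features(PixelColor(R, G, B))
        assert np.all(f >= 0.0) and np.all(f <= 1.0)


class TestNormalizationBounds:
    def test_bounds_well_formed(self):
        for name, (lo, hi) in NORMALIZATION_BOUNDS.items():
            assert lo < hi, name

    def test_frozen_bounds_match_edge_scan(self):
        # all raw extrema of a/b (Lab) and u/v (Luv) over the full RGB
        # cube lie on cube edges (verified by an offline 256^3 scan);
        # rescanning the 12 edges with the independent oracle must
        # reproduce the frozen bounds
        from _oracle import lab_raw, luv_raw

        vals = {"Lab_a": [], "Lab_b": [], "Luv_u": [], "Luv_v": []}
        levels = range(256)
        corners = (0, 255)
        for free_axis in range(3):
            for c1 in corners:
                for c2 in corners:
                    for t in levels:
                        rgb = [c1, c2]
                        rgb.insert(free_axis, t)
                        _, a, b = lab_raw(*rgb)
                        _, u, v = luv_raw(*rgb)
                        vals["Lab_a"].append(a)
                        vals["Lab_b"].append(b)
                        vals["Luv_u"].append(u)
                        vals["Luv_v"].append(v)
        for name, seq in vals.items():
            lo, hi = NORMALIZATION_BOUNDS[name]
            assert min(seq) == pytest.approx(lo, abs=1e-6), name
            assert max(seq) == pytest.approx(hi, abs=1e-6), name
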