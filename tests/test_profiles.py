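import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vesselcaliber.profiles import (
    ClrRuleConfig,
    IntensityProfile,
    StraightenedSegment,
    cut_profiles,
    determine_limits,
    find_extrema,
    initial_half_length,
    sample_profile,
    segment_profile_length,
    smooth_straightened,
    smoothed_mean_profile,
)


def _disc_mask(shape, center, diameter):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= diameter / 2


def _stack(rows_values, center=None):
    rows = [
        IntensityProfile(values=np.asarray(v, dtype=float),
                         center_index=(len(v) - 1) // 2)
        for v in rows_values
    ]
    return StraightenedSegment(rows=rows)


class TestSampleProfile:
    def test_constant_image(self):
        img = np.full((20, 20), 0.7)
        prof = sample_profile(img, (10, 10), np.array([0.6, 0.8]), 5)
        assert np.allclose(prof.values, 0.7)
        assert prof.center_index == 5
        assert len(prof) == 11

    def test_bilinear_at_grid_node_returns_pixel_value(self):
        rng = np.random.default_rng(1)
        img = rng.random((15, 15))
        prof = sample_profile(img, (7, 4), np.array([1.0, 0.0]), 3)
        # samples land on integer grid points (4..10, row 4)
        assert np.allclose(prof.values, img[4, 4:11])

    def test_bilinear_midpoint_of_2x2_block(self):
        img = np.array([[0.0, 0.0], [1.0, 1.0]])
        prof = sample_profile(img, (0.5, 0.5), np.array([1.0, 0.0]), 1)
        assert abs(prof.values[1] - 0.5) < 1e-12

    def test_center_outside_image_raises(self):
        with pytest.raises(ValueError, match="outside"):
            sample_profile(np.zeros((10, 10)), (20, 5), np.array([1.0, 0]), 3)

    def test_out_of_image_samples_flagged_and_edge_filled(self):
        img = np.tile(np.linspace(0, 1, 10), (10, 1))
        prof = sample_profile(img, (1, 5), np.array([1.0, 0.0]), 4)
        assert prof.outside[:3].all() and not prof.outside[3:].any()
        assert np.allclose(prof.values[:4], img[5, 0])  # nearest-edge fill
        assert 0 < prof.outside_fraction < 0.5


class TestInitialHalfLength:
    def test_single_disc_lower_bound(self):
        mask = _disc_mask((40, 40), (20, 20), 10)
        assert initial_half_length(mask) >= 8

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            initial_half_length(np.zeros((5, 5), dtype=bool))

    def test_two_discs_takes_the_larger(self):
        mask = _disc_mask((60, 120), (30, 30), 6) | _disc_mask((60, 120), (30, 90), 14)
        assert initial_half_length(mask) >= 11


class TestSmoothedMeanProfile:
    def test_polynomial_rows_reproduced(self):
        x = np.arange(21.0)
        quad = 0.5 + 0.01 * (x - 10) ** 2
        straight = _stack([quad] * 15)
        out = smoothed_mean_profile(straight, 7)
        assert np.allclose(out, quad, atol=1e-10)

    def test_linear_ramp_unchanged(self):
        ramp = np.linspace(0, 1, 21)
        out = smoothed_mean_profile(_stack([ramp] * 3), 1)
        assert np.allclose(out, ramp, atol=1e-10)

    def test_noise_reduced_relative_to_single_row(self):
        rng = np.random.default_rng(5)
        clean = 0.8 - 0.5 * np.exp(-(((np.arange(31) - 15) / 6.0) ** 2))
        rows = [clean + rng.normal(0, 0.05, 31) for _ in range(11)]
        out = smoothed_mean_profile(_stack(rows), 5)
        rms_out = np.sqrt(((out - clean) ** 2).mean())
        rms_single = min(np.sqrt(((r - clean) ** 2).mean()) for r in rows)
        assert rms_out < rms_single

    def test_window_truncated_at_segment_ends(self):
        rows = [np.full(11, float(i)) for i in range(20)]
        out = smoothed_mean_profile(_stack(rows), 0)
        # rows 0..5 averaged -> 2.5
        assert np.allclose(out, 2.5, atol=1e-9)


class TestFindExtrema:
    def test_monotone_profile_has_no_interior_extrema(self):
        minima, maxima = find_extrema(np.linspace(0, 1, 20))
        assert len(minima) == 0 and len(maxima) == 0

    def test_v_shape_minimum_at_vertex(self):
        v = np.abs(np.arange(15.0) - 7)
        minima, maxima = find_extrema(v)
        assert list(minima) == [7.0] and len(maxima) == 0

    def test_w_shape_with_plateau_midpoints(self):
        v = np.array([4, 3, 2, 1, 2, 3, 3, 2, 1, 2, 3, 3, 2, 1, 2, 3, 4], dtype=float)
        minima, maxima = find_extrema(v)
        assert list(minima) == [3.0, 8.0, 13.0]
        assert list(maxima) == [5.5, 10.5]


def _tent(center, width, height, n):
    """Triangular bump at ``center`` on an n-sample zero baseline."""
    x = np.arange(n, dtype=float)
    return np.maximum(0.0, height * (1 - np.abs(x - center) / width))


class TestDetermineLimits:
    def test_clr_profile_length_formula(self):
        # W-vessel: limiting maxima at 5 and 25, CLR peak at 15, minima 10/20
        prof = (
            0.5
            + _tent(5, 4, 0.3, 31)
            + _tent(25, 4, 0.3, 31)
            + _tent(15, 4, 0.25, 31)
        )
        lim = determine_limits(prof)
        assert lim.is_clr
        assert (lim.x_maxL, lim.x_center, lim.x_maxR) == (5.0, 15.0, 25.0)
        assert lim.prof_length == pytest.approx(2 * np.mean([10, 10]))

    def test_plain_vessel_length_formula(self):
        x = np.arange(31.0)
        prof = 0.8 - 0.5 * np.exp(-(((x - 15) / 5.0) ** 2)) + _tent(8, 3, 0.2, 31) + _tent(22, 3, 0.2, 31)
        lim = determine_limits(prof)
        assert not lim.is_clr
        assert (lim.x_maxL, lim.x_center, lim.x_maxR) == (8.0, 15.0, 22.0)
        assert lim.prof_length == pytest.approx(2 * np.mean([7, 7]))

    def test_unbalanced_bump_depths_reject_clr(self):
        # left bump much deeper than right -> CLR invalid, plain branch taken
        prof = (
            0.5
            + _tent(5, 4, 0.40, 31)
            + _tent(25, 4, 0.05, 31)
            + _tent(15, 4, 0.03, 31)
        )
        lim = determine_limits(prof)
        assert not lim.is_clr

    def test_flat_profile_falls_back_to_full_length(self):
        lim = determine_limits(np.full(21, 0.5))
        assert lim.fallback
        assert lim.prof_length == 20.0
        assert (lim.x_maxL, lim.x_maxR) == (0.0, 20.0)

    def test_clr_center_elevation_must_not_surpass_limits(self):
        # CLR peak above the limiting maxima -> rejected
        prof = (
            0.5
            + _tent(5, 4, 0.2, 31)
            + _tent(25, 4, 0.2, 31)
            + _tent(15, 4, 0.35, 31)
        )
        assert not determine_limits(prof).is_clr

    def test_minima_too_close_reject_clr(self):
        rules = ClrRuleConfig(min_minima_separation=12.0)
        prof = (
            0.5
            + _tent(5, 4, 0.3, 31)
            + _tent(25, 4, 0.3, 31)
            + _tent(15, 4, 0.25, 31)
        )
        assert determine_limits(prof).is_clr
        assert not determine_limits(prof, rules).is_clr

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=3, max_size=60)
    )
    def test_always_returns_positive_length(self, values):
        lim = determine_limits(np.array(values))
        assert lim.prof_length > 0
        assert lim.x_maxL < lim.x_center < lim.x_maxR


class TestSegmentProfileLength:
    @pytest.mark.parametrize(
        "values,expected", [([10, 12, 14], 12), ([9], 9), ([10, 12, 14, 100], 13)]
    )
    def test_median_convention(self, values, expected):
        assert segment_profile_length([float(v) for v in values]) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            segment_profile_length([])


class TestCutProfiles:
    def test_cut_to_length_20_keeps_21_samples(self):
        rng = np.random.default_rng(2)
        straight = _stack([rng.random(41) for _ in range(5)])
        cut = cut_profiles(straight, 20.0)
        assert all(len(r) == 21 for r in cut.rows)
        for before, after in zip(straight.rows, cut.rows):
            assert after.values[10] == before.values[20]  # center preserved

    def test_cut_to_current_length_is_identity(self):
        straight = _stack([np.arange(41.0)])
        cut = cut_profiles(straight, 40.0)
        assert np.allclose(cut.rows[0].values, straight.rows[0].values)

    def test_nonpositive_length_raises(self):
        with pytest.raises(ValueError):
            cut_profiles(_stack([np.arange(11.0)]), 0.0)


class TestSmoothStraightened:
    def test_constant_image_unchanged(self):
        straight = _stack([np.full(21, 0.4) for _ in range(9)])
        out = smooth_straightened(straight, 10.0)
        assert np.allclose(out.as_array(), 0.4, atol=1e-12)

    def test_impulse_second_moment_matches_sigma_across(self):
        # prof_length 20 -> sigma_across = 2 px; check the discrete kernel's
        # across-profile second moment within 5 %
        n_rows, n_cols = 31, 81
        arr = np.zeros((n_rows, n_cols))
        arr[n_rows // 2, n_cols // 2] = 1.0
        straight = _stack(list(arr))
        out = smooth_straightened(straight, 20.0).as_array()
        marginal = out.sum(axis=0)
        x = np.arange(n_cols) - n_cols // 2
        var = (marginal * x**2).sum() / marginal.sum()
        assert var == pytest.approx(2.0**2, rel=0.05)
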