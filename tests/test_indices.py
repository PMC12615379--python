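"""Dual-temporal index families: DSRI, DSDI, DSDI-SL and candidate naming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from paddyspec import (
    DsdiSlSpec,
    SpectralGrid,
    build_candidates,
    candidate_matrix,
    default_grid,
    dsdi,
    dsdi_sl,
    dsri,
)

spectra = arrays(
    float, st.integers(min_value=3, max_value=12),
    elements=st.floats(min_value=0.01, max_value=1.0),
)


class TestDsri:
    def test_worked_single_band_example(self):
        value = dsri(np.array([0.25]* 2), np.array([0.30, 0.25]))
        assert value[0] == pytest.approx(0.0909090909)
        assert round(float(value[0]), 2) == 0.09

    def test_identical_dates_give_zero(self, rng):
        r = rng.random(10) + 0.1
        assert np.allclose(dsri(r, r), 0.0)

    @given(spectra, spectra)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_in_dates(self, a, b):
        n = min(a.size, b.size)
        a, b = a[:n], b[:n]
        assert np.allclose(dsri(a, b), -dsri(b, a), equal_nan=True)

    @given(spectra, st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=100, deadline=None)
    def test_invariant_to_common_illumination_gain(self, r, gain):
        late = 1.3 * r
        assert np.allclose(dsri(gain * r, gain * late), dsri(r, late))

    def test_zero_denominator_flagged_not_zeroed(self):
        out = dsri(np.array([0.0, 0.2]), np.array([0.0, 0.3]))
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_bounded_for_positive_reflectance(self, rng):
        a, b = rng.random((2, 500, 30)) + 1e-6
        out = dsri(a, b)
        assert np.all(out >= -1) and np.all(out <= 1)


class TestDsdi:
    def test_hand_computed_normalization(self):
        out = dsdi(np.zeros(3), np.array([0.05, -0.01, 0.03]))
        assert np.allclose(out, [1.0, 0.0, 2 / 3])

    def test_difference_before_normalization_is_plain_subtraction(self):
        # 0.30 − 0.25 = 0.05 enters the min–max step
        d = np.array([0.30, 0.10]) - np.array([0.25, 0.10])
        assert d[0] == pytest.approx(0.05)

    @given(spectra, spectra, st.floats(min_value=-0.5, max_value=0.5))
    @settings(max_examples=100, deadline=None)
    def test_shift_invariance(self, a, b, c):
        from hypothesis import assume

        n = min(a.size, b.size)
        a, b = a[:n], b[:n]
        d = b - a
        assume(d.max() - d.min() > 1e-3)  # keep away from the degenerate case
        assert np.allclose(dsdi(a, b), dsdi(a, b + c), atol=1e-6)

    def test_min_zero_max_one_per_pixel(self, rng):
        early = rng.random((200, 40))
        late = rng.random((200, 40))
        out = dsdi(early, late)
        assert np.allclose(out.min(axis=1), 0.0)
        assert np.allclose(out.max(axis=1), 1.0)
        # oracle: brute-force per-pixel recomputation
        d = late - early
        brute = (d - d.min(1, keepdims=True)) / (
            d.max(1, keepdims=True) - d.min(1, keepdims=True)
        )
        assert np.abs(out - brute).max() < 1e-12

    def test_constant_difference_flagged_degenerate(self):
        out, degen = dsdi(np.full(5, 0.2), np.full(5, 0.3), return_degenerate=True)
        assert degen and np.all(out == 0)

    def test_needs_two_bands(self):
        with pytest.raises(ValueError):
            dsdi(np.array([0.1]), np.array([0.2]))


class TestDsdiSl:
    def setup_method(self):
        self.grid = SpectralGrid([500.0, 600.0, 800.0, 900.0])

    def test_equal_values_give_zero(self):
        vals = np.array([0.2, 0.5, 0.2, 0.9])
        assert dsdi_sl(vals, self.grid, DsdiSlSpec(500, 800)) == pytest.approx(0.0)

    def test_short_long_contrast_orientation(self):
        # short-wave 0.6, long-wave 0.2 -> (0.6−0.2)/(0.6+0.2) = +0.5: the
        # index rises when the short-wave side dominates (worse stress)
        vals = np.array([0.6, 0.1, 0.2, 0.9])
        assert dsdi_sl(vals, self.grid, DsdiSlSpec(500, 800)) == pytest.approx(0.5)

    def test_extremes(self):
        vals = np.array([1.0, 0.5, 0.0, 0.9])
        assert dsdi_sl(vals, self.grid, DsdiSlSpec(500, 800)) == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        vals = np.array([0.0, 0.5, 0.0, 0.9])
        assert np.isnan(dsdi_sl(vals, self.grid, DsdiSlSpec(500, 800)))

    def test_bounded_in_unit_interval_inputs(self, rng):
        vals = rng.random((300, 4))
        out = dsdi_sl(vals, self.grid, DsdiSlSpec(600, 900))
        ok = ~np.isnan(out)
        assert np.all(out[ok] >= -1) and np.all(out[ok] <= 1)

    @pytest.mark.parametrize("short, long", [(800, 900), (500, 600)])
    def test_band_regions_enforced(self, short, long):
        with pytest.raises(ValueError):
            DsdiSlSpec(short, long)


class TestCandidateSet:
    def test_full_study_candidate_count(self):
        grid = default_grid()
        short = [399, 463, 529, 607, 639, 707]
        long = [763, 817, 898, 1006]
        names = build_candidates(grid, short, long)
        assert len(names) == 632
        assert sum(n.startswith("DSRI_") for n in names) == 304
        assert sum(n.startswith("DSDI_") for n in names) == 304
        assert sum(n.startswith("DSDI-SL_") for n in names) == 24

    def test_tiny_grid_counting(self):
        grid = SpectralGrid([500.0, 800.0])
        names = build_candidates(grid, [500], [800])
        assert len(names) == 5
        assert "DSDI-SL_500-800" in names

    def test_names_encode_wavelengths(self):
        grid = default_grid()
        names = build_candidates(grid, [399], [817])
        assert "DSRI_525" in names and "DSDI_525" in names
        assert names[-1] == "DSDI-SL_399-817"

    def test_candidate_matrix_values_match_direct_computation(self, small_scene):
        from paddyspec import extract_plot_pixels

        pairs = extract_plot_pixels(
            small_scene.cube_t1, small_scene.cube_t2, small_scene.footprints[:2]
        )
        short, long = [529], [898]
        feats = candidate_matrix(pairs, short, long)
        assert len(feats) == 2 * 49
        j = pairs.grid.nearest_band(529)
        direct = dsri(pairs.r_early, pairs.r_late)[:, j]
        assert np.allclose(feats["DSRI_529"], direct, equal_nan=True)
        sl = dsdi_sl(dsdi(pairs.r_early, pairs.r_late), pairs.grid, DsdiSlSpec(529, 898))
        assert np.allclose(feats["DSDI-SL_529-898"], sl, equal_nan=True)
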