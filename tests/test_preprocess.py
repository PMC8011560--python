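"""Smoothing, baseline estimation/subtraction and rt alignment."""

import numpy as np
import pytest

from mrmscreen.io_mrm import Chromatogram
from mrmscreen.preprocess import (
    BaselineConfig,
    SmoothingConfig,
    align_to_standards,
    baseline_knots,
    estimate_baseline,
    savgol_smooth,
    subtract_baseline,
)


def chrom(grid, intensity, cid=1):
    return Chromatogram(rt=grid, intensity=np.asarray(intensity, float), channel_id=cid)


def gaussian(x, height, rt, width):
    return height * np.exp(-(((x - rt) / width) ** 2))


def quantile_oracle(segment, q):
    """Order-statistic quantile with linear interpolation, from first principles."""
    s = np.sort(np.asarray(segment, float))
    h = (s.size - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, s.size - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


class TestSavgolSmooth:
    def test_constant_trace_unchanged(self, flat_grid):
        out = savgol_smooth(chrom(flat_grid, np.full(flat_grid.size, 7.0)))
        np.testing.assert_allclose(out.intensity, 7.0, atol=1e-9)

    @pytest.mark.parametrize("order", [0, 1, 2, 3])
    def test_polynomials_up_to_filter_order_pass_through(self, flat_grid, order):
        y = sum((0.3 + order) * flat_grid**k for k in range(order + 1))
        out = savgol_smooth(chrom(flat_grid, y), SmoothingConfig(half_width=5, poly_order=3))
        np.testing.assert_allclose(out.intensity, y, atol=1e-9 * max(1.0, np.abs(y).max()))

    def test_noise_variance_reduced_and_matches_windowed_lsq_oracle(self, rng):
        grid = np.arange(0, 2, 0.005)
        y = rng.normal(size=grid.size)
        cfg = SmoothingConfig(half_width=5, poly_order=3)
        out = savgol_smooth(chrom(grid, y), cfg)
        assert out.intensity.var() < y.var()
        # per-window polynomial least squares, evaluated at the window centre
        d, N = cfg.half_width, cfg.poly_order
        m = np.arange(-d, d + 1)
        A = np.vander(m, N + 1, increasing=True)
        for center in [20, 100, 250]:
            h = y[center - d : center + d + 1]
            alpha, *_ = np.linalg.lstsq(A, h, rcond=None)
            assert out.intensity[center] == pytest.approx(alpha[0], abs=1e-9)

    def test_linearity(self, rng, flat_grid):
        a, b = 2.5, -0.7
        x1 = rng.normal(size=flat_grid.size)
        x2 = rng.normal(size=flat_grid.size)
        sm = lambda v: savgol_smooth(chrom(flat_grid, v)).intensity
        np.testing.assert_allclose(sm(a * x1 + b * x2), a * sm(x1) + b * sm(x2), atol=1e-9)

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError):
            savgol_smooth(chrom(np.arange(5.0) + 1, np.zeros(5)), SmoothingConfig(5, 3))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SmoothingConfig(half_width=1, poly_order=3)


class TestBaseline:
    def test_all_zero_trace(self, flat_grid):
        out = estimate_baseline(chrom(flat_grid, np.zeros(flat_grid.size)), BaselineConfig(50, 0.05))
        np.testing.assert_array_equal(out.intensity, 0.0)

    def test_knots_equal_order_statistic_oracle(self, rng):
        grid = np.arange(0, 10, 0.005)
        y = rng.uniform(0, 100, grid.size)
        cfg = BaselineConfig(window=400, quantile=0.05)
        krt, kval = baseline_knots(y, grid, cfg)
        for i, s in enumerate(range(0, grid.size, cfg.window)):
            seg = y[s : s + cfg.window]
            assert kval[i] == pytest.approx(quantile_oracle(seg, cfg.quantile), abs=1e-12)

    def test_peakless_ramp_tracked_within_window_offset(self):
        grid = np.arange(0, 10, 0.005)
        ramp = 10.0 * grid  # 0 to 100
        cfg = BaselineConfig(window=50, quantile=0.05)
        krt, kval = baseline_knots(ramp, grid, cfg)
        # within one window the ramp spans 50 * slope * step intensity units
        window_span = 50 * 10.0 * 0.005
        np.testing.assert_array_less(np.abs(kval - 10.0 * krt), window_span + 1e-9)

    def test_narrow_peaks_do_not_lift_baseline(self):
        grid = np.arange(0, 10, 0.005)
        ramp = 10.0 * grid
        peaks = sum(gaussian(grid, 1000.0, c, 0.02) for c in (2.0, 5.0, 8.0))
        cfg = BaselineConfig(window=400, quantile=0.05)
        _, kval_clean = baseline_knots(ramp, grid, cfg)
        _, kval_peaky = baseline_knots(ramp + peaks, grid, cfg)
        assert np.max(np.abs(kval_peaky - kval_clean)) < 0.05 * 1000.0

    def test_quantile_monotonicity(self, rng):
        grid = np.arange(0, 5, 0.005)
        y = rng.uniform(0, 100, grid.size)
        lo = baseline_knots(y, grid, BaselineConfig(200, 0.05))[1]
        hi = baseline_knots(y, grid, BaselineConfig(200, 0.25))[1]
        assert np.all(hi >= lo - 1e-12)

    def test_too_short_trace_raises(self, flat_grid):
        with pytest.raises(ValueError):
            estimate_baseline(chrom(flat_grid[:100], np.zeros(100)), BaselineConfig(window=400))


class TestSubtractBaseline:
    def test_self_subtraction_is_zero(self, flat_grid, rng):
        c = chrom(flat_grid, rng.uniform(0, 10, flat_grid.size))
        np.testing.assert_array_equal(subtract_baseline(c, c).intensity, 0.0)

    def test_zero_baseline_is_identity(self, flat_grid, rng):
        c = chrom(flat_grid, rng.uniform(0, 10, flat_grid.size))
        z = chrom(flat_grid, np.zeros(flat_grid.size))
        np.testing.assert_array_equal(subtract_baseline(c, z).intensity, c.intensity)

    def test_output_nonnegative(self, flat_grid, rng):
        c = chrom(flat_grid, rng.normal(size=flat_grid.size))
        b = chrom(flat_grid, rng.normal(size=flat_grid.size))
        assert subtract_baseline(c, b).intensity.min() >= 0.0

    def test_apex_recovery_under_drift(self):
        """Peaks on a bleed-like drifting background recover apex heights within 5%."""
        grid = np.arange(0, 20, 0.005)
        drift = 5.0 * grid + 40.0 * (np.exp(0.05 * grid) - 1.0)
        truth = {4.0: 400.0, 9.5: 250.0, 15.0: 700.0}
        y = drift + sum(gaussian(grid, h, c, 0.03) for c, h in truth.items())
        c = chrom(grid, y)
        corrected = subtract_baseline(c, estimate_baseline(c, BaselineConfig(400, 0.05)))
        for center, height in truth.items():
            apex = corrected.intensity[np.argmin(np.abs(grid - center))]
            assert apex == pytest.approx(height, rel=0.05)


class TestAlignment:
    def test_zero_delta_is_identity(self, flat_grid, rng):
        c = chrom(flat_grid, rng.uniform(0, 10, flat_grid.size))
        out = align_to_standards(c, [5.0], [5.0])
        np.testing.assert_allclose(out.intensity, c.intensity, atol=1e-12)

    def test_planted_shift_corrected_within_one_grid_step(self):
        grid = np.arange(0, 10, 0.005)
        shift = 0.30
        std_rt = 5.0
        y = gaussian(grid, 1000.0, std_rt + shift, 0.03)
        out = align_to_standards(chrom(grid, y), [std_rt + shift], [std_rt])
        apex_rt = grid[np.argmax(out.intensity)]
        assert abs(apex_rt - std_rt) <= 0.005 + 1e-12

    def test_two_samples_coalign_within_two_steps(self):
        grid = np.arange(0, 10, 0.005)
        std_rt = 5.0
        apexes = []
        for shift in (0.21, -0.13):
            y = gaussian(grid, 1000.0, std_rt + shift, 0.03)
            out = align_to_standards(chrom(grid, y), [std_rt + shift], [std_rt])
            apexes.append(grid[np.argmax(out.intensity)])
        assert abs(apexes[0] - apexes[1]) <= 2 * 0.005 + 1e-12

    def test_missing_standard_raises(self, flat_grid):
        c = chrom(flat_grid, np.zeros(flat_grid.size))
        with pytest.raises(KeyError):
            align_to_standards(c, [], [5.0])
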