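"""Quantification core: integrals, areas, CD%, calibration, uncertainty."""

import numpy as np
import pytest

from ramancd import (
    A_RANGE_ROOT,
    L_RANGE,
    NoiseParams,
    Spectrum,
    TruthParams,
    apply_calibration,
    band_area,
    bulk_cd_percent,
    cd_map,
    compute_cd_percent,
    determine_a_range,
    fit_calibration,
    generate_glucose_standard,
    generate_root_cube,
    pretreat,
    primitive_integral,
    propagate_uncertainty,
    rayleigh_resolution,
    scan_grid,
    silent_region_correction,
)
from ramancd.exceptions import CalibrationError, NoBandError, ValidationError
from ramancd.segment import bulk_root_spectrum

from conftest import gaussian_spectrum, make_flat_spectrum


class TestPrimitiveIntegral:
    def test_zero_spectrum(self, coarse_axis):
        a_i = primitive_integral(make_flat_spectrum(coarse_axis, 0.0))
        assert np.all(a_i.values == 0.0)

    def test_constant_closed_form(self, coarse_axis):
        c = 2.5
        a_i = primitive_integral(make_flat_spectrum(coarse_axis, c))
        expected = c * (coarse_axis - coarse_axis[0])
        assert np.allclose(a_i.values, expected)

    def test_monotone_for_nonnegative(self, coarse_axis, rng):
        y = rng.uniform(0, 5, coarse_axis.size)
        a_i = primitive_integral(Spectrum(coarse_axis, y))
        assert np.all(np.diff(a_i.values) >= 0)
        assert a_i.values[0] == 0.0

    def test_matches_fine_grid_riemann_oracle(self, coarse_axis, rng):
        """Total integral equals a 20x subdivided midpoint Riemann sum of the
        piecewise-linear signal."""
        y = rng.uniform(1, 3, coarse_axis.size)
        spec = Spectrum(coarse_axis, y)
        a_i = primitive_integral(spec)
        total = 0.0
        for k in range(coarse_axis.size - 1):
            sub = np.linspace(coarse_axis[k], coarse_axis[k + 1], 21)
            mid = 0.5 * (sub[:-1] + sub[1:])
            total += np.sum(np.interp(mid, coarse_axis, y)) * (sub[1] - sub[0])
        assert a_i.values[-1] == pytest.approx(total, rel=1e-6)


class TestBandArea:
    def test_degenerate_window_is_zero(self, coarse_axis):
        a_i = primitive_integral(make_flat_spectrum(coarse_axis, 5.0))
        # both bounds snap to the same channel
        assert band_area(a_i, (2000.2, 2000.9)) == 0.0

    def test_constant_times_width(self, coarse_axis):
        c = 3.0
        a_i = primitive_integral(make_flat_spectrum(coarse_axis, c))
        assert band_area(a_i, (2000.0, 2400.0)) == pytest.approx(c * 400.0)

    def test_gaussian_band_analytic_area(self, coarse_axis):
        amplitude, sigma = 40.0, 30.0
        spec = gaussian_spectrum(coarse_axis, 2170, sigma, amplitude)
        a_i = primitive_integral(spec)
        area = band_area(a_i, (2170 - 4 * sigma, 2170 + 4 * sigma))
        assert area == pytest.approx(amplitude * sigma * np.sqrt(2 * np.pi), rel=0.005)


class TestSilentCorrection:
    def test_empty_silent_region_no_correction(self, coarse_axis):
        spec = gaussian_spectrum(coarse_axis, 2170, 20, 50.0)
        a_i = primitive_integral(spec)
        a_ch, a_cd, b = silent_region_correction(a_i)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert a_cd == pytest.approx(band_area(a_i, L_RANGE.cd))

    def test_flat_spectrum_cancels_exactly(self, coarse_axis):
        a_i = primitive_integral(make_flat_spectrum(coarse_axis, 6.0))
        a_ch, a_cd, b = silent_region_correction(a_i)
        assert b == pytest.approx(6.0)
        assert a_ch == pytest.approx(0.0, abs=1e-9)
        assert a_cd == pytest.approx(0.0, abs=1e-9)


class TestComputeCDPercent:
    @pytest.mark.parametrize(
        "a_ch,a_cd,expected",
        [(100.0, 0.0, 0.0), (50.0, 50.0, 50.0), (190.0, 10.0, 5.0)],
    )
    def test_arithmetic(self, a_ch, a_cd, expected):
        assert compute_cd_percent(a_ch, a_cd) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        assert np.isnan(compute_cd_percent(0.0, 0.0))

    def test_negative_cd_area_gives_negative_percent(self):
        assert compute_cd_percent(100.0, -5.0) == pytest.approx(-5.0 / 95.0 * 100.0)

    def test_negative_ch_area_undefined(self):
        assert np.isnan(compute_cd_percent(-10.0, 50.0))


class TestCDMapExactness:
    def test_noise_free_recovery_exact(self, cube_noise_free_pre):
        pre, truth = cube_noise_free_pre
        result = cd_map(pre, truth.mask)
        root = truth.mask == 1
        assert np.all(np.abs(result.cd_percent[root] - 20.0) < 1e-9)

    def test_void_pixels_undefined(self, cube_noise_free_pre):
        pre, truth = cube_noise_free_pre
        result = cd_map(pre, truth.mask)
        assert np.all(np.isnan(result.cd_percent[truth.mask == 0]))

    def test_scale_invariance(self, cube_noise_free_pre):
        """CD% is a ratio: a global intensity rescaling changes nothing."""
        pre, truth = cube_noise_free_pre
        scaled = pre.with_cube(pre.cube * 7.3)
        a = cd_map(pre, truth.mask).cd_percent
        b = cd_map(scaled, truth.mask).cd_percent
        assert np.allclose(a[truth.mask == 1], b[truth.mask == 1], atol=1e-9)

    def test_l_range_and_a_range_agree(self, cube_noise_free_pre):
        """Bands inside both window families give identical CD%."""
        pre, truth = cube_noise_free_pre
        a = cd_map(pre, truth.mask, L_RANGE).cd_percent
        b = cd_map(pre, truth.mask, A_RANGE_ROOT).cd_percent
        root = truth.mask == 1
        assert np.all(np.abs(a[root] - b[root]) < 0.1)

    def test_noisy_mean_near_truth(self):
        """Root-pixel mean CD% within +-0.5 of 20 at default noise (20 seeds)."""
        means = []
        for seed in range(20):
            hsmap, truth = generate_root_cube(8, 10, seed=100 + seed)
            pre = pretreat(hsmap)
            result = cd_map(pre, truth.mask)
            means.append(np.nanmean(result.cd_percent))
        assert abs(np.mean(means) - 20.0) < 0.5

    def test_bulk_consistent_with_area_weighted_pixels(self, cube_noise_free_pre):
        """Bulk CD% equals the ratio of summed per-pixel areas, not the mean
        of per-pixel CD%."""
        pre, truth = cube_noise_free_pre
        bulk = bulk_root_spectrum(pre, truth.mask)
        cd_bulk, _ = bulk_cd_percent(bulk)
        a_ch_sum = a_cd_sum = 0.0
        for r in range(pre.shape[0]):
            for c in range(pre.shape[1]):
                if truth.mask[r, c]:
                    a_ch, a_cd, _ = silent_region_correction(
                        primitive_integral(pre.spectrum(r, c))
                    )
                    a_ch_sum += a_ch
                    a_cd_sum += a_cd
        assert cd_bulk == pytest.approx(compute_cd_percent(a_ch_sum, a_cd_sum), abs=1e-9)


class TestARange:
    def test_single_band_edges_symmetric(self, coarse_axis):
        spec = gaussian_spectrum(coarse_axis, 2170, 40, 100.0)
        lo, hi = determine_a_range([spec], "cd")
        assert (lo + hi) / 2 == pytest.approx(2170, abs=2.0)

    def test_edges_average_across_spectra(self, coarse_axis):
        """Rectangular bands with known edges average channel-exactly."""
        def rect(lo, hi):
            y = np.where((coarse_axis >= lo) & (coarse_axis <= hi), 50.0, 0.0)
            return Spectrum(coarse_axis, y)

        result = determine_a_range([rect(2100, 2300), rect(2090, 2310)], "cd")
        assert result[0] == pytest.approx(2095, abs=4.0)
        assert result[1] == pytest.approx(2305, abs=4.0)

    def test_larger_fraction_gives_narrower_range(self, coarse_axis, rng):
        for _ in range(10):
            center = rng.uniform(2100, 2250)
            sigma = rng.uniform(20, 60)
            spec = gaussian_spectrum(coarse_axis, center, sigma, rng.uniform(20, 200))
            lo1, hi1 = determine_a_range([spec], "cd", edge_fraction=0.05)
            lo2, hi2 = determine_a_range([spec], "cd", edge_fraction=0.2)
            assert lo2 >= lo1 and hi2 <= hi1

    def test_no_band_raises(self, coarse_axis, rng):
        spec = Spectrum(coarse_axis, rng.normal(10, 1, coarse_axis.size))
        with pytest.raises(NoBandError):
            determine_a_range([spec], "cd")


class TestCalibration:
    def test_perfect_standards_identity(self):
        model = fit_calibration([(0, 0), (10, 10), (20, 20), (40, 40)])
        assert model.slope == pytest.approx(1.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        assert apply_calibration(model, 12.5) == pytest.approx(12.5)

    def test_constructed_line_recovered_exactly(self):
        true = np.array([0.0, 10.0, 20.0, 40.0])
        model = fit_calibration(np.column_stack([true, 0.9 * true + 1.0]))
        assert model.slope == pytest.approx(0.9)
        assert model.intercept == pytest.approx(1.0)
        assert apply_calibration(model, 0.9 * 10 + 1.0) == pytest.approx(10.0)

    def test_noisy_standards_slope_within_three_sigma(self):
        """100-seed Monte-Carlo: OLS slope stays within 3 sigma of truth."""
        true = np.array([0.0, 5.0, 10.0, 20.0, 30.0, 40.0])
        rng = np.random.default_rng(55)
        slopes = []
        for _ in range(100):
            meas = true + rng.normal(0, 0.3, true.size)
            slopes.append(fit_calibration(np.column_stack([true, meas])).slope)
        x = true - true.mean()
        slope_sigma = 0.3 / np.sqrt((x**2).sum())
        assert np.mean(np.abs(np.array(slopes) - 1.0) < 3 * slope_sigma) > 0.95

    def test_linear_distortion_inverted(self):
        """Known distortion of synthetic standards is inverted to < 0.2%
        absolute bias at CD% >= 5."""
        true = np.array([0.0, 5.0, 10.0, 20.0, 30.0, 40.0])
        measured = 0.93 * true + 0.8
        model = fit_calibration(np.column_stack([true, measured]))
        recovered = apply_calibration(model, measured)
        assert np.max(np.abs(recovered[true >= 5] - true[true >= 5])) < 0.2

    def test_identical_true_values_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([(10, 9), (10, 11)])


class TestUncertainty:
    def test_zero_perturbations_zero_uncertainty(self, cube_noise_free_pre):
        pre, truth = cube_noise_free_pre
        r, c = np.argwhere(truth.mask == 1)[0]
        budget = propagate_uncertainty(pre.spectrum(r, c), delta_E=0.0, delta_I=0.0)
        assert budget.d_cd_percent == pytest.approx(0.0, abs=1e-12)

    def test_baseline_only_closed_form(self, cube_noise_free_pre):
        """Bands with zero-intensity margins >= delta_E: limit component
        vanishes and the budget reduces to the baseline closed form."""
        pre, truth = cube_noise_free_pre
        r, c = np.argwhere(truth.mask == 1)[0]
        spec = pre.spectrum(r, c)
        delta_I = 1.0
        budget = propagate_uncertainty(spec, delta_E=10.0, delta_I=delta_I)
        from ramancd.quantify import snapped_width

        w_ch = snapped_width(spec.wavenumbers, L_RANGE.ch)
        w_cd = snapped_width(spec.wavenumbers, L_RANGE.cd)
        a_ch, a_cd = budget.a_ch, budget.a_cd
        total = a_ch + a_cd
        expected = (
            100.0
            / total**2
            * np.hypot(a_ch * delta_I * w_cd, a_cd * delta_I * w_ch)
        )
        assert budget.d_a_ch == pytest.approx(delta_I * w_ch, rel=1e-6)
        assert budget.d_a_cd == pytest.approx(delta_I * w_cd, rel=1e-6)
        assert budget.d_cd_percent == pytest.approx(expected, rel=1e-6)

    def test_homogeneity_under_rescaling(self, cube_noise_free_pre):
        """Scaling intensities and delta_I together leaves the CD% error
        unchanged."""
        pre, truth = cube_noise_free_pre
        r, c = np.argwhere(truth.mask == 1)[0]
        spec = pre.spectrum(r, c)
        scale = 4.0
        a = propagate_uncertainty(spec, delta_E=10.0, delta_I=1.0)
        b = propagate_uncertainty(
            spec.with_intensities(spec.intensities * scale),
            delta_E=10.0,
            delta_I=1.0 * scale,
        )
        assert b.d_cd_percent == pytest.approx(a.d_cd_percent, rel=1e-9)


class TestClosedFormUtilities:
    def test_rayleigh_at_instrument_configuration(self):
        value = rayleigh_resolution(532, 0.5)
        assert value == pytest.approx(649.04)
        assert round(value, -1) == 650

    def test_rayleigh_cancellation(self):
        assert rayleigh_resolution(500, 0.61) == pytest.approx(500.0)

    def test_rayleigh_na_proportionality(self):
        assert rayleigh_resolution(532, 1.0) == pytest.approx(
            rayleigh_resolution(532, 0.5) / 2
        )

    @pytest.mark.parametrize(
        "dims,expected",
        [
            ((500, 50, 2), (250, 25, 6250)),
            ((400, 50, 2), (200, 25, 5000)),
            ((600, 50, 2), (300, 25, 7500)),
        ],
    )
    def test_scan_grid(self, dims, expected):
        assert scan_grid(*dims) == expected

    def test_scan_grid_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            scan_grid(0, 50, 2)
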