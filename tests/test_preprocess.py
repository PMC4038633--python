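"""Fourier smoothing, baseline correction and NADH normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from collafluor.preprocess import (
    NormalizedSpectrum,
    PreprocessConfig,
    PreprocessError,
    baseline_correct,
    fourier_smooth,
    normalize_max,
    preprocess,
    smoothing_passband,
)
from collafluor.spectra import Spectrum

from conftest import gaussian_spectrum


class TestFourierSmooth:
    def test_constant_signal_is_fixed_point(self, grid):
        s = Spectrum(grid, np.full(len(grid), 3.25))
        out = fourier_smooth(s, 0.8)
        np.testing.assert_allclose(out.intensities, s.intensities, atol=1e-12)

    def test_fraction_zero_is_identity(self, two_peak_spectrum):
        out = fourier_smooth(two_peak_spectrum, 0.0)
        np.testing.assert_array_equal(out.intensities, two_peak_spectrum.intensities)

    def test_low_frequency_sinusoid_passes(self, grid):
        n = len(grid)
        untapered, _ = smoothing_passband(n, 0.8)
        k = untapered // 2  # well inside the unit-gain band
        y = 2.0 + np.sin(2 * np.pi * k * np.arange(n) / n)
        out = fourier_smooth(Spectrum(grid, y), 0.8)
        np.testing.assert_allclose(out.intensities, y, rtol=1e-6, atol=1e-9)

    def test_high_frequency_sinusoid_attenuated(self, grid):
        n = len(grid)
        _, kept = smoothing_passband(n, 0.8)
        k = kept + 20  # beyond the retained band
        y = 2.0 + np.sin(2 * np.pi * k * np.arange(n) / n)
        out = fourier_smooth(Spectrum(grid, y), 0.8)
        residual_amp = np.max(np.abs(out.intensities - 2.0))
        assert residual_amp <= 0.1  # >= 90% attenuation

    def test_dc_mean_preserved(self, grid, rng):
        y = rng.random(len(grid)) + 1.0
        out = fourier_smooth(Spectrum(grid, y), 0.8)
        assert abs(out.intensities.mean() - y.mean()) <= 1e-9 * abs(y.mean())

    def test_nonuniform_grid_rejected(self):
        wl = np.sort(np.random.default_rng(0).uniform(350, 460, 50))
        with pytest.raises(PreprocessError, match="resample"):
            fourier_smooth(Spectrum(wl, np.ones(50)), 0.5)


class TestBaselineCorrect:
    def test_linear_spectrum_zeroed(self, grid):
        s = Spectrum(grid, 0.3 + 0.01 * (grid - grid[0]))
        out = baseline_correct(s)
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-12)

    def test_zero_endpoint_spectrum_unchanged(self, grid):
        y = np.sin(np.pi * (grid - grid[0]) / (grid[-1] - grid[0]))  # 0 at ends
        s = Spectrum(grid, y)
        out = baseline_correct(s)
        np.testing.assert_allclose(out.intensities, y, atol=1e-12)

    def test_quadratic_bump_recovered_exactly(self, grid):
        x = (grid - grid[0]) / (grid[-1] - grid[0])
        bump = x * (1 - x)  # zero at both ends
        trend = 1.7 - 0.004 * (grid - grid[0])
        out = baseline_correct(Spectrum(grid, bump + trend))
        np.testing.assert_allclose(out.intensities, bump, atol=1e-9)

    def test_projection_idempotent(self, two_peak_spectrum):
        once = baseline_correct(two_peak_spectrum)
        twice = baseline_correct(once)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)

    def test_output_exactly_zero_at_anchors(self, two_peak_spectrum):
        out = baseline_correct(two_peak_spectrum, 350.0, 500.0)
        wl = out.wavelengths
        assert out.intensities[np.argmin(np.abs(wl - 350))] == 0.0
        assert out.intensities[np.argmin(np.abs(wl - 500))] == 0.0

    def test_anchor_outside_coverage_errors(self, two_peak_spectrum):
        with pytest.raises(PreprocessError, match="coverage"):
            baseline_correct(two_peak_spectrum, 100.0, 500.0)


class TestNormalizeMax:
    def test_divides_by_global_max(self, two_peak_spectrum):
        s = Spectrum(two_peak_spectrum.wavelengths,
                     two_peak_spectrum.intensities * 2.0
                     / two_peak_spectrum.intensities.max())
        out = normalize_max(s)
        assert out.intensities.max() == pytest.approx(1.0, abs=1e-15)
        assert out.normalization_factor == pytest.approx(2.0)

    def test_idempotent(self, two_peak_spectrum):
        once = normalize_max(two_peak_spectrum)
        twice = normalize_max(once)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-15)
        assert twice.normalization_factor == pytest.approx(1.0)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariant(self, scale):
        s = gaussian_spectrum()
        a = normalize_max(s).intensities
        b = normalize_max(
            Spectrum(s.wavelengths, s.intensities * scale)
        ).intensities
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_records_nadh_peak_wavelength(self, two_peak_spectrum):
        out = normalize_max(two_peak_spectrum)
        assert 440 <= out.nadh_peak_wavelength <= 470
        assert out.warnings == []

    def test_flags_peak_outside_nadh_window(self, grid):
        s = gaussian_spectrum(grid, peaks=((380.0, 10.0, 1.0),))
        out = normalize_max(s)
        assert any("NADH window" in w for w in out.warnings)

    def test_two_separated_peaks_ratio(self, grid):
        # narrow, non-overlapping peaks: normalized collagen value is the
        # amplitude ratio 0.8 / 1.6 = 0.5 by closed form
        s = gaussian_spectrum(grid, peaks=((405.0, 5.0, 0.8), (455.0, 5.0, 1.6)))
        out = normalize_max(s)
        i405 = np.argmin(np.abs(grid - 405))
        assert out.intensities[i405] == pytest.approx(0.5, abs=1e-6)

    def test_all_zero_errors(self, grid):
        with pytest.raises(PreprocessError, match="undefined"):
            normalize_max(Spectrum(grid, np.zeros(len(grid))))


class TestPreprocessChain:
    def test_linear_spectrum_degenerates_at_normalize(self, grid):
        s = Spectrum(grid, 1.0 + 0.002 * (grid - grid[0]))
        with pytest.raises(PreprocessError, match="undefined"):
            preprocess(s, PreprocessConfig(smoothing_fraction=0.0))

    def test_max_exactly_one(self, two_peak_spectrum):
        out = preprocess(two_peak_spectrum)
        assert abs(out.intensities.max() - 1.0) <= 1e-12
        assert isinstance(out, NormalizedSpectrum)
        assert out.provenance["smoothing_fraction"] == 0.80

    def test_noisy_replicates_recover_noiseless_value(self, grid, rng):
        template = gaussian_spectrum(grid, baseline=(0.1, 0.0005))
        clean = preprocess(template)
        i405 = np.argmin(np.abs(grid - 405))
        truth = clean.intensities[i405]
        vals = []
        for _ in range(100):
            noisy = Spectrum(grid, template.intensities
                             + rng.normal(0, 0.01, len(grid)))
            vals.append(preprocess(noisy).intensities[i405])
        assert abs(np.mean(vals) - truth) < 0.02

    def test_rank_order_of_collagen_ratio_preserved(self, grid):
        amps = np.linspace(0.25, 0.9, 10)
        values = []
        for a in amps:
            s = gaussian_spectrum(grid, peaks=((405, 18, a), (455, 28, 1.0)),
                                  baseline=(0.2, 0.001))
            n = preprocess(s)
            values.append(n.intensities[np.argmin(np.abs(grid - 405))])
        assert np.all(np.diff(values) > 0)

    def test_invalid_smoothing_fraction(self, two_peak_spectrum):
        with pytest.raises(PreprocessError):
            fourier_smooth(two_peak_spectrum, 1.5)
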