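"""Preprocessing: smoothing, baseline, QC filtering, cropping, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.polynomial import polynomial as npoly

from skindepth import (
    DegenerateInputError,
    InvalidConfigError,
    InvalidInputError,
    MapPixel,
    PreprocessConfig,
    SpectralMap,
    Spectrum,
    correct_baseline,
    crop,
    filter_low_signal,
    preprocess_map,
    smooth_savitzky_golay,
    vector_normalize,
)


def sg_oracle(w, y, window, order):
    """Independent SG: explicit truncated-window least squares at every point."""
    half = window // 2
    out = np.empty(len(y))
    for i in range(len(y)):
        lo, hi = max(0, i - half), min(len(y), i + half + 1)
        t = w[lo:hi] - w[i]
        deg = min(order, hi - lo - 1)
        coef = npoly.polyfit(t, y[lo:hi], deg)
        out[i] = coef[0]
    return out


class TestSavitzkyGolay:
    def test_constant_is_fixed_point(self, axis, cfg):
        s = Spectrum(axis, np.full_like(axis, 100.0))
        out = smooth_savitzky_golay(s, cfg)
        np.testing.assert_allclose(out.intensities, 100.0, rtol=1e-12)

    @pytest.mark.parametrize("wavenumbers", [
        400.0 + 2.0 * np.arange(200),
        np.sort(np.random.default_rng(7).uniform(400, 800, 150)),  # irregular
    ], ids=["uniform", "irregular"])
    def test_quadratic_is_fixed_point(self, wavenumbers, cfg):
        """An order-2 filter reproduces y = 3w² − w + 5 exactly on any axis."""
        y = 3 * wavenumbers**2 - wavenumbers + 5
        out = smooth_savitzky_golay(Spectrum(wavenumbers, y), cfg)
        np.testing.assert_allclose(out.intensities, y, rtol=1e-9)

    def test_matches_least_squares_oracle(self, noisy_spectrum, cfg):
        """White noise, window 11: equals per-window LS fits, edges included."""
        out = smooth_savitzky_golay(noisy_spectrum, cfg)
        expected = sg_oracle(noisy_spectrum.wavenumbers,
                             noisy_spectrum.intensities, 11, 2)
        np.testing.assert_allclose(out.intensities, expected, atol=1e-8)

    def test_window_longer_than_spectrum_rejected(self):
        s = Spectrum(np.arange(5.0), np.ones(5))
        with pytest.raises(InvalidConfigError):
            smooth_savitzky_golay(s, PreprocessConfig(sg_window=11))

    def test_even_window_rejected(self):
        with pytest.raises(InvalidConfigError):
            PreprocessConfig(sg_window=10)

    @settings(max_examples=25, deadline=None)
    @given(coeffs=st.lists(st.floats(-5, 5), min_size=1, max_size=3),
           n=st.integers(30, 120))
    def test_low_degree_polynomials_are_fixed_points(self, coeffs, n):
        w = 400.0 + 3.0 * np.arange(n)
        y = npoly.polyval((w - w[0]) / 100.0, coeffs)
        out = smooth_savitzky_golay(Spectrum(w, y), PreprocessConfig())
        np.testing.assert_allclose(out.intensities, y, atol=1e-8 * (1 + np.abs(y).max()))


class TestBaseline:
    def test_pure_degree7_polynomial_removed(self, axis, cfg):
        t = (axis - axis[0]) / (axis[-1] - axis[0])
        y = 1000 * (1 + t - 3 * t**2 + t**3 - 0.5 * t**5 + 2 * t**7)
        out = correct_baseline(Spectrum(axis, y), cfg)
        assert np.max(np.abs(out.intensities)) < 1e-6 * np.ptp(y)

    def test_all_zero_input_stays_zero(self, axis, cfg):
        out = correct_baseline(Spectrum(axis, np.zeros_like(axis)), cfg)
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-9)

    def test_peak_heights_preserved_within_5_percent(self, axis, cfg):
        """Degree-3 baseline + two isolated Gaussians; oracle fits the
        polynomial on the known peak-free channels only."""
        t = (axis - axis[0]) / (axis[-1] - axis[0])
        baseline = 2000 * (1 + 0.5 * t - t**2 + 0.3 * t**3)
        peaks = (800 * np.exp(-0.5 * ((axis - 700) / 10) ** 2)
                 + 600 * np.exp(-0.5 * ((axis - 1600) / 12) ** 2))
        s = Spectrum(axis, baseline + peaks)
        out = correct_baseline(s, cfg)
        # oracle: true baseline is known exactly on peak-free channels
        free = (np.abs(axis - 700) > 60) & (np.abs(axis - 1600) > 72)
        coef = npoly.polyfit(t[free], (baseline + peaks)[free], 7)
        oracle_corrected = baseline + peaks - npoly.polyval(t, coef)
        for pos, height in ((700, 800), (1600, 600)):
            i = np.argmin(np.abs(axis - pos))
            assert out.intensities[i] == pytest.approx(height, rel=0.05)
            assert oracle_corrected[i] == pytest.approx(height, rel=0.05)

    def test_too_short_spectrum_rejected(self, cfg):
        s = Spectrum(np.arange(6.0), np.ones(6))
        with pytest.raises(InvalidInputError):
            correct_baseline(s, cfg)

    def test_coefficients_recorded_in_meta(self, axis, cfg):
        out = correct_baseline(Spectrum(axis, np.ones_like(axis)), cfg)
        assert len(out.meta["baseline_coefficients"]) == cfg.baseline_degree + 1


def _map_with_band_peaks(axis, band_values, step=5.0):
    """One-column map whose i-th pixel peaks at band_values[i] in 1530–1730."""
    pixels = []
    for i, value in enumerate(band_values):
        y = 50.0 + (value - 50.0) * np.exp(-0.5 * ((axis - 1630) / 20) ** 2)
        pixels.append(MapPixel(0.0, step * i, Spectrum(axis, y)))
    return SpectralMap(pixels, step=step)


class TestLowSignalFilter:
    def test_strict_threshold_boundary(self, axis, cfg):
        """399 cts in band → suppressed; exactly 400 cts → retained."""
        m = _map_with_band_peaks(axis, [399.0, 400.0, 1200.0])
        out = filter_low_signal(m, cfg)
        assert [p.y for p in out.pixels] == [5.0, 10.0]
        assert out.meta["suppressed_pixels"] == [(0.0, 0.0)]

    def test_identity_when_all_pixels_pass(self, axis, cfg):
        m = _map_with_band_peaks(axis, [500.0, 800.0, 1200.0])
        out = filter_low_signal(m, cfg)
        assert len(out) == len(m)
        for a, b in zip(m.pixels, out.pixels):
            np.testing.assert_array_equal(a.spectrum.intensities,
                                          b.spectrum.intensities)

    def test_band_outside_axis_rejected(self, cfg):
        w = np.linspace(400, 800, 100)
        m = SpectralMap([MapPixel(0, 0, Spectrum(w, np.ones(100)))])
        with pytest.raises(InvalidConfigError):
            filter_low_signal(m, cfg)

    def test_cached_meta_value_used_after_crop(self, axis, cfg):
        m = _map_with_band_peaks(axis, [1200.0])
        m.pixels[0].spectrum.meta["qc_signal_cts"] = 10.0
        cropped = SpectralMap(
            [MapPixel(p.x, p.y, crop(p.spectrum, cfg)) for p in m.pixels],
            step=m.step)
        out = filter_low_signal(cropped, cfg)
        assert len(out) == 0  # cached value 10 < 400 wins once band is gone


class TestCrop:
    def test_inclusive_bounds(self, cfg):
        s = Spectrum(np.array([399.0, 400.0, 785.0, 786.0]), np.arange(4.0))
        out = crop(s, cfg)
        np.testing.assert_array_equal(out.wavenumbers, [400.0, 785.0])
        np.testing.assert_array_equal(out.intensities, [1.0, 2.0])

    def test_full_range_crop_is_identity(self, axis):
        s = Spectrum(axis, np.arange(len(axis), dtype=float))
        out = crop(s, PreprocessConfig(crop_band=(axis[0], axis[-1])))
        np.testing.assert_array_equal(out.wavenumbers, s.wavenumbers)
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_band_within_study_window(self, axis, cfg):
        s = Spectrum(axis, np.ones_like(axis))
        out = crop(s, cfg)
        assert out.wavenumbers.min() >= 400.0
        assert out.wavenumbers.max() <= 785.0

    def test_empty_intersection_rejected(self, cfg):
        s = Spectrum(np.array([1000.0, 1100.0]), np.ones(2))
        with pytest.raises(InvalidInputError):
            crop(s, PreprocessConfig(crop_band=(100.0, 200.0)))


class TestVectorNormalize:
    def test_three_four_five(self):
        out = vector_normalize(Spectrum(np.array([1.0, 2.0]), np.array([3.0, 4.0])))
        np.testing.assert_allclose(out.intensities, [0.6, 0.8])

    def test_unit_norm(self, noisy_spectrum):
        out = vector_normalize(noisy_spectrum)
        assert np.linalg.norm(out.intensities) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(1e-6, 1e6))
    def test_scale_invariance(self, scale):
        w = np.arange(10.0)
        y = np.sin(w) + 2.0
        a = vector_normalize(Spectrum(w, y))
        b = vector_normalize(Spectrum(w, scale * y))
        np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            vector_normalize(Spectrum(np.arange(3.0), np.zeros(3)))


class TestPreprocessMap:
    def test_surviving_pixels_unit_norm_in_window(self, sim_map, cfg):
        smap, _ = sim_map
        out = preprocess_map(smap, cfg)
        assert 0 < len(out) <= len(smap)
        for p in out.pixels:
            assert np.linalg.norm(p.spectrum.intensities) == pytest.approx(1.0)
            assert p.spectrum.wavenumbers.min() >= 400.0
            assert p.spectrum.wavenumbers.max() <= 785.0
        counts = out.meta["pixel_counts"]
        assert counts["input"] == 93 and counts["output"] == len(out)

    def test_sub_threshold_pixel_removed(self, axis, cfg):
        m = _map_with_band_peaks(axis, [1200.0, 399.0, 1200.0])
        out = preprocess_map(m, cfg)
        assert len(out) == len(m) - 1

    def test_deterministic(self, sim_map, cfg):
        smap, _ = sim_map
        a = preprocess_map(smap, cfg)
        b = preprocess_map(smap, cfg)
        for pa, pb in zip(a.pixels, b.pixels):
            np.testing.assert_array_equal(pa.spectrum.intensities,
                                          pb.spectrum.intensities)

    def test_second_pass_is_near_identity(self, sim_map, cfg):
        """Re-running on an already-preprocessed map must not error and must
        keep the same pixels with nearly unchanged (unit-norm) spectra."""
        smap, _ = sim_map
        once = preprocess_map(smap, cfg)
        twice = preprocess_map(once, cfg)
        assert len(twice) == len(once)
        for pa, pb in zip(once.pixels, twice.pixels):
            cos = float(np.dot(pa.spectrum.intensities, pb.spectrum.intensities))
            assert cos > 0.9
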