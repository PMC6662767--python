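"""Acoustic-parameter contracts: spectra, snippet medians, validity gates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

import vocalshift as vs
from vocalshift.detect import CallSegment
from vocalshift.features import (FeatureParams, fundamental_autocorr,
                                 magnitude_spectrum, peak_min_max_bandwidth,
                                 shannon_entropy, snippet_median,
                                 snippet_windows, spectral_centroid,
                                 wiener_entropy)

FS = 192000.0


def _tone(freq, duration_s=0.05, amp=0.5, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _stack(f0, n_harm, duration_s=0.05, fs=FS):
    call = vs.CallSpec(duration_s=duration_s, fundamental_hz=f0,
                       n_harmonics=n_harm, amplitude=0.2)
    return vs.synthesize_call(call, fs)


class TestMagnitudeSpectrum:
    def test_tone_peak_location(self):
        freqs, mags = magnitude_spectrum(_tone(10000), FS)
        binw = freqs[1] - freqs[0]
        assert abs(freqs[np.argmax(mags)] - 10000) <= binw

    def test_amplitude_scaling(self):
        x = _tone(5000)
        _, m1 = magnitude_spectrum(x, FS)
        _, m2 = magnitude_spectrum(2 * x, FS)
        np.testing.assert_allclose(m2, 2 * m1, rtol=1e-9, atol=1e-9)

    def test_zero_signal(self):
        _, mags = magnitude_spectrum(np.zeros(1024), FS)
        np.testing.assert_array_equal(mags, 0.0)


class TestBandwidth:
    def test_single_tone_zero_bandwidth(self):
        freqs, mags = magnitude_spectrum(_tone(10000, 0.02), FS)
        peak, fmin, fmax, bw = peak_min_max_bandwidth(freqs, mags, 25.0)
        binw = freqs[1] - freqs[0]
        assert abs(peak - 10000) <= binw
        # windowed tone: the -25 dB width spans a handful of bins only
        assert bw <= 30 * binw

    def test_tone_30db_down_excluded(self):
        # designed line spectrum: second tone 30 dB below the first
        freqs = np.arange(0, 50000.0, 100.0)
        mags = np.full_like(freqs, 1e-6)
        mags[np.searchsorted(freqs, 10000.0)] = 1.0
        mags[np.searchsorted(freqs, 20000.0)] = 10 ** (-30 / 20)
        peak, fmin, fmax, bw = peak_min_max_bandwidth(freqs, mags, 25.0)
        assert peak == 10000.0
        assert fmax < 20000.0            # -30 dB tone outside the -25 dB band

    def test_tone_20db_down_included(self):
        freqs = np.arange(0, 50000.0, 100.0)
        mags = np.full_like(freqs, 1e-6)
        mags[np.searchsorted(freqs, 10000.0)] = 1.0
        mags[np.searchsorted(freqs, 20000.0)] = 10 ** (-20 / 20)
        _, _, fmax, _ = peak_min_max_bandwidth(freqs, mags, 25.0)
        assert fmax == 20000.0

    def test_white_noise_wide_band(self, rng):
        freqs, mags = magnitude_spectrum(rng.standard_normal(8192), FS)
        _, fmin, fmax, bw = peak_min_max_bandwidth(freqs, mags, 25.0)
        assert bw > 0.8 * freqs[-1]

    def test_flat_zero_spectrum_undefined(self):
        freqs = np.arange(10.0)
        out = peak_min_max_bandwidth(freqs, np.zeros(10), 25.0)
        assert all(np.isnan(v) for v in out)

    def test_ordering_invariant(self, small_session_calls):
        df = small_session_calls
        assert (df.min_freq_hz <= df.peak_freq_hz).all()
        assert (df.peak_freq_hz <= df.max_freq_hz).all()
        np.testing.assert_allclose(df.bandwidth_hz,
                                   df.max_freq_hz - df.min_freq_hz)


class TestSnippets:
    def test_window_count_law(self):
        starts, w = snippet_windows(1000, 0.10, 0.09)
        assert w == 100
        assert len(starts) == 11          # floor((1000-100)/90)+1

    def test_constant_function(self):
        assert snippet_median(np.ones(500), lambda s: 3.0) == 3.0

    def test_median_is_middle_order_statistic(self):
        vals = iter([5.0, 1.0, 3.0, 2.0, 4.0, 9.0, 0.0, 7.0, 8.0, 6.0, 4.5])
        out = snippet_median(np.zeros(1000), lambda s: next(vals))
        assert out == 4.5                 # median of the 11 snippet values


class TestCentroid:
    def test_tone(self):
        freqs, mags = magnitude_spectrum(_tone(10000, 0.01), FS)
        c = spectral_centroid(freqs, mags, (500, 60000))
        assert c == pytest.approx(10000, abs=200)

    def test_two_equal_tones_symmetric(self):
        x = _tone(10000, 0.01) + _tone(20000, 0.01)
        freqs, mags = magnitude_spectrum(x, FS)
        c = spectral_centroid(freqs, mags, (500, 60000))
        assert c == pytest.approx(15000, abs=300)

    def test_harmonic_stack_matches_line_spectrum(self):
        f0, n = 2000.0, 10
        x = _stack(f0, n)
        c = snippet_median(
            x, lambda s: spectral_centroid(
                *magnitude_spectrum(s, FS), (500, 60000)))
        expected = vs.true_centroid(f0, n, 0.0)
        assert c == pytest.approx(expected, rel=0.02)

    def test_zero_in_range_power_undefined(self):
        freqs = np.arange(0, 96000.0, 100.0)
        mags = np.where(freqs < 20000, 1.0, 0.0)
        assert np.isnan(spectral_centroid(freqs, mags, (50000, 60000)))


class TestFundamental:
    def test_pure_tone_pitch(self):
        f = fundamental_autocorr(_tone(2000, 0.01), FS)
        lag = round(FS / 2000)
        quantum = FS / lag - FS / (lag + 1)
        assert abs(f - 2000) <= 2 * quantum

    def test_harmonic_stack_pitch(self):
        x = _stack(3000.0, 8, duration_s=0.01)
        f = fundamental_autocorr(x, FS)
        lag = round(FS / 3000)
        quantum = FS / lag - FS / (lag + 1)
        assert abs(f - 3000) <= 2 * quantum

    def test_white_noise_unvoiced(self, rng):
        assert np.isnan(fundamental_autocorr(rng.standard_normal(2000), FS))


class TestEntropies:
    def test_white_noise_flatness_high(self, rng):
        _, mags = magnitude_spectrum(rng.standard_normal(4096), FS)
        assert wiener_entropy(mags) >= 0.9

    def test_tone_flatness_low(self):
        _, mags = magnitude_spectrum(_tone(10000, 0.02), FS)
        assert wiener_entropy(mags) <= 0.05

    def test_flatness_scale_invariant(self, rng):
        _, mags = magnitude_spectrum(rng.standard_normal(4096), FS)
        assert wiener_entropy(5 * mags) == pytest.approx(wiener_entropy(mags))

    def test_shannon_uniform(self):
        assert shannon_entropy(np.ones(64)) == pytest.approx(6.0)

    def test_shannon_single_bin(self):
        v = np.zeros(64)
        v[3] = 1.0
        assert shannon_entropy(v) == 0.0

    def test_shannon_noise_exceeds_tone(self, rng):
        _, m_noise = magnitude_spectrum(rng.standard_normal(4096), FS)
        _, m_tone = magnitude_spectrum(_tone(10000, 0.02), FS)
        assert shannon_entropy(m_noise ** 2) > shannon_entropy(m_tone ** 2)

    def test_all_zero_undefined(self):
        assert np.isnan(shannon_entropy(np.zeros(8)))
        assert np.isnan(wiener_entropy(np.zeros(8)))


class TestComposition:
    def _features_for(self, wave):
        seg = CallSegment(0.0, len(wave) / FS, wave)
        return vs.compute_features(seg, FS)

    def test_valid_call_inside_gates(self):
        f = self._features_for(_stack(2000.0, 12))
        assert f.is_valid
        assert 500 <= f.fundamental_hz <= 5000
        assert f.centroid_hz < 80000

    def test_high_fundamental_invalid(self):
        f = self._features_for(_stack(6000.0, 3))
        assert not f.is_valid

    def test_deterministic(self):
        a = self._features_for(_stack(2500.0, 10))
        b = self._features_for(_stack(2500.0, 10))
        assert a == b

    def test_batch_centroid_error_vs_truth(self, small_session,
                                           small_session_calls):
        df = small_session_calls
        err = np.abs(df.centroid_hz / 1000.0 - df.true_centroid_khz)
        assert err.mean() <= 1.0         # kHz, at default SNR

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(scale=st_h.floats(0.1, 10.0))
    def test_scale_invariance(self, scale):
        base = self._features_for(_stack(2500.0, 10))
        scaled = self._features_for(_stack(2500.0, 10) * scale)
        assert scaled.centroid_hz == pytest.approx(base.centroid_hz, rel=1e-6)
        assert scaled.fundamental_hz == pytest.approx(base.fundamental_hz,
                                                      rel=1e-6)
        assert scaled.wiener_entropy == pytest.approx(base.wiener_entropy,
                                                      rel=1e-6)
        assert scaled.rms == pytest.approx(base.rms * scale, rel=1e-6)
        assert scaled.peak_to_peak == pytest.approx(base.peak_to_peak * scale,
                                                    rel=1e-6)
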