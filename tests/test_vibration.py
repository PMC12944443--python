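"""Sliding RMS, transfer ratios, gain estimation, band-pass and
spectral integration to velocity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seatvib.errors import ConfigError, ContractError, SessionDataError
from seatvib.vibration import (
    bandpass,
    differential_acceleration,
    estimate_gain_k,
    sliding_rms,
    spectral_velocity,
    vtr,
    vtr_cam,
)


def brute_force_rms(x, half, detrend):
    """Independent O(N*W) loop implementing the windowed RMS definition."""
    x = np.atleast_2d(x.T).T if x.ndim == 1 else x
    n = x.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        w = x[max(0, i - half) : min(n, i + half + 1)]
        w = w[np.all(np.isfinite(w), axis=1)]
        if w.shape[0] == 0:
            continue
        if detrend:
            w = w - w.mean(axis=0)
        out[i] = np.sqrt(np.mean(np.sum(w**2, axis=1)))
    return out


class TestSlidingRms:
    def test_constant_signal_detrends_to_zero(self):
        x = np.tile([1.0, -2.0, 9.81], (100, 1))
        series = sliding_rms(x, fs=20.0, window=2.0, detrend=True)
        np.testing.assert_allclose(series.value, 0.0, atol=1e-12)

    def test_sinusoid_rms_is_amplitude_over_sqrt2(self):
        fs, amp = 100.0, 1.7
        t = np.arange(4000) / fs
        x = np.zeros((t.size, 3))
        x[:, 1] = amp * np.sin(2 * np.pi * 5.0 * t)
        series = sliding_rms(x, fs=fs, window=10.0)
        mid = series.value[~series.truncated]
        np.testing.assert_allclose(mid, amp / np.sqrt(2), rtol=0.01)

    @pytest.mark.parametrize("detrend", [True, False])
    @pytest.mark.parametrize("n", [7, 50])
    def test_matches_brute_force_loop(self, rng, detrend, n):
        x = rng.normal(size=(n, 3)) + 9.81
        series = sliding_rms(x, fs=10.0, window=0.5, detrend=detrend)
        half = int(round(0.5 * 10.0 / 2))
        np.testing.assert_allclose(series.value, brute_force_rms(x, half, detrend), atol=1e-9)

    def test_nan_rows_are_skipped_like_brute_force(self, rng):
        x = rng.normal(size=(60, 3))
        x[10:15] = np.nan
        series = sliding_rms(x, fs=10.0, window=1.0, detrend=True)
        np.testing.assert_allclose(
            series.value, brute_force_rms(x, 5, True), atol=1e-9
        )

    def test_edges_flagged_truncated(self):
        series = sliding_rms(np.random.default_rng(0).normal(size=(50, 3)), fs=10.0, window=2.0)
        assert series.truncated[:10].all() and series.truncated[-10:].all()
        assert not series.truncated[10:-10].any()

    def test_too_short_window_rejected(self):
        with pytest.raises(ConfigError):
            sliding_rms(np.zeros((10, 3)), fs=10.0, window=0.05)


class TestVtr:
    def test_identical_signals_give_unity(self, rng):
        a = rng.normal(size=(200, 3))
        series = vtr(a, a, fs=20.0)
        np.testing.assert_allclose(series.value, 1.0, atol=1e-9)

    def test_linear_gain_recovered(self, rng):
        a_seat = rng.normal(size=(200, 3))
        series = vtr(0.7 * a_seat, a_seat, fs=20.0)
        np.testing.assert_allclose(series.value, 0.7, atol=1e-9)

    def test_independent_noise_raises_median_above_gain(self, rng):
        fs, k = 100.0, 0.9
        t = np.arange(3000) / fs
        a_seat = np.column_stack(
            [0.3 * np.sin(2 * np.pi * 4 * t), 0.5 * np.sin(2 * np.pi * 2 * t), np.zeros_like(t)]
        )
        a_body = k * a_seat + rng.normal(0, 0.1, a_seat.shape)
        series = vtr(a_body, a_seat, fs=fs)
        assert np.nanmedian(series.value) > k

    def test_zero_seat_yields_nan(self):
        series = vtr(np.random.default_rng(0).normal(size=(50, 3)), np.zeros((50, 3)), fs=10.0)
        assert np.isnan(series.value).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            vtr(np.zeros((10, 3)), np.zeros((9, 3)), fs=10.0)


class TestVtrCam:
    def test_camera_following_seat_scores_zero(self, rng):
        a = rng.normal(size=(200, 3))
        series = vtr_cam(a, a, fs=20.0)
        np.testing.assert_allclose(series.value, 0.0, atol=1e-9)

    def test_doubled_seat_motion_scores_unity(self, rng):
        a_seat = rng.normal(size=(200, 3))
        series = vtr_cam(2.0 * a_seat, a_seat, fs=20.0)
        np.testing.assert_allclose(series.value, 1.0, atol=1e-9)

    def test_resonant_burst_peaks_during_excitation(self):
        fs = 100.0
        t = np.arange(3000) / fs
        a_seat = np.column_stack([np.zeros_like(t), 0.5 * np.sin(2 * np.pi * 4 * t), np.zeros_like(t)])
        burst = (t > 10) & (t < 20)
        res = np.column_stack([0.8 * np.sin(2 * np.pi * 6 * t) * burst, np.zeros_like(t), np.zeros_like(t)])
        series = vtr_cam(a_seat + res, a_seat, fs=fs)
        inside = series.value[(t > 12) & (t < 18)]
        outside = series.value[(t > 2) & (t < 8)]
        assert np.nanmedian(inside) > 5 * np.nanmedian(outside)


class TestGainEstimation:
    def test_exact_linear_relation(self, rng):
        a_seat = rng.normal(size=(1000, 3))
        est = estimate_gain_k(0.8 * a_seat, a_seat)
        assert est.k == pytest.approx(0.8, abs=1e-9)
        assert est.residual_fraction == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_within_tolerance(self, rng):
        fs = 100.0
        t = np.arange(1000) / fs  # 10 s
        a_seat = np.column_stack(
            [0.5 * np.sin(2 * np.pi * 4 * t), 0.8 * np.sin(2 * np.pi * 2 * t + 1), 0.3 * np.sin(2 * np.pi * 8 * t)]
        )
        signal_power = np.mean((0.8 * a_seat) ** 2)
        noise_sd = np.sqrt(signal_power / 10.0)  # SNR 10
        errs = []
        for _ in range(20):
            a_body = 0.8 * a_seat + rng.normal(0, noise_sd, a_seat.shape)
            errs.append(abs(estimate_gain_k(a_body, a_seat, fs=fs).k - 0.8))
        assert np.mean(errs) < 0.05

    def test_orthogonal_signals_give_zero(self):
        t = np.arange(1000) / 100.0
        a_seat = np.column_stack([np.sin(2 * np.pi * 5 * t), np.zeros_like(t), np.zeros_like(t)])
        a_body = np.column_stack([np.zeros_like(t), np.cos(2 * np.pi * 3 * t), np.zeros_like(t)])
        assert estimate_gain_k(a_body, a_seat).k == pytest.approx(0.0, abs=1e-9)

    def test_zero_seat_energy_rejected(self):
        with pytest.raises(SessionDataError):
            estimate_gain_k(np.random.default_rng(0).normal(size=(600, 3)), np.zeros((600, 3)))

    def test_short_segment_rejected(self):
        with pytest.raises(ContractError):
            estimate_gain_k(np.zeros((100, 3)), np.ones((100, 3)), fs=100.0)


class TestDifferentialAcceleration:
    def test_matched_gain_cancels(self, rng):
        a_seat = rng.normal(size=(100, 3))
        d = differential_acceleration(0.8 * a_seat, a_seat, k=0.8)
        np.testing.assert_allclose(d.a_diff, 0.0, atol=1e-12)

    def test_zero_gain_returns_body(self, rng):
        a_body = rng.normal(size=(100, 3))
        d = differential_acceleration(a_body, rng.normal(size=(100, 3)), k=0.0)
        np.testing.assert_array_equal(d.a_diff, a_body)

    def test_matches_elementwise_oracle(self, rng):
        a_body, a_seat, k = rng.normal(size=(50, 3)), rng.normal(size=(50, 3)), 1.3
        d = differential_acceleration(a_body, a_seat, k=k)
        np.testing.assert_allclose(d.a_diff, a_body - k * a_seat, atol=1e-12)

    def test_negative_gain_warns(self):
        with pytest.warns(UserWarning):
            differential_acceleration(np.zeros((5, 3)), np.zeros((5, 3)), k=-0.5)


class TestBandpass:
    def test_midband_amplitude_preserved(self):
        fs = 100.0
        t = np.arange(2000) / fs
        y = bandpass(np.sin(2 * np.pi * 5 * t), fs)
        interior = y[200:-200]
        assert np.max(np.abs(interior)) == pytest.approx(1.0, abs=0.02)

    def test_dc_offset_removed(self):
        y = bandpass(np.full(2000, 3.0), fs=100.0)
        assert np.max(np.abs(y)) < 0.01

    def test_stopband_attenuation(self):
        fs = 200.0
        t = np.arange(4000) / fs
        low = bandpass(np.sin(2 * np.pi * 0.2 * t), fs)
        high = bandpass(np.sin(2 * np.pi * 40.0 * t), fs)
        assert np.max(np.abs(low[400:-400])) < 0.1
        assert np.max(np.abs(high[400:-400])) < 0.1

    def test_sampling_rate_guard(self):
        with pytest.raises(ConfigError):
            bandpass(np.zeros(100), fs=30.0, f_hi=20.0)


class TestSpectralVelocity:
    def test_sinusoid_amplitude_matches_analytic_integral(self):
        fs, f = 100.0, 5.0
        t = np.arange(int(20 * fs)) / fs
        a = np.sin(2 * np.pi * f * t)
        series = spectral_velocity(a, fs)
        interior = series.value[int(2 * fs) : -int(2 * fs)]
        expected = 1.0 / (2 * np.pi * f)
        assert np.max(interior) == pytest.approx(expected, rel=0.02)

    def test_below_cutoff_suppressed(self):
        fs, f = 100.0, 0.3
        t = np.arange(int(20 * fs)) / fs
        series = spectral_velocity(np.sin(2 * np.pi * f * t), fs, f_min=0.8)
        uncut = 1.0 / (2 * np.pi * f)
        assert np.max(series.value) < 0.05 * uncut

    def test_zero_input_zero_output(self):
        series = spectral_velocity(np.zeros((100, 3)), fs=100.0)
        np.testing.assert_array_equal(series.value, 0.0)

    def test_linearity(self, rng):
        a1, a2 = rng.normal(size=(512, 3)), rng.normal(size=(512, 3))
        v1 = spectral_velocity(a1, fs=100.0).vector
        v2 = spectral_velocity(a2, fs=100.0).vector
        v12 = spectral_velocity(a1 + a2, fs=100.0).vector
        np.testing.assert_allclose(v12, v1 + v2, atol=1e-9)

    def test_non_uniform_timestamps_rejected(self):
        t = np.array([0.0, 0.01, 0.025, 0.03])
        with pytest.raises(SessionDataError, match="align"):
            spectral_velocity(np.zeros(4), fs=100.0, t=t)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(c=st.floats(0.1, 50.0), seed=st.integers(0, 1000))
def test_vtr_scale_equivariance(c, seed):
    rng = np.random.default_rng(seed)
    a_body = rng.normal(size=(80, 3))
    a_seat = rng.normal(size=(80, 3))
    v1 = vtr(a_body, a_seat, fs=20.0).value
    v2 = vtr(c * a_body, c * a_seat, fs=20.0).value
    np.testing.assert_allclose(v2, v1, rtol=1e-9)


def test_doubling_seat_halves_vtr(rng):
    a_body = rng.normal(size=(80, 3))
    a_seat = rng.normal(size=(80, 3))
    v1 = vtr(a_body, a_seat, fs=20.0).value
    v2 = vtr(a_body, 2.0 * a_seat, fs=20.0).value
    np.testing.assert_allclose(v2, v1 / 2.0, rtol=1e-9)
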