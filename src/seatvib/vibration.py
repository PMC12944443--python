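"""Vibration-layer metrics.

Sliding detrended RMS of acceleration magnitude, seat-body and seat-camera
vibration transfer ratios (VTR), least-squares estimation of the passive
seat-to-body gain k, band-pass differential acceleration, and body
vibration velocity by spectral integration (division of the acceleration
spectrum by j*2*pi*f above a low cutoff).

Windows are centred on each sample with a duration of ``window`` seconds;
windows truncated by the session edges are still computed but flagged.
Records rejected by the quality mask enter these routines as NaN rows and
are excluded from every window average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from seatvib.errors import ConfigError, ContractError, SessionDataError

__all__ = [
    "MetricSeries",
    "DifferentialSignal",
    "GainEstimate",
    "sliding_rms",
    "vtr",
    "vtr_cam",
    "estimate_gain_k",
    "differential_acceleration",
    "bandpass",
    "spectral_velocity",
]

#: Denominator guard for RMS ratios, m/s^2.
RMS_EPS = 1e-6


@dataclass
class MetricSeries:
    """A time-indexed scalar metric with its window length.

    ``value`` holds the scalar series (NaN where undefined); ``truncated``
    flags samples whose centred window was clipped by a session edge.
    ``vector`` optionally carries the underlying per-axis series (used by
    the velocity metric).
    """

    t: np.ndarray
    value: np.ndarray
    window: float
    kind: str
    truncated: np.ndarray = field(default=None)  # type: ignore[assignment]
    vector: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.truncated is None:
            self.truncated = np.zeros(len(self.value), dtype=bool)


@dataclass
class DifferentialSignal:
    """Body acceleration minus the scaled seat contribution, per axis."""

    t: np.ndarray
    a_diff: np.ndarray  # (N, 3)
    k_used: float
    band: Optional[tuple] = None


@dataclass
class GainEstimate:
    """Least-squares passive gain with its residual energy fraction."""

    k: float
    residual_fraction: float


def _window_half(window: float, fs: float) -> int:
    half = int(round(window * fs / 2.0))
    if 2 * half + 1 < 2 and int(round(window * fs)) < 2:
        raise ConfigError(
            f"window of {window} s spans fewer than 2 samples at fs={fs} Hz"
        )
    return half


def _sliding_moments(x: np.ndarray, half: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NaN-aware windowed sums of x and x^2 and finite counts, per axis.

    Windows are index-centred: ``W(i) = [i-half, i+half]`` clipped to the
    array, so truncated edge windows use whatever samples exist.
    """
    n = x.shape[0]
    finite = np.all(np.isfinite(x), axis=1)
    xf = np.where(finite[:, None], x, 0.0)
    cs = np.concatenate([np.zeros((1, x.shape[1])), np.cumsum(xf, axis=0)])
    cs2 = np.concatenate([np.zeros((1, x.shape[1])), np.cumsum(xf * xf, axis=0)])
    cn = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    sums = cs[hi] - cs[lo]
    sums2 = cs2[hi] - cs2[lo]
    counts = cn[hi] - cn[lo]
    return sums, sums2, counts


def sliding_rms(
    x: np.ndarray,
    fs: float,
    window: float = 2.0,
    detrend: bool = True,
    t: np.ndarray | None = None,
) -> MetricSeries:
    """Centred sliding RMS of the vector magnitude of a signal.

    For each sample i the RMS of ``||x_j - mean_W||`` over the centred
    window is returned; with ``detrend`` the per-axis mean of the window
    is subtracted first, so constant offsets (gravity, bias) do not
    contribute.  NaN rows (masked-out records) are excluded from the
    window statistics; a window with no finite sample yields NaN.

    Accepts (N,) scalar or (N, 3) vector signals.
    """
    x = np.asarray(x, dtype=float)
    scalar_in = x.ndim == 1
    if scalar_in:
        x = x[:, None]
    n = x.shape[0]
    half = _window_half(window, fs)
    if detrend:
        # centring on the global mean leaves windowed variances unchanged
        # but avoids cancellation against large offsets (gravity)
        finite = np.all(np.isfinite(x), axis=1)
        if np.any(finite):
            x = x - x[finite].mean(axis=0)
    sums, sums2, counts = _sliding_moments(x, half)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_sq = sums2 / counts[:, None]
        if detrend:
            mean = sums / counts[:, None]
            per_axis = mean_sq - mean * mean
        else:
            per_axis = mean_sq
        per_axis = np.clip(per_axis, 0.0, None)
        value = np.sqrt(np.sum(per_axis, axis=1))
    value[counts == 0] = np.nan
    idx = np.arange(n)
    truncated = (idx - half < 0) | (idx + half + 1 > n)
    if t is None:
        t = idx / fs
    return MetricSeries(
        t=np.asarray(t, dtype=float), value=value, window=window, kind="rms", truncated=truncated
    )


def vtr(
    a_body: np.ndarray,
    a_seat: np.ndarray,
    fs: float,
    window: float = 2.0,
    t: np.ndarray | None = None,
    eps: float = RMS_EPS,
) -> MetricSeries:
    """Seat-to-body vibration transfer ratio: RMS_body / RMS_seat.

    A value near 1 means the body vibrates like the seat (passive
    transmission); below 1 attenuation; above 1 amplification.  Undefined
    (NaN) wherever the seat RMS falls below ``eps``.
    """
    a_body = np.asarray(a_body, dtype=float)
    a_seat = np.asarray(a_seat, dtype=float)
    if a_body.shape != a_seat.shape:
        raise ContractError("a_body and a_seat must have identical shapes")
    num = sliding_rms(a_body, fs, window, detrend=True, t=t)
    den = sliding_rms(a_seat, fs, window, detrend=True, t=t)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(den.value >= eps, num.value / den.value, np.nan)
    return MetricSeries(
        t=num.t, value=value, window=window, kind="vtr", truncated=num.truncated
    )


def vtr_cam(
    a_cam: np.ndarray,
    a_seat: np.ndarray,
    fs: float,
    window: float = 2.0,
    t: np.ndarray | None = None,
    eps: float = RMS_EPS,
) -> MetricSeries:
    """Seat-to-camera transfer ratio on the *relative* camera acceleration.

    The numerator RMS is computed on ``a_cam - a_seat``, so a camera
    rigidly following the seat scores 0 and mount resonances show up as
    peaks; the denominator is the seat RMS.
    """
    a_cam = np.asarray(a_cam, dtype=float)
    a_seat = np.asarray(a_seat, dtype=float)
    if a_cam.shape != a_seat.shape:
        raise ContractError("a_cam and a_seat must have identical shapes")
    num = sliding_rms(a_cam - a_seat, fs, window, detrend=True, t=t)
    den = sliding_rms(a_seat, fs, window, detrend=True, t=t)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(den.value >= eps, num.value / den.value, np.nan)
    return MetricSeries(
        t=num.t, value=value, window=window, kind="vtr_cam", truncated=num.truncated
    )


def estimate_gain_k(
    a_body: np.ndarray,
    a_seat: np.ndarray,
    fs: float | None = None,
    min_seconds: float = 5.0,
    eps: float = RMS_EPS,
) -> GainEstimate:
    """Passive seat-to-body gain by least squares on a passive segment.

    Minimises ``sum ||a_body - k a_seat||^2`` over the segment after
    removing the per-axis mean from both signals, giving the closed form
    ``k = <a_body, a_seat> / <a_seat, a_seat>`` on the stacked axes.
    NaN rows (masked records) are dropped.  Raises when the seat carries
    essentially no energy (k is then unidentifiable).
    """
    a_body = np.asarray(a_body, dtype=float)
    a_seat = np.asarray(a_seat, dtype=float)
    if a_body.shape != a_seat.shape:
        raise ContractError("a_body and a_seat must have identical shapes")
    ok = np.all(np.isfinite(a_body), axis=-1) & np.all(np.isfinite(a_seat), axis=-1)
    b = np.atleast_2d(a_body)[ok]
    s = np.atleast_2d(a_seat)[ok]
    if fs is not None and b.shape[0] / fs < min_seconds:
        raise ContractError(
            f"passive segment of {b.shape[0] / fs:.2f} s is shorter than {min_seconds} s"
        )
    b = b - b.mean(axis=0)
    s = s - s.mean(axis=0)
    denom = float(np.sum(s * s))
    if denom < eps**2 * max(1, s.size):
        raise SessionDataError("seat energy is near zero; gain k is unidentifiable")
    k = float(np.sum(b * s) / denom)
    resid = b - k * s
    total = float(np.sum(b * b))
    residual_fraction = float(np.sum(resid * resid) / total) if total > 0 else 0.0
    return GainEstimate(k=k, residual_fraction=residual_fraction)


def differential_acceleration(
    a_body: np.ndarray,
    a_seat: np.ndarray,
    k: float,
    t: np.ndarray | None = None,
) -> DifferentialSignal:
    """Per-axis differential acceleration ``a_body - k * a_seat``.

    Removes the component of body acceleration attributable to passive
    seat following, leaving the body's own (compensatory) motion.
    """
    a_body = np.asarray(a_body, dtype=float)
    a_seat = np.asarray(a_seat, dtype=float)
    if a_body.shape != a_seat.shape:
        raise ContractError("a_body and a_seat must have identical shapes")
    if k < 0:
        warnings.warn("negative passive gain k is physically unusual", stacklevel=2)
    if t is None:
        t = np.arange(a_body.shape[0], dtype=float)
    return DifferentialSignal(
        t=np.asarray(t, dtype=float), a_diff=a_body - k * a_seat, k_used=float(k)
    )


def bandpass(
    x: np.ndarray,
    fs: float,
    f_lo: float = 1.0,
    f_hi: float = 20.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase band-pass with offset removal.

    A Butterworth design applied forward-backward (no group delay); the
    passband preserves a mid-band sinusoid's amplitude within 2% and
    frequencies a decade outside the band are attenuated by well over
    20 dB.  The mean is removed so the output is offset-free.
    """
    if fs <= 2 * f_hi:
        raise ConfigError(f"fs={fs} Hz too low for an upper band edge of {f_hi} Hz")
    if not 0 < f_lo < f_hi:
        raise ConfigError("need 0 < f_lo < f_hi")
    x = np.asarray(x, dtype=float)
    sos = sps.butter(order, [f_lo, f_hi], btype="band", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x, axis=0)
    return y - y.mean(axis=0)


def spectral_velocity(
    a: np.ndarray,
    fs: float,
    f_min: float = 0.8,
    t: np.ndarray | None = None,
    window: float = 2.0,
) -> MetricSeries:
    """Vibration velocity by spectral integration of acceleration.

    Divides the acceleration spectrum by ``j 2 pi f`` for ``f >= f_min``
    and zeroes everything below the cutoff (quasi-static drift would
    otherwise blow up under the 1/f division), then inverse-transforms.
    The input must already be band-passed and mean-free and uniformly
    sampled.  The returned series is the per-sample velocity magnitude;
    the per-axis velocity is available as ``.vector``.
    """
    a = np.asarray(a, dtype=float)
    if t is not None:
        t = np.asarray(t, dtype=float)
        dt = np.diff(t)
        if dt.size and (np.max(dt) - np.min(dt)) > 0.01 / fs + 1e-12:
            raise SessionDataError(
                "timestamps are not uniform; run align_streams (or integrate per segment) first"
            )
    scalar_in = a.ndim == 1
    if scalar_in:
        a = a[:, None]
    n = a.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    A = np.fft.rfft(a, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1j * 2.0 * np.pi * freqs
        V = np.where(freqs[:, None] >= f_min, A / denom[:, None], 0.0)
    v = np.fft.irfft(V, n=n, axis=0).real
    mag = np.abs(v[:, 0]) if scalar_in else np.linalg.norm(v, axis=1)
    if t is None:
        t = np.arange(n) / fs
    return MetricSeries(
        t=t,
        value=mag,
        window=window,
        kind="velocity",
        vector=v[:, 0] if scalar_in else v,
    )
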