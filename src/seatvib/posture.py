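"""Postural compensation and geometric consistency metrics.

Rotational PCI: sliding RMS of the body-seat differential angular
velocity; low values mean the torso follows the seat rigidly, peaks mean
active reorientation.  Translational PCI: sliding RMS of each landmark's
finite-difference velocity relative to a neutral reference pose averaged
over a short static interval.  Axis-wise energy percentages quantify the
anisotropy of both the differential body vibration and the landmark
compensation velocities.  Anthropometric deviations (shoulder width,
nose-to-mid-shoulder) act as a stability check of the fused pipeline:
rigid geometry should survive de-jittering and world mapping unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from seatvib.errors import ConfigError, ContractError, SessionDataError
from seatvib.vibration import MetricSeries, sliding_rms, _sliding_moments, _window_half

__all__ = [
    "ReferencePose",
    "AxisEnergySummary",
    "AnthropometricReport",
    "rotational_pci",
    "reference_pose",
    "rtv",
    "translational_pci",
    "axis_energy_body",
    "axis_energy_landmark",
    "anthropometrics",
]

AXES = ("x", "y", "z")


@dataclass
class ReferencePose:
    """Neutral landmark positions averaged over a static interval."""

    p_nose: np.ndarray
    p_lsh: np.ndarray
    p_rsh: np.ndarray
    interval: tuple


@dataclass
class AxisEnergySummary:
    """Per-axis energy summary with percentage contributions.

    ``R`` holds the per-axis scalar summaries (mean sliding RMS for the
    body signal, mean windowed squared energy for landmark velocities);
    ``P`` the percentages summing to 100 when total energy is positive.
    """

    R: np.ndarray  # (3,)
    P: np.ndarray  # (3,) percentages, NaN when undefined
    defined: bool

    @property
    def dominant_axis(self) -> Optional[str]:
        if not self.defined:
            return None
        return AXES[int(np.argmax(self.R))]


@dataclass
class AnthropometricReport:
    """Deviation of reconstructed distances from tape-measured nominals."""

    t: np.ndarray
    e_sh: np.ndarray  # mm
    e_nm: np.ndarray  # mm
    summary: dict  # mean / max_abs per distance, mm


def rotational_pci(
    w_body: np.ndarray,
    w_seat: np.ndarray,
    fs: float,
    k_rot: float = 1.0,
    window: float = 2.0,
    t: np.ndarray | None = None,
) -> MetricSeries:
    """Rotational postural compensation index.

    ``w_diff = w_body - k_rot * w_seat`` (rad/s) and the PCI is the
    sliding RMS of its magnitude over the centred window.  No window
    detrending is applied: the differencing already removes the common
    base rotation.
    """
    w_body = np.asarray(w_body, dtype=float)
    w_seat = np.asarray(w_seat, dtype=float)
    if w_body.shape != w_seat.shape:
        raise ContractError("w_body and w_seat must have identical shapes")
    series = sliding_rms(w_body - k_rot * w_seat, fs, window, detrend=False, t=t)
    series.kind = "pci_rot"
    return series


def reference_pose(
    traj: dict,
    t: np.ndarray,
    interval: tuple = (0.0, 2.0),
    valid: np.ndarray | None = None,
) -> ReferencePose:
    """Neutral pose: per-landmark mean over valid samples in ``interval``."""
    t = np.asarray(t, dtype=float)
    t0, t1 = interval
    sel = (t >= t0) & (t <= t1)
    if valid is not None:
        sel &= np.asarray(valid, dtype=bool)
    means = {}
    for name in ("nose", "lsh", "rsh"):
        p = np.asarray(traj[name], dtype=float)
        rows = p[sel]
        rows = rows[np.all(np.isfinite(rows), axis=1)]
        if rows.shape[0] < 2:
            raise SessionDataError(
                f"fewer than 2 valid samples for {name} in [{t0}, {t1}] s; "
                "choose a different reference interval"
            )
        means[name] = rows.mean(axis=0)
    return ReferencePose(
        p_nose=means["nose"], p_lsh=means["lsh"], p_rsh=means["rsh"], interval=(t0, t1)
    )


def rtv(
    p_w: np.ndarray,
    t: np.ndarray,
    ref: np.ndarray,
    valid: np.ndarray | None = None,
    max_gap: float | None = None,
) -> np.ndarray:
    """Finite-difference translational velocity of a landmark's deviation
    from its reference.

    ``c(t) = p_w(t) - ref`` and ``v_i = (c_i - c_{i-1}) / (t_i - t_{i-1})``
    within contiguous runs of valid samples.  Differences are never taken
    across mask gaps (neighbours further apart than ``max_gap``, default
    twice the median sampling period); the first sample of each run has no
    velocity (NaN row).  The reference shifts c but cancels in the
    difference, so v is reference-invariant.
    """
    p_w = np.asarray(p_w, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(np.diff(t) == 0):
        raise SessionDataError("duplicate timestamps in trajectory")
    ok = np.all(np.isfinite(p_w), axis=1)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    if max_gap is None:
        dt_all = np.diff(t)
        max_gap = 2.0 * float(np.median(dt_all)) if dt_all.size else np.inf

    c = p_w - np.asarray(ref, dtype=float)
    v = np.full_like(p_w, np.nan)
    idx = np.flatnonzero(ok)
    if idx.size >= 2:
        prev, cur = idx[:-1], idx[1:]
        dt = t[cur] - t[prev]
        contiguous = dt <= max_gap
        v[cur[contiguous]] = (
            (c[cur[contiguous]] - c[prev[contiguous]]) / dt[contiguous][:, None]
        )
    return v


def translational_pci(
    v: np.ndarray,
    fs: float,
    window: float = 2.0,
    t: np.ndarray | None = None,
) -> MetricSeries:
    """Translational PCI: sliding RMS of the landmark velocity magnitude.

    No detrending: the velocity is already relative to the neutral
    reference.  NaN rows (run starts, masked frames) are excluded from
    the window statistics.
    """
    series = sliding_rms(np.asarray(v, dtype=float), fs, window, detrend=False, t=t)
    series.kind = "pci_trans"
    return series


def _valid_window_mean(
    per_axis: np.ndarray, counts: np.ndarray, full: int
) -> tuple[np.ndarray, bool]:
    """Average per-axis window statistics over windows fully inside valid
    runs (count == window size)."""
    sel = counts >= full
    if not np.any(sel):
        sel = counts > 0  # fall back to partial windows on very short input
    if not np.any(sel):
        return np.full(3, np.nan), False
    return per_axis[sel].mean(axis=0), True


def axis_energy_body(
    a_diff: np.ndarray,
    fs: float,
    window: float = 2.0,
    valid: np.ndarray | None = None,
) -> AxisEnergySummary:
    """Axis-wise contribution of the differential body vibration.

    The per-axis mean over the valid set is removed, a per-axis sliding
    RMS is computed, averaged over windows fully inside valid runs, and
    expressed as percentages of the summed axis RMS.
    """
    a = np.asarray(a_diff, dtype=float).copy()
    if valid is not None:
        a[~np.asarray(valid, dtype=bool)] = np.nan
    ok = np.all(np.isfinite(a), axis=1)
    if not np.any(ok):
        return AxisEnergySummary(R=np.full(3, np.nan), P=np.full(3, np.nan), defined=False)
    a = a - np.nanmean(np.where(ok[:, None], a, np.nan), axis=0)

    half = _window_half(window, fs)
    _, sums2, counts = _sliding_moments(a, half)
    with np.errstate(invalid="ignore", divide="ignore"):
        rms_axis = np.sqrt(sums2 / counts[:, None])
    R, any_win = _valid_window_mean(rms_axis, counts, 2 * half + 1)
    total = np.sum(R)
    if not any_win or not total > 0:
        return AxisEnergySummary(R=R, P=np.full(3, np.nan), defined=False)
    return AxisEnergySummary(R=R, P=100.0 * R / total, defined=True)


def axis_energy_landmark(
    v: np.ndarray,
    fs: float,
    window: float = 2.0,
) -> AxisEnergySummary:
    """Axis-wise energy ratios of a landmark's compensation velocity.

    Same windowing as the body variant but on squared velocity components
    (windowed mean-square energies, not their square roots), matching the
    energy definition used for landmark trajectories.
    """
    v = np.asarray(v, dtype=float)
    ok = np.all(np.isfinite(v), axis=1)
    if not np.any(ok):
        return AxisEnergySummary(R=np.full(3, np.nan), P=np.full(3, np.nan), defined=False)
    half = _window_half(window, fs)
    _, sums2, counts = _sliding_moments(v, half)
    with np.errstate(invalid="ignore", divide="ignore"):
        energy_axis = sums2 / counts[:, None]
    E, any_win = _valid_window_mean(energy_axis, counts, 2 * half + 1)
    total = np.sum(E)
    if not any_win or not total > 0:
        return AxisEnergySummary(R=E, P=np.full(3, np.nan), defined=False)
    return AxisEnergySummary(R=E, P=100.0 * E / total, defined=True)


def anthropometrics(
    traj: dict,
    d_sh_real: float,
    d_nm_real: float,
    t: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> AnthropometricReport:
    """Anthropometric deviations of the reconstructed skeleton, in mm.

    Shoulder width is the 3D distance between the shoulders; the
    nose-to-mid-shoulder distance uses the shoulder midpoint.  Deviations
    are measured against the tape-measured nominals; on mask-invalid
    frames they are NaN.
    """
    if not (d_sh_real > 0 and d_nm_real > 0):
        raise ConfigError("nominal anthropometric distances must be positive")
    p_nose = np.asarray(traj["nose"], dtype=float)
    p_lsh = np.asarray(traj["lsh"], dtype=float)
    p_rsh = np.asarray(traj["rsh"], dtype=float)
    n = p_nose.shape[0]
    if t is None:
        t = np.arange(n, dtype=float)

    d_sh = np.linalg.norm(p_lsh - p_rsh, axis=1)
    p_mid = 0.5 * (p_lsh + p_rsh)
    d_nm = np.linalg.norm(p_nose - p_mid, axis=1)
    e_sh = 1000.0 * (d_sh - d_sh_real)
    e_nm = 1000.0 * (d_nm - d_nm_real)
    if valid is not None:
        invalid = ~np.asarray(valid, dtype=bool)
        e_sh = e_sh.copy()
        e_nm = e_nm.copy()
        e_sh[invalid] = np.nan
        e_nm[invalid] = np.nan

    def _summ(e: np.ndarray) -> dict:
        finite = e[np.isfinite(e)]
        if finite.size == 0:
            return {"mean": np.nan, "max_abs": np.nan}
        return {"mean": float(finite.mean()), "max_abs": float(np.max(np.abs(finite)))}

    return AnthropometricReport(
        t=np.asarray(t, dtype=float),
        e_sh=e_sh,
        e_nm=e_nm,
        summary={"e_sh": _summ(e_sh), "e_nm": _summ(e_nm)},
    )
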