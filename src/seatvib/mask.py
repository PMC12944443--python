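"""Frame-level quality gates and the global conjunction mask.

A frame survives only if (i) body and seat acceleration norms stay below
the spike gate ``a_th`` and (ii) all three landmarks are defined, visible
enough, and within the plausible depth band in the camera frame.  Every
rejected frame carries a single cause code; when several gates fail at
once, precedence is imu_gap/imu_spike > nan_depth > depth_out_of_range >
low_visibility (IMU loss first, then depth loss, then confidence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from seatvib.config import PipelineConfig
from seatvib.errors import SessionDataError
from seatvib.session import SessionLog

__all__ = ["CAUSES", "QualityMask", "imu_validity", "rgbd_validity", "global_mask"]

#: Single-cause rejection taxonomy (``imu_gap`` is the alignment-loss
#: sub-code of the IMU class).
CAUSES = ("none", "imu_gap", "imu_spike", "nan_depth", "depth_out_of_range", "low_visibility")


@dataclass
class QualityMask:
    """Per-record validity with cause codes and a rejection tally."""

    valid: np.ndarray  # bool (N,)
    cause: np.ndarray  # str (N,), values in CAUSES
    tally: dict  # cause -> count (rejection causes only)
    kept: int
    dropped: int

    def __post_init__(self) -> None:
        assert self.kept + self.dropped == self.valid.size
        assert sum(self.tally.values()) == self.dropped

    @property
    def retention(self) -> float:
        """Fraction of frames kept, in [0, 1]."""
        return self.kept / self.valid.size if self.valid.size else 0.0

    def to_frame(self, session_id: str = "session") -> pd.DataFrame:
        """One-row tally table: total/kept/dropped plus per-cause counts."""
        row = {
            "session": session_id,
            "total_frames": int(self.valid.size),
            "kept": self.kept,
            "dropped": self.dropped,
            "retention_pct": 100.0 * self.retention,
        }
        for cause in CAUSES[1:]:
            row[cause] = int(self.tally.get(cause, 0))
        return pd.DataFrame([row])


def imu_validity(a_body: np.ndarray, a_seat: np.ndarray, a_th: float = 30.0) -> np.ndarray:
    """IMU gate: both acceleration norms strictly below ``a_th``.

    NaN components fail the gate (a missing sample is never valid).
    Accepts single 3-vectors or (N, 3) arrays; gyro channels are
    implicitly validated through this same flag.
    """
    a_body = np.atleast_2d(np.asarray(a_body, dtype=float))
    a_seat = np.atleast_2d(np.asarray(a_seat, dtype=float))
    nb = np.linalg.norm(a_body, axis=-1)
    ns = np.linalg.norm(a_seat, axis=-1)
    finite = np.all(np.isfinite(a_body), axis=-1) & np.all(np.isfinite(a_seat), axis=-1)
    flag = finite & (nb < a_th) & (ns < a_th)
    return flag if flag.size > 1 else bool(flag[0])


def rgbd_validity(
    p_nose: np.ndarray,
    p_lsh: np.ndarray,
    p_rsh: np.ndarray,
    vis: np.ndarray,
    z_min: float = 0.0,
    z_max: float = 2.0,
    vis_min: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Landmark gate: every landmark defined, visible and in depth range.

    Returns ``(flag, cause)`` where cause is ``none`` for valid records and
    otherwise the highest-precedence failing cause (``nan_depth`` before
    ``depth_out_of_range`` before ``low_visibility``).  Depth is the
    z-component in the camera frame.
    """
    pts = np.stack(
        [np.atleast_2d(np.asarray(p, dtype=float)) for p in (p_nose, p_lsh, p_rsh)], axis=1
    )  # (N, 3 landmarks, 3 coords)
    vis = np.atleast_2d(np.asarray(vis, dtype=float))
    n = pts.shape[0]

    defined = np.all(np.isfinite(pts), axis=2)  # (N, 3)
    z = pts[:, :, 2]
    with np.errstate(invalid="ignore"):
        in_range = (z >= z_min) & (z <= z_max)
    visible = vis >= vis_min

    any_nan = ~np.all(defined, axis=1)
    any_oor = ~np.all(in_range | ~defined, axis=1)
    any_lowvis = ~np.all(visible, axis=1)

    flag = ~(any_nan | any_oor | any_lowvis)
    cause = np.full(n, "none", dtype=object)
    cause[any_lowvis] = "low_visibility"
    cause[any_oor] = "depth_out_of_range"
    cause[any_nan] = "nan_depth"
    if n == 1 and np.ndim(p_nose) == 1:
        return bool(flag[0]), str(cause[0])
    return flag, cause


def global_mask(session: SessionLog, config: PipelineConfig | None = None) -> QualityMask:
    """Conjunction of the IMU and RGB-D gates with a cause-coded tally.

    All downstream metrics consume only records where ``valid`` is true.
    The landmark gate is evaluated in the camera frame; sessions whose
    landmarks were already mapped to the world frame skip depth gating
    (depth is a camera-frame quantity) but keep visibility gating.
    """
    if session.n == 0:
        raise SessionDataError("cannot mask an empty session")
    cfg = config or PipelineConfig()

    imu_ok = imu_validity(session.a_body, session.a_seat, cfg.a_th)
    imu_ok = np.atleast_1d(imu_ok)
    if cfg.gate_cam_accel:
        a_cam = session.a_cam
        finite = np.all(np.isfinite(a_cam), axis=1)
        imu_ok &= finite & (np.linalg.norm(a_cam, axis=1) < cfg.a_th)
    gap = session.imu_gap

    if session.lm_frame == "camera":
        z_lo, z_hi = cfg.z_min, cfg.z_max
    else:  # depth gating is meaningful only in the camera frame
        z_lo, z_hi = -np.inf, np.inf
    rgbd_ok, rgbd_cause = rgbd_validity(
        session.p_nose,
        session.p_lsh,
        session.p_rsh,
        session.visibility,
        z_min=z_lo,
        z_max=z_hi,
        vis_min=cfg.vis_min,
    )

    valid = imu_ok & rgbd_ok & ~gap
    cause = np.full(session.n, "none", dtype=object)
    # lowest precedence first; later assignments overwrite
    cause[~rgbd_ok] = rgbd_cause[~rgbd_ok]
    cause[~imu_ok] = "imu_spike"
    cause[gap] = "imu_gap"

    tally = {c: int(np.sum(cause == c)) for c in CAUSES[1:]}
    kept = int(np.sum(valid))
    return QualityMask(
        valid=valid,
        cause=cause,
        tally=tally,
        kept=kept,
        dropped=session.n - kept,
    )
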