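"""Pipeline configuration and calibration metadata.

All thresholds that gate or shape the analysis live here so that a session
can be re-processed reproducibly from a single sidecar file.  Defaults
follow the seated whole-body-vibration setting: a conservative 30 m/s^2
acceleration spike gate, a 0-2 m plausible depth band for a seated person
in front of the camera, a 2 s sliding window spanning several cycles of
the 1-20 Hz band of interest, and a 0.8 Hz low cutoff for spectral
integration of acceleration to velocity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np

from seatvib.errors import CalibrationError, ConfigError

__all__ = ["CalibrationMeta", "PipelineConfig"]


@dataclass
class CalibrationMeta:
    """Extrinsic calibration of the (de-jittered) camera frame to the world.

    ``R_ext``/``t_ext`` map de-jittered camera coordinates into the world
    frame (x lateral, y vertical, z anteroposterior).  ``board_spec`` records
    the checkerboard used for calibration as ``(inner_cols, inner_rows,
    square_size_m)``; ``recon_error`` is the scalar distance-reconstruction
    check value from the calibration step, kept as metadata only.
    """

    R_ext: np.ndarray = field(default_factory=lambda: np.eye(3))
    t_ext: np.ndarray = field(default_factory=lambda: np.zeros(3))
    board_spec: tuple = (7, 5, 0.03)
    recon_error: float = 0.0

    def __post_init__(self) -> None:
        self.R_ext = np.asarray(self.R_ext, dtype=float).reshape(3, 3)
        self.t_ext = np.asarray(self.t_ext, dtype=float).reshape(3)
        self.validate()

    def validate(self) -> None:
        R = self.R_ext
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise CalibrationError("R_ext is not orthonormal (tolerance 1e-9)")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise CalibrationError("R_ext must have determinant +1")

    def to_dict(self) -> dict:
        return {
            "R_ext": self.R_ext.ravel().tolist(),
            "t_ext": self.t_ext.tolist(),
            "board_spec": list(self.board_spec),
            "recon_error": self.recon_error,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationMeta":
        return cls(
            R_ext=np.asarray(d.get("R_ext", np.eye(3).ravel()), dtype=float).reshape(3, 3),
            t_ext=np.asarray(d.get("t_ext", [0.0, 0.0, 0.0]), dtype=float),
            board_spec=tuple(d.get("board_spec", (7, 5, 0.03))),
            recon_error=float(d.get("recon_error", 0.0)),
        )


@dataclass
class PipelineConfig:
    """Thresholds, window lengths and gains for the full pipeline.

    Parameters
    ----------
    a_th : float
        IMU acceleration-norm spike gate, m/s^2.
    z_min, z_max : float
        Plausible camera-frame depth band for landmarks, m.
    vis_min : float
        Minimum landmark visibility score in [0, 1].
    window : float
        Sliding-window duration for every RMS-based metric, s.
    band : (float, float)
        Band-pass corner frequencies (f_lo, f_hi) for differential
        acceleration, Hz.
    f_min : float
        Low-frequency cutoff for spectral integration to velocity, Hz.
    k : float or "estimate"
        Passive seat-to-body gain; ``"estimate"`` fits it by least squares
        on the valid segment.
    k_rot : float
        Rotational gain applied to seat angular velocity before
        differencing (1.0 = plain difference).
    t_ref : float
        Length of the static reference interval for the neutral pose, s.
    align_tol : float
        Maximum IMU-to-frame time offset accepted during alignment, s.
    gate_cam_accel : bool
        Whether the camera IMU acceleration is also gated by ``a_th``
        (off by default; only body and seat norms are gated).
    interp_imu : bool
        Linearly interpolate IMU channels onto the master timeline instead
        of nearest-neighbour matching.
    seed : int
        Seed recorded with any stochastic step configured from this object.
    """

    a_th: float = 30.0
    z_min: float = 0.0
    z_max: float = 2.0
    vis_min: float = 0.5
    window: float = 2.0
    band: tuple = (1.0, 20.0)
    f_min: float = 0.8
    k: Union[float, str] = "estimate"
    k_rot: float = 1.0
    t_ref: float = 2.0
    align_tol: float = 0.02
    gate_cam_accel: bool = False
    interp_imu: bool = False
    seed: int = 1355

    def __post_init__(self) -> None:
        self.band = tuple(float(b) for b in self.band)
        self.validate()

    def validate(self, fs_nominal: float | None = None) -> None:
        f_lo, f_hi = self.band
        if not (0.0 < self.f_min < f_lo < f_hi):
            raise ConfigError(
                f"need 0 < f_min < f_lo < f_hi, got f_min={self.f_min}, band={self.band}"
            )
        if fs_nominal is not None and not f_hi < fs_nominal / 2:
            raise ConfigError(
                f"band upper edge {f_hi} Hz exceeds Nyquist for fs={fs_nominal} Hz"
            )
        if self.z_min >= self.z_max:
            raise ConfigError(f"z_min ({self.z_min}) must be < z_max ({self.z_max})")
        if self.window <= 0:
            raise ConfigError("window must be positive")
        if self.align_tol <= 0:
            raise ConfigError("align_tol must be positive")
        if not 0.0 <= self.vis_min <= 1.0:
            raise ConfigError("vis_min must lie in [0, 1]")
        if isinstance(self.k, str) and self.k != "estimate":
            raise ConfigError(f"k must be a number or 'estimate', got {self.k!r}")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["band"] = list(self.band)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)
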