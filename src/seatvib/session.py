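"""Unified session-log data model and multi-rate stream alignment.

One session is a time-ordered table with one row per sample and a fixed
column set covering three IMUs (body, seat, camera), the camera orientation
quaternion, three RGB-D landmarks (nose, left shoulder, right shoulder)
with visibility scores, per-sample measured anthropometric distances and
the tape-measured nominals held constant across the session.

File dialect: UTF-8, comma-delimited, ``.`` decimal, one header line,
optionally preceded by ``#``-comment metadata lines (``key=value`` pairs;
``omega=deg/s`` converts angular-velocity columns to rad/s at read time).
Quaternions are Hamilton, scalar-first (w, x, y, z).  Axes follow the
seated-world convention: x lateral, y vertical, z anteroposterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from seatvib.config import CalibrationMeta
from seatvib.errors import ConfigError, SessionDataError, SessionFormatError

__all__ = [
    "COLUMNS",
    "LANDMARKS",
    "SessionLog",
    "ImuStream",
    "LandmarkStream",
    "read_session",
    "write_session",
    "align_streams",
]

LANDMARKS = ("nose", "lsh", "rsh")
_AXES = ("x", "y", "z")

#: Fixed, versioned column order of the session-log file format (v1).
COLUMNS = (
    ["t"]
    + [f"a_body_{c}" for c in _AXES]
    + [f"w_body_{c}" for c in _AXES]
    + [f"a_seat_{c}" for c in _AXES]
    + [f"w_seat_{c}" for c in _AXES]
    + [f"a_cam_{c}" for c in _AXES]
    + [f"w_cam_{c}" for c in _AXES]
    + ["q_w", "q_x", "q_y", "q_z"]
    + [f"p_{l}_{c}" for l in LANDMARKS for c in _AXES]
    + [f"vis_{l}" for l in LANDMARKS]
    + ["d_sh_meas", "d_nm_meas", "d_sh_real", "d_nm_real"]
)

_FRAME_TAGS = ("camera", "dejittered", "world")


@dataclass
class SessionLog:
    """An aligned measurement session: one row per time sample.

    ``df`` holds the numeric table (columns :data:`COLUMNS` plus the
    optional boolean ``imu_gap`` alignment flag); ``lm_frame`` tags the
    coordinate frame of all landmark columns.
    """

    df: pd.DataFrame
    fs_nominal: float
    calibration: CalibrationMeta = field(default_factory=CalibrationMeta)
    session_id: str = "session"
    lm_frame: str = "camera"

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SessionFormatError(f"session table is missing columns: {missing}")
        if len(self.df) < 1:
            raise SessionDataError("a session needs at least one record")
        t = self.df["t"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise SessionDataError(
                f"timestamps must be strictly increasing; violations at indices {(bad + 1).tolist()}"
            )
        if self.lm_frame not in _FRAME_TAGS:
            raise SessionDataError(f"unknown landmark frame tag {self.lm_frame!r}")
        for col in ("d_sh_real", "d_nm_real"):
            vals = self.df[col].to_numpy(dtype=float)
            if not np.all(vals == vals[0]):
                raise SessionDataError(f"{col} must be constant across the session")
            if not vals[0] > 0:
                raise SessionDataError(f"{col} must be positive")
        if "imu_gap" not in self.df.columns:
            self.df = self.df.assign(imu_gap=False)

    # -- column-group accessors -------------------------------------------

    def _vec(self, prefix: str) -> np.ndarray:
        return self.df[[f"{prefix}_{c}" for c in _AXES]].to_numpy(dtype=float)

    @property
    def t(self) -> np.ndarray:
        return self.df["t"].to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def a_body(self) -> np.ndarray:
        return self._vec("a_body")

    @property
    def w_body(self) -> np.ndarray:
        return self._vec("w_body")

    @property
    def a_seat(self) -> np.ndarray:
        return self._vec("a_seat")

    @property
    def w_seat(self) -> np.ndarray:
        return self._vec("w_seat")

    @property
    def a_cam(self) -> np.ndarray:
        return self._vec("a_cam")

    @property
    def w_cam(self) -> np.ndarray:
        return self._vec("w_cam")

    @property
    def q(self) -> np.ndarray:
        return self.df[["q_w", "q_x", "q_y", "q_z"]].to_numpy(dtype=float)

    def landmark(self, name: str) -> np.ndarray:
        if name not in LANDMARKS:
            raise KeyError(f"unknown landmark {name!r}")
        return self._vec(f"p_{name}")

    @property
    def p_nose(self) -> np.ndarray:
        return self.landmark("nose")

    @property
    def p_lsh(self) -> np.ndarray:
        return self.landmark("lsh")

    @property
    def p_rsh(self) -> np.ndarray:
        return self.landmark("rsh")

    @property
    def visibility(self) -> np.ndarray:
        return self.df[[f"vis_{l}" for l in LANDMARKS]].to_numpy(dtype=float)

    @property
    def imu_gap(self) -> np.ndarray:
        return self.df["imu_gap"].to_numpy(dtype=bool)

    @property
    def d_sh_real(self) -> float:
        return float(self.df["d_sh_real"].iloc[0])

    @property
    def d_nm_real(self) -> float:
        return float(self.df["d_nm_real"].iloc[0])

    def copy(self) -> "SessionLog":
        return SessionLog(
            df=self.df.copy(),
            fs_nominal=self.fs_nominal,
            calibration=self.calibration,
            session_id=self.session_id,
            lm_frame=self.lm_frame,
        )


@dataclass
class ImuStream:
    """A native-rate IMU stream: time, acceleration, angular velocity,
    and (camera IMU only) an orientation quaternion per sample."""

    t: np.ndarray
    a: np.ndarray
    w: np.ndarray
    q: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.q is not None:
            self.q = np.asarray(self.q, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise SessionDataError("IMU stream timestamps must be strictly increasing")


@dataclass
class LandmarkStream:
    """A native-rate landmark stream from the RGB-D camera (camera frame)."""

    t: np.ndarray
    p_nose: np.ndarray
    p_lsh: np.ndarray
    p_rsh: np.ndarray
    vis: np.ndarray  # (N, 3) visibility per landmark in LANDMARKS order

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise SessionDataError("landmark stream timestamps must be strictly increasing")


# -- file I/O --------------------------------------------------------------


def _parse_comment_meta(path: Path) -> dict:
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].split():
                if "=" in token:
                    key, val = token.split("=", 1)
                    meta[key] = val
    return meta


def read_session(
    path: str | Path,
    calibration: CalibrationMeta | None = None,
    fs_nominal: float | None = None,
) -> SessionLog:
    """Read a session log from a delimited text file.

    Missing numeric cells become NaN (never silently zero).  An optional
    leading ``# key=value`` comment line supplies metadata: ``omega=deg/s``
    converts angular-velocity columns to rad/s, ``fs`` the nominal rate,
    ``lm_frame`` the landmark frame tag, ``session`` the id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _parse_comment_meta(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SessionFormatError(f"header is missing required columns: {missing}")
    t = df["t"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise SessionDataError(
            f"timestamps not strictly increasing at indices {(bad + 1).tolist()}"
        )
    if meta.get("omega", "rad/s") == "deg/s":
        wcols = [c for c in df.columns if c.startswith("w_")]
        df[wcols] = np.deg2rad(df[wcols].to_numpy(dtype=float))
    if fs_nominal is None:
        if "fs" in meta:
            fs_nominal = float(meta["fs"])
        elif len(df) > 1:
            fs_nominal = float(1.0 / np.median(np.diff(t)))
        else:
            fs_nominal = 1.0
    return SessionLog(
        df=df,
        fs_nominal=fs_nominal,
        calibration=calibration or CalibrationMeta(),
        session_id=meta.get("session", path.stem),
        lm_frame=meta.get("lm_frame", "camera"),
    )


def write_session(session: SessionLog, path: str | Path) -> None:
    """Write a session log; numeric content round-trips through
    :func:`read_session` to better than 1e-9."""
    path = Path(path)
    cols = list(COLUMNS) + (["imu_gap"] if "imu_gap" in session.df.columns else [])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# seatvib-session v1 omega=rad/s fs={session.fs_nominal:.9g} "
            f"lm_frame={session.lm_frame} session={session.session_id}\n"
        )
        session.df[cols].to_csv(fh, index=False, float_format="%.17g")


# -- multi-rate alignment --------------------------------------------------


def _nearest_index(t_ref: np.ndarray, t_query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each query time, the index of the nearest reference time and
    the absolute offset."""
    pos = np.searchsorted(t_ref, t_query)
    pos = np.clip(pos, 1, len(t_ref) - 1) if len(t_ref) > 1 else np.zeros_like(pos)
    left = np.clip(pos - 1, 0, len(t_ref) - 1)
    right = np.clip(pos, 0, len(t_ref) - 1)
    choose_right = np.abs(t_ref[right] - t_query) < np.abs(t_query - t_ref[left])
    idx = np.where(choose_right, right, left)
    return idx, np.abs(t_ref[idx] - t_query)


def align_streams(
    imu_body: ImuStream,
    imu_seat: ImuStream,
    imu_cam: ImuStream,
    landmark_stream: LandmarkStream,
    tol: float,
    *,
    d_sh_real: float = 0.40,
    d_nm_real: float = 0.22,
    calibration: CalibrationMeta | None = None,
    fs_nominal: float | None = None,
    interp: bool = False,
    session_id: str = "aligned",
) -> SessionLog:
    """Align multi-rate streams onto the camera (landmark) timeline.

    One output record per landmark frame; each IMU channel is filled with
    its nearest-in-time sample within ``tol`` seconds (or linearly
    interpolated when ``interp``), otherwise left NaN with the record's
    ``imu_gap`` flag set so the quality mask can tally the loss.
    """
    if tol <= 0:
        raise ConfigError("alignment tolerance must be positive")
    t_cam = np.asarray(landmark_stream.t, dtype=float)
    if t_cam.size == 0:
        raise SessionDataError("landmark stream is empty; nothing to align to")

    n = t_cam.size
    data: dict[str, np.ndarray] = {"t": t_cam}
    gap = np.zeros(n, dtype=bool)

    def fill(prefix: str, stream: ImuStream, field: str) -> None:
        nonlocal gap
        values = getattr(stream, field)
        idx, off = _nearest_index(stream.t, t_cam)
        ok = off <= tol
        gap |= ~ok
        if interp:
            out = np.column_stack(
                [np.interp(t_cam, stream.t, values[:, k]) for k in range(values.shape[1])]
            )
        else:
            out = values[idx].astype(float).copy()
        out[~ok] = np.nan
        for k, c in enumerate(_AXES):
            data[f"{prefix}_{c}"] = out[:, k]

    fill("a_body", imu_body, "a")
    fill("w_body", imu_body, "w")
    fill("a_seat", imu_seat, "a")
    fill("w_seat", imu_seat, "w")
    fill("a_cam", imu_cam, "a")
    fill("w_cam", imu_cam, "w")

    if imu_cam.q is not None:
        idx, off = _nearest_index(imu_cam.t, t_cam)
        qq = imu_cam.q[idx].astype(float).copy()
        qq[off > tol] = np.nan
    else:
        qq = np.full((n, 4), np.nan)
    for k, c in enumerate(("w", "x", "y", "z")):
        data[f"q_{c}"] = qq[:, k]

    for name, arr in (
        ("nose", landmark_stream.p_nose),
        ("lsh", landmark_stream.p_lsh),
        ("rsh", landmark_stream.p_rsh),
    ):
        arr = np.asarray(arr, dtype=float)
        for k, c in enumerate(_AXES):
            data[f"p_{name}_{c}"] = arr[:, k]
    vis = np.asarray(landmark_stream.vis, dtype=float)
    for k, name in enumerate(LANDMARKS):
        data[f"vis_{name}"] = vis[:, k]

    p_lsh = np.asarray(landmark_stream.p_lsh, dtype=float)
    p_rsh = np.asarray(landmark_stream.p_rsh, dtype=float)
    p_nose = np.asarray(landmark_stream.p_nose, dtype=float)
    p_mid = 0.5 * (p_lsh + p_rsh)
    data["d_sh_meas"] = np.linalg.norm(p_lsh - p_rsh, axis=1)
    data["d_nm_meas"] = np.linalg.norm(p_nose - p_mid, axis=1)
    data["d_sh_real"] = np.full(n, float(d_sh_real))
    data["d_nm_real"] = np.full(n, float(d_nm_real))
    data["imu_gap"] = gap

    if fs_nominal is None:
        fs_nominal = float(1.0 / np.median(np.diff(t_cam))) if n > 1 else 1.0
    return SessionLog(
        df=pd.DataFrame(data),
        fs_nominal=fs_nominal,
        calibration=calibration or CalibrationMeta(),
        session_id=session_id,
        lm_frame="camera",
    )
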