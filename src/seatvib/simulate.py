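"""Seeded synthetic seated-rider sessions with ground truth.

The generator realises the three-layer decomposition as a generative
model: the seat carries a sum of sinusoids (typical rail-vehicle
excitation concentrated below 10 Hz, vertical-dominant) plus broadband
noise and transient events; the body follows the seat with a passive gain
``k_true`` plus its own compensation motion; the camera follows the seat
through its mount gain with an added mount resonance and a rotational
jitter described by exact quaternions.  Landmarks are a rigid
nose/shoulder triplet placed by the geometry, displaced by the
compensation, and expressed in the camera frame through the jitter
rotation and the inverse extrinsics, so that depth is the camera-frame
z-component.  Compensation displacements are differentiated analytically
so the landmark and IMU channels stay mutually consistent.

Everything is deterministic under a fixed seed, and a
:class:`GroundTruth` records every injected quantity so pipeline recovery
can be tested exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seatvib.config import CalibrationMeta
from seatvib.errors import ConfigError
from seatvib.session import LANDMARKS, ImuStream, LandmarkStream, SessionLog

__all__ = ["ScenarioParams", "GroundTruth", "simulate_session", "simulate_streams", "inject_artifacts"]

G = 9.81
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def _axis_unit(axis: str) -> np.ndarray:
    u = np.zeros(3)
    u[_AXIS_INDEX[axis]] = 1.0
    return u


def _default_calibration() -> CalibrationMeta:
    # camera on the window mount at (0, 0.5, 1.4) m facing the occupant
    # along -z: the de-jittered camera frame is the world frame rotated
    # 180 degrees about y
    R = np.array([[-1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, -1.0]])
    return CalibrationMeta(R_ext=R, t_ext=np.array([0.0, 0.5, 1.4]))


@dataclass
class ScenarioParams:
    """Tunable scenario: excitation, coupling gains, jitter, artefacts.

    Spectral components are ``(freq_Hz, amplitude, axis)`` tuples;
    compensation entries per landmark are ``(axis, amplitude_m, freq_Hz)``.
    Defaults emulate a tram ride: vertical-dominant seat excitation below
    10 Hz with transient events, near-unity passive transmission, a
    window-mounted camera that slightly amplifies the seat motion and
    resonates at 6 Hz, and small rotational camera jitter.
    """

    duration: float = 60.0
    fs_imu: float = 100.0
    fs_cam: float = 20.0
    master: str = "camera"  # timeline of the produced SessionLog

    seat_spectrum: tuple = (
        (1.5, 0.30, "y"),
        (4.0, 0.50, "y"),
        (6.0, 0.25, "x"),
        (8.0, 0.15, "z"),
    )
    seat_noise_sd: float = 0.05  # broadband seat acceleration noise, m/s^2
    seat_rot_spectrum: tuple = ((2.0, 0.02, "x"), (5.0, 0.015, "z"))
    events: tuple = ((20.0, 2.0, 2.5), (40.0, 2.0, 3.0))  # (start s, dur s, multiplier)

    k_true: float = 0.9
    k_rot_true: float = 1.0

    # postural compensation: per-landmark displacement sinusoids and a
    # torso angular component
    compensation: dict = field(
        default_factory=lambda: {
            "nose": (("x", 0.010, 0.5),),
            "lsh": (("z", 0.004, 0.3),),
            "rsh": (("z", 0.004, 0.3),),
        }
    )
    torso_angular: tuple = (("z", 0.05, 0.4),)  # (axis, amplitude rad/s, freq)

    cam_gain: float = 1.1
    mount_resonance: tuple = (6.0, 0.2, "x")  # (freq, amplitude m/s^2, axis)
    jitter: tuple = (1.0, 3.0, "y")  # (amplitude deg, freq Hz, axis)

    # rigid geometry, m
    shoulder_width: float = 0.40
    nose_rise: float = 0.20  # nose height above the shoulder midpoint
    nose_forward: float = 0.10  # nose offset towards the camera (+z)
    calibration: CalibrationMeta = field(default_factory=_default_calibration)

    accel_noise_sd: float = 0.02
    gyro_noise_sd: float = 0.005
    # pose-tracker landmark noise: stationary sd (m) of an AR(1) process;
    # tracker output is temporally smoothed, so sample-to-sample noise is
    # strongly correlated rather than white
    landmark_noise_sd: float = 0.002
    landmark_noise_corr: float = 0.95
    visibility: float = 0.98
    include_gravity: bool = True

    dropout_rate: float = 0.0
    depth_spike_rate: float = 0.0
    imu_spike_rate: float = 0.0

    seed: int = 1355

    def validate(self) -> None:
        fs = self.fs_cam if self.master == "camera" else self.fs_imu
        nyq = fs / 2.0
        freqs = [f for f, _, _ in self.seat_spectrum]
        freqs += [f for f, _, _ in self.seat_rot_spectrum]
        freqs += [f for _, _, f in self.torso_angular]
        freqs += [self.mount_resonance[0], self.jitter[1]]
        for comps in self.compensation.values():
            freqs += [f for _, _, f in comps]
        bad = [f for f in freqs if f >= nyq]
        if bad:
            raise ConfigError(
                f"spectral components {bad} Hz alias at the {fs} Hz master rate"
            )
        for r in (self.dropout_rate, self.depth_spike_rate, self.imu_spike_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("artefact rates must lie in [0, 1]")
        if self.dropout_rate + self.depth_spike_rate + self.imu_spike_rate > 1.0:
            raise ConfigError("artefact rates sum to more than one per frame")
        if self.master not in ("camera", "imu"):
            raise ConfigError("master must be 'camera' or 'imu'")
        if not (self.shoulder_width > 0 and self.nose_rise >= 0):
            raise ConfigError("geometry must be positive")


@dataclass
class GroundTruth:
    """Everything the simulator injected, for recovery tests."""

    k_true: float
    k_rot_true: float
    world_traj: dict  # landmark -> (N, 3) true world positions
    dominant_axis: dict  # landmark -> 'x'|'y'|'z' of strongest compensation
    jitter_q: np.ndarray  # (N, 4) exact camera orientation
    d_sh: float
    d_nm: float
    cam_gain: float
    artefact_indices: dict = field(default_factory=dict)  # cause -> indices


class _Generator:
    """Deterministic evaluation of every channel at arbitrary times."""

    def __init__(self, params: ScenarioParams, seed: int | None = None):
        params.validate()
        self.p = params
        self.seed = int(params.seed if seed is None else seed)
        # phases are drawn once so every query timeline sees the same signal
        rng = np.random.default_rng(self.seed)
        self.ph_seat = rng.uniform(0, 2 * np.pi, len(params.seat_spectrum))
        self.ph_rot = rng.uniform(0, 2 * np.pi, len(params.seat_rot_spectrum))
        self.ph_comp = {
            l: rng.uniform(0, 2 * np.pi, len(comps))
            for l, comps in params.compensation.items()
        }
        self.ph_torso = rng.uniform(0, 2 * np.pi, len(params.torso_angular))
        self.ph_mount = rng.uniform(0, 2 * np.pi)
        self.noise_rng = np.random.default_rng(self.seed + 7919)

        w = params.shoulder_width / 2.0
        mid = np.array([0.0, 0.45, 0.0])
        self.base = {
            "nose": mid + np.array([0.0, params.nose_rise, params.nose_forward]),
            "lsh": mid + np.array([-w, 0.0, 0.0]),
            "rsh": mid + np.array([+w, 0.0, 0.0]),
        }
        self.d_sh = params.shoulder_width
        self.d_nm = float(np.hypot(params.nose_rise, params.nose_forward))

    # -- deterministic components -----------------------------------------

    def _event_envelope(self, t: np.ndarray) -> np.ndarray:
        env = np.ones_like(t)
        for start, dur, mult in self.p.events:
            env += (mult - 1.0) * ((t >= start) & (t < start + dur))
        return env

    def seat_dyn(self, t: np.ndarray) -> np.ndarray:
        out = np.zeros((t.size, 3))
        env = self._event_envelope(t)
        for (f, amp, axis), ph in zip(self.p.seat_spectrum, self.ph_seat):
            out += np.outer(env * amp * np.sin(2 * np.pi * f * t + ph), _axis_unit(axis))
        return out

    def seat_rot(self, t: np.ndarray) -> np.ndarray:
        out = np.zeros((t.size, 3))
        for (f, amp, axis), ph in zip(self.p.seat_rot_spectrum, self.ph_rot):
            out += np.outer(amp * np.sin(2 * np.pi * f * t + ph), _axis_unit(axis))
        return out

    def comp_disp(self, name: str, t: np.ndarray) -> np.ndarray:
        out = np.zeros((t.size, 3))
        for (axis, amp, f), ph in zip(
            self.p.compensation.get(name, ()), self.ph_comp.get(name, ())
        ):
            out += np.outer(amp * np.sin(2 * np.pi * f * t + ph), _axis_unit(axis))
        return out

    def comp_accel(self, name: str, t: np.ndarray) -> np.ndarray:
        out = np.zeros((t.size, 3))
        for (axis, amp, f), ph in zip(
            self.p.compensation.get(name, ()), self.ph_comp.get(name, ())
        ):
            w2 = (2 * np.pi * f) ** 2
            out += np.outer(-w2 * amp * np.sin(2 * np.pi * f * t + ph), _axis_unit(axis))
        return out

    def torso_rot(self, t: np.ndarray) -> np.ndarray:
        out = np.zeros((t.size, 3))
        for (axis, amp, f), ph in zip(self.p.torso_angular, self.ph_torso):
            out += np.outer(amp * np.sin(2 * np.pi * f * t + ph), _axis_unit(axis))
        return out

    def mount(self, t: np.ndarray) -> np.ndarray:
        f, amp, axis = self.p.mount_resonance
        return np.outer(amp * np.sin(2 * np.pi * f * t + self.ph_mount), _axis_unit(axis))

    def jitter_angle(self, t: np.ndarray) -> np.ndarray:
        amp_deg, f, _ = self.p.jitter
        return np.deg2rad(amp_deg) * np.sin(2 * np.pi * f * t)

    def jitter_rate(self, t: np.ndarray) -> np.ndarray:
        amp_deg, f, axis = self.p.jitter
        dtheta = np.deg2rad(amp_deg) * 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        return np.outer(dtheta, _axis_unit(axis))

    def jitter_quat(self, t: np.ndarray) -> np.ndarray:
        theta = self.jitter_angle(t)
        u = _axis_unit(self.p.jitter[2])
        q = np.zeros((t.size, 4))
        q[:, 0] = np.cos(theta / 2.0)
        q[:, 1:] = np.outer(np.sin(theta / 2.0), u)
        return q

    # -- channel assembly --------------------------------------------------

    def _noise(self, shape: tuple, sd: float) -> np.ndarray:
        if sd <= 0:
            return np.zeros(shape)
        return self.noise_rng.normal(0.0, sd, shape)

    def _landmark_noise(self, shape: tuple) -> np.ndarray:
        """AR(1) tracker noise with stationary sd ``landmark_noise_sd``."""
        sd = self.p.landmark_noise_sd
        if sd <= 0:
            return np.zeros(shape)
        rho = float(np.clip(self.p.landmark_noise_corr, 0.0, 0.999))
        innov = self.noise_rng.normal(0.0, sd * np.sqrt(1.0 - rho * rho), shape)
        innov[0] = self.noise_rng.normal(0.0, sd, shape[1:])
        out = np.empty(shape)
        out[0] = innov[0]
        for i in range(1, shape[0]):
            out[i] = rho * out[i - 1] + innov[i]
        return out

    def imu_channels(self, t: np.ndarray) -> dict:
        p = self.p
        g_vec = np.array([0.0, G, 0.0]) if p.include_gravity else np.zeros(3)
        s = self.seat_dyn(t)
        wr = self.seat_rot(t)
        torso_acc = 0.5 * (self.comp_accel("lsh", t) + self.comp_accel("rsh", t))
        ch = {
            "a_seat": g_vec + s + self._noise(s.shape, p.seat_noise_sd),
            "a_body": g_vec
            + p.k_true * s
            + torso_acc
            + self._noise(s.shape, p.accel_noise_sd),
            "a_cam": g_vec
            + p.cam_gain * s
            + self.mount(t)
            + self._noise(s.shape, p.accel_noise_sd),
            "w_seat": wr + self._noise(wr.shape, p.gyro_noise_sd),
            "w_body": p.k_rot_true * wr
            + self.torso_rot(t)
            + self._noise(wr.shape, p.gyro_noise_sd),
            "w_cam": self.jitter_rate(t) + self._noise(wr.shape, p.gyro_noise_sd),
            "q": self.jitter_quat(t),
        }
        return ch

    def landmark_channels(self, t: np.ndarray) -> dict:
        p = self.p
        cal = p.calibration
        q = self.jitter_quat(t)
        # quaternion -> rotation matrices (scalar-first, Hamilton)
        w, x, y, z = q.T
        R = np.empty((t.size, 3, 3))
        R[:, 0, 0] = 1 - 2 * (y * y + z * z)
        R[:, 0, 1] = 2 * (x * y - w * z)
        R[:, 0, 2] = 2 * (x * z + w * y)
        R[:, 1, 0] = 2 * (x * y + w * z)
        R[:, 1, 1] = 1 - 2 * (x * x + z * z)
        R[:, 1, 2] = 2 * (y * z - w * x)
        R[:, 2, 0] = 2 * (x * z - w * y)
        R[:, 2, 1] = 2 * (y * z + w * x)
        R[:, 2, 2] = 1 - 2 * (x * x + y * y)

        out = {"world": {}, "camera": {}}
        for name in LANDMARKS:
            p_w = self.base[name] + self.comp_disp(name, t)
            out["world"][name] = p_w
            p_dejit = (p_w - cal.t_ext) @ cal.R_ext  # R_ext^T (p_w - t_ext)
            p_cam = np.einsum("nij,nj->ni", R, p_dejit)
            p_cam = p_cam + self._landmark_noise(p_cam.shape)
            out["camera"][name] = p_cam
        return out


def _assemble_session(
    gen: _Generator, t: np.ndarray, session_id: str, fs: float
) -> tuple[SessionLog, GroundTruth]:
    imu = gen.imu_channels(t)
    lms = gen.landmark_channels(t)
    data = {"t": t}
    for key in ("a_body", "w_body", "a_seat", "w_seat", "a_cam", "w_cam"):
        for k, c in enumerate(("x", "y", "z")):
            data[f"{key}_{c}"] = imu[key][:, k]
    for k, c in enumerate(("w", "x", "y", "z")):
        data[f"q_{c}"] = imu["q"][:, k]
    for name in LANDMARKS:
        for k, c in enumerate(("x", "y", "z")):
            data[f"p_{name}_{c}"] = lms["camera"][name][:, k]
        data[f"vis_{name}"] = np.full(t.size, gen.p.visibility)
    p_mid = 0.5 * (lms["camera"]["lsh"] + lms["camera"]["rsh"])
    data["d_sh_meas"] = np.linalg.norm(
        lms["camera"]["lsh"] - lms["camera"]["rsh"], axis=1
    )
    data["d_nm_meas"] = np.linalg.norm(lms["camera"]["nose"] - p_mid, axis=1)
    data["d_sh_real"] = np.full(t.size, gen.d_sh)
    data["d_nm_real"] = np.full(t.size, gen.d_nm)

    session = SessionLog(
        df=pd.DataFrame(data),
        fs_nominal=fs,
        calibration=gen.p.calibration,
        session_id=session_id,
        lm_frame="camera",
    )

    dominant = {}
    for name in LANDMARKS:
        comps = gen.p.compensation.get(name, ())
        if comps:
            strongest = max(comps, key=lambda c: c[1])
            dominant[name] = strongest[0]
        else:
            dominant[name] = None
    truth = GroundTruth(
        k_true=gen.p.k_true,
        k_rot_true=gen.p.k_rot_true,
        world_traj=lms["world"],
        dominant_axis=dominant,
        jitter_q=imu["q"],
        d_sh=gen.d_sh,
        d_nm=gen.d_nm,
        cam_gain=gen.p.cam_gain,
    )
    return session, truth


def simulate_session(
    params: ScenarioParams | None = None, seed: int | None = None
) -> tuple[SessionLog, GroundTruth]:
    """Generate one aligned session on the master timeline plus its truth.

    The master rate is ``fs_cam`` (default) or ``fs_imu`` depending on
    ``params.master``; every channel is evaluated from the same generative
    model, so the result is an already-aligned log.  Artefacts are
    injected afterwards when any of the artefact rates is positive.
    Deterministic under a fixed seed.
    """
    params = params or ScenarioParams()
    gen = _Generator(params, seed)
    fs = params.fs_cam if params.master == "camera" else params.fs_imu
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs
    session, truth = _assemble_session(gen, t, f"sim-{gen.seed}", fs)
    if params.dropout_rate or params.depth_spike_rate or params.imu_spike_rate:
        session, idx = inject_artifacts(
            session,
            dropout=params.dropout_rate,
            depth_spike=params.depth_spike_rate,
            imu_spike=params.imu_spike_rate,
            seed=gen.seed + 104729,
        )
        truth.artefact_indices = idx
    return session, truth


def simulate_streams(
    params: ScenarioParams | None = None, seed: int | None = None
) -> tuple[ImuStream, ImuStream, ImuStream, LandmarkStream]:
    """Native-rate streams (IMUs at ``fs_imu``, landmarks at ``fs_cam``)
    from the same generative model, for exercising stream alignment."""
    params = params or ScenarioParams()
    gen = _Generator(params, seed)
    n_imu = int(round(params.duration * params.fs_imu))
    t_imu = np.arange(n_imu) / params.fs_imu
    n_cam = int(round(params.duration * params.fs_cam))
    t_cam = np.arange(n_cam) / params.fs_cam
    imu = gen.imu_channels(t_imu)
    lms = gen.landmark_channels(t_cam)
    body = ImuStream(t=t_imu, a=imu["a_body"], w=imu["w_body"])
    seat = ImuStream(t=t_imu, a=imu["a_seat"], w=imu["w_seat"])
    cam = ImuStream(t=t_imu, a=imu["a_cam"], w=imu["w_cam"], q=imu["q"])
    lm = LandmarkStream(
        t=t_cam,
        p_nose=lms["camera"]["nose"],
        p_lsh=lms["camera"]["lsh"],
        p_rsh=lms["camera"]["rsh"],
        vis=np.full((n_cam, 3), params.visibility),
    )
    return body, seat, cam, lm


def inject_artifacts(
    session: SessionLog,
    dropout: float | int = 0,
    depth_spike: float | int = 0,
    imu_spike: float | int = 0,
    seed: int | None = None,
    z_spike: float = 2.5,
    spike_magnitude: float = 40.0,
) -> tuple[SessionLog, dict]:
    """Inject RGB-D and IMU artefacts into a clean session.

    Each argument is either an exact frame count (int) or a per-frame
    probability (float < 1).  Injected frame sets are mutually disjoint by
    construction: dropouts blank one landmark's coordinates (NaN), depth
    spikes push the nose depth to ``z_spike`` (beyond the plausible band),
    and IMU spikes add ``spike_magnitude`` m/s^2 to the vertical seat
    channel.  Returns the modified copy and a dict of injected indices
    per cause.
    """
    rng = np.random.default_rng(seed)
    n = session.n
    counts = {}
    rates = {}
    for name, val in (("nan_depth", dropout), ("depth_out_of_range", depth_spike), ("imu_spike", imu_spike)):
        if isinstance(val, (int, np.integer)) and not isinstance(val, bool):
            counts[name] = int(val)
        else:
            rates[name] = float(val)
    if sum(rates.values()) > 1.0:
        raise ConfigError("artefact probabilities sum to more than one per frame")
    if sum(counts.values()) > n:
        raise ConfigError("more artefact frames requested than frames available")

    chosen: dict[str, np.ndarray] = {}
    pool = np.arange(n)
    for name, cnt in counts.items():
        pick = rng.choice(pool, size=cnt, replace=False) if cnt else np.array([], dtype=int)
        chosen[name] = np.sort(pick)
        pool = np.setdiff1d(pool, pick)
    if rates and any(r > 0 for r in rates.values()):
        u = rng.uniform(size=pool.size)
        edges = np.cumsum([rates.get(c, 0.0) for c in ("nan_depth", "depth_out_of_range", "imu_spike")])
        lo = 0.0
        for name, hi in zip(("nan_depth", "depth_out_of_range", "imu_spike"), edges):
            sel = pool[(u >= lo) & (u < hi)]
            chosen[name] = np.sort(np.concatenate([chosen.get(name, np.array([], dtype=int)), sel]))
            lo = hi
    for name in ("nan_depth", "depth_out_of_range", "imu_spike"):
        chosen.setdefault(name, np.array([], dtype=int))

    out = session.copy()
    df = out.df
    if chosen["nan_depth"].size:
        lm_pick = rng.integers(0, len(LANDMARKS), size=chosen["nan_depth"].size)
        for idx, lm_i in zip(chosen["nan_depth"], lm_pick):
            name = LANDMARKS[lm_i]
            df.loc[df.index[idx], [f"p_{name}_x", f"p_{name}_y", f"p_{name}_z"]] = np.nan
    if chosen["depth_out_of_range"].size:
        jit = rng.uniform(0.0, 0.5, size=chosen["depth_out_of_range"].size)
        df.iloc[
            chosen["depth_out_of_range"], df.columns.get_loc("p_nose_z")
        ] = z_spike + jit
    if chosen["imu_spike"].size:
        col = df.columns.get_loc("a_seat_y")
        df.iloc[chosen["imu_spike"], col] = (
            df.iloc[chosen["imu_spike"], col].to_numpy() + spike_magnitude
        )
    return out, {k: v for k, v in chosen.items()}
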