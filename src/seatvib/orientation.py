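"""Camera orientation estimation and landmark de-jittering.

The camera orientation quaternion (Hamilton, scalar-first) describes the
rotation taking camera-frame vectors into the reference frame:
``v_ref = R(q) v_cam``.  Orientation is either taken from the logged
quaternion channel or re-estimated from the camera IMU with an
accelerometer+gyroscope Madgwick filter (gradient-descent complementary
filter, no magnetometer).  Jitter is cancelled by applying the transpose
of the camera rotation to camera-frame landmarks, after which the
checkerboard extrinsics map them into the world frame (x lateral,
y vertical, z anteroposterior).

Only rotational jitter is compensated; translational camera jitter is not
subtracted from the landmarks, which is a documented limitation of the
approach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from seatvib.errors import CalibrationError, ContractError
from seatvib.session import LANDMARKS, SessionLog

__all__ = [
    "OrientationSeries",
    "madgwick_orientation",
    "quat_to_rotmat",
    "dejitter_landmark",
    "to_world",
    "landmarks_to_world",
]

#: World-frame gravity direction (y is vertical up).
GRAVITY_REF = np.array([0.0, 1.0, 0.0])


@dataclass
class OrientationSeries:
    """A time series of unit orientation quaternions (scalar-first)."""

    t: np.ndarray
    q: np.ndarray  # (N, 4)
    beta: float
    fs: float

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.q, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ContractError("orientation quaternions must be unit norm (tol 1e-6)")
        # hemisphere continuity: consecutive quaternions share a hemisphere
        dots = np.sum(self.q[:-1] * self.q[1:], axis=1)
        if np.any(dots < 0):
            raise ContractError("quaternion series has hemisphere sign flips")


def _quat_multiply(p: np.ndarray, r: np.ndarray) -> np.ndarray:
    pw, px, py, pz = p
    rw, rx, ry, rz = r
    return np.array(
        [
            pw * rw - px * rx - py * ry - pz * rz,
            pw * rx + px * rw + py * rz - pz * ry,
            pw * ry - px * rz + py * rw + pz * rx,
            pw * rz + px * ry - py * rx + pz * rw,
        ]
    )


def _rotate_ref_into_body(q: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """``v = R(q)^T d`` and its Jacobian with respect to (w, x, y, z)."""
    w, x, y, z = q
    dx, dy, dz = d
    v = np.array(
        [
            dx * (1 - 2 * (y * y + z * z)) + 2 * dy * (x * y + w * z) + 2 * dz * (x * z - w * y),
            2 * dx * (x * y - w * z) + dy * (1 - 2 * (x * x + z * z)) + 2 * dz * (y * z + w * x),
            2 * dx * (x * z + w * y) + 2 * dy * (y * z - w * x) + dz * (1 - 2 * (x * x + y * y)),
        ]
    )
    J = np.array(
        [
            [
                2 * (dy * z - dz * y),
                2 * (dy * y + dz * z),
                -4 * dx * y + 2 * dy * x - 2 * dz * w,
                -4 * dx * z + 2 * dy * w + 2 * dz * x,
            ],
            [
                2 * (dz * x - dx * z),
                2 * dx * y - 4 * dy * x + 2 * dz * w,
                2 * (dx * x + dz * z),
                -2 * dx * w - 4 * dy * z + 2 * dz * y,
            ],
            [
                2 * (dx * y - dy * x),
                2 * dx * z - 2 * dy * w - 4 * dz * x,
                2 * dx * w + 2 * dy * z - 4 * dz * y,
                2 * (dx * x + dy * y),
            ],
        ]
    )
    return v, J


def _init_from_gravity(a0: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Orientation whose predicted gravity direction matches ``a0``."""
    norm = np.linalg.norm(a0)
    if norm == 0 or not np.all(np.isfinite(a0)):
        return np.array([1.0, 0.0, 0.0, 0.0])
    rot, _ = Rotation.align_vectors([d], [a0 / norm])
    q = rot.as_quat(scalar_first=True)
    return q if q[0] >= 0 else -q


def madgwick_orientation(
    a: np.ndarray,
    w: np.ndarray,
    fs: float,
    beta: float = 0.1,
    q0: np.ndarray | None = None,
    t: np.ndarray | None = None,
    gravity_ref: np.ndarray = GRAVITY_REF,
) -> OrientationSeries:
    """Estimate orientation from accelerometer + gyroscope (Madgwick).

    Gyroscope rates (rad/s) are integrated through the quaternion
    kinematics while a gradient-descent step of size ``beta`` pulls the
    predicted gravity direction towards the measured acceleration.  A
    zero-norm accelerometer sample skips the correction (gyro-only
    propagation for that step).  ``q0`` defaults to the gravity-aligned
    orientation of the first accelerometer sample.

    Parameters
    ----------
    a, w : (N, 3) arrays
        Accelerometer (m/s^2, any scale: only direction is used) and
        gyroscope (rad/s) samples, uniformly sampled at ``fs``.
    beta : float
        Filter gain; 0 gives pure gyro integration.
    """
    a = np.asarray(a, dtype=float)
    w = np.asarray(w, dtype=float)
    if a.shape != w.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ContractError("a and w must be equal-length (N, 3) arrays")
    if fs <= 0:
        raise ContractError("fs must be positive")
    n = a.shape[0]
    d = np.asarray(gravity_ref, dtype=float)
    d = d / np.linalg.norm(d)
    dt = 1.0 / fs

    q = (
        np.asarray(q0, dtype=float)
        if q0 is not None
        else _init_from_gravity(a[0], d)
    )
    q = q / np.linalg.norm(q)
    out = np.empty((n, 4))
    for i in range(n):
        wi = w[i] if np.all(np.isfinite(w[i])) else np.zeros(3)
        qdot = 0.5 * _quat_multiply(q, np.array([0.0, *wi]))
        norm_a = np.linalg.norm(a[i])
        if norm_a > 0 and np.all(np.isfinite(a[i])) and beta > 0:
            f, J = _rotate_ref_into_body(q, d)
            f = f - a[i] / norm_a
            grad = J.T @ f
            gnorm = np.linalg.norm(grad)
            if gnorm > 0:
                qdot = qdot - beta * grad / gnorm
        q = q + qdot * dt
        q = q / np.linalg.norm(q)
        if i > 0 and np.dot(q, out[i - 1]) < 0:
            q = -q
        out[i] = q
    if t is None:
        t = np.arange(n) / fs
    return OrientationSeries(t=np.asarray(t, dtype=float), q=out, beta=beta, fs=fs)


def quat_to_rotmat(q: np.ndarray) -> np.ndarray:
    """Unit quaternion (scalar-first) to rotation matrix in SO(3)."""
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1)
    if np.any(norm == 0) or not np.all(np.isfinite(q)):
        raise ContractError("zero or non-finite quaternion")
    if not np.allclose(norm, 1.0, atol=1e-6):
        raise ContractError("quaternion must be unit norm (tol 1e-6)")
    return Rotation.from_quat(q, scalar_first=True).as_matrix()


def dejitter_landmark(
    p_cam: np.ndarray, q: np.ndarray, q_ref: np.ndarray | None = None
) -> np.ndarray:
    """Cancel camera rotational jitter: ``p_dejit = R(q_ref) R(q)^T p_cam``.

    With the default ``q_ref`` (identity) this is the plain reverse
    orientation; passing the session-start orientation as ``q_ref``
    expresses the result in the camera pose at which the extrinsics were
    calibrated.  A pure rotation, so norms and pairwise distances are
    preserved.  Accepts single vectors or (N, 3) / (N, 4) series.
    """
    p_cam = np.asarray(p_cam, dtype=float)
    q = np.asarray(q, dtype=float)
    R = quat_to_rotmat(q)
    if p_cam.ndim == 1:
        out = R.T @ p_cam if R.ndim == 2 else np.einsum("nji,j->ni", R, p_cam)
    else:
        if R.ndim == 2:
            out = p_cam @ R  # (R^T p)^T = p^T R
        else:
            out = np.einsum("nji,nj->ni", R, p_cam)
    if q_ref is not None:
        R0 = quat_to_rotmat(np.asarray(q_ref, dtype=float))
        out = out @ R0.T
    return out


def to_world(p_dejit: np.ndarray, R_ext: np.ndarray, t_ext: np.ndarray) -> np.ndarray:
    """Map de-jittered camera coordinates into the world frame:
    ``p_w = R_ext p_dejit + t_ext``."""
    R_ext = np.asarray(R_ext, dtype=float)
    if not (
        np.allclose(R_ext.T @ R_ext, np.eye(3), atol=1e-9)
        and np.isclose(np.linalg.det(R_ext), 1.0, atol=1e-9)
    ):
        raise CalibrationError("R_ext is not a proper rotation")
    p_dejit = np.asarray(p_dejit, dtype=float)
    return p_dejit @ R_ext.T + np.asarray(t_ext, dtype=float)


def landmarks_to_world(
    session: SessionLog,
    beta: float = 0.1,
    use_logged_q: bool = True,
    compensate: bool = True,
) -> dict[str, np.ndarray]:
    """Full de-jitter + extrinsic mapping for all three landmarks.

    Uses the logged quaternion channel when present and finite (the
    authoritative path); otherwise re-estimates orientation from the
    camera IMU by Madgwick.  Jitter is measured relative to the first
    valid orientation of the session, which anchors the de-jittered frame
    to the pose at which the extrinsics were calibrated.  With
    ``compensate=False`` the landmarks are mapped by the extrinsics alone
    (the uncompensated baseline).

    Returns a dict with per-landmark (N, 3) world trajectories plus the
    quaternion series used under key ``"q"``.
    """
    if session.lm_frame != "camera":
        raise ContractError(
            f"landmarks are tagged {session.lm_frame!r}; de-jitter expects camera frame"
        )
    q = session.q
    have_logged = np.all(np.isfinite(q), axis=1)
    if not (use_logged_q and bool(np.all(have_logged))):
        est = madgwick_orientation(
            session.a_cam, session.w_cam, fs=session.fs_nominal, beta=beta, t=session.t
        )
        q = np.where(have_logged[:, None] & use_logged_q, q, est.q)
    # frames with no usable orientation (alignment gaps) fall back to the
    # last finite quaternion; such frames are rejected by the mask anyway
    finite_rows = np.all(np.isfinite(q), axis=1)
    if not finite_rows.all():
        q = q.copy()
        last = np.array([1.0, 0.0, 0.0, 0.0])
        for i in range(len(q)):
            if finite_rows[i]:
                last = q[i]
            else:
                q[i] = last
    # normalize + hemisphere continuity
    q = q / np.linalg.norm(q, axis=1, keepdims=True)
    for i in range(1, len(q)):
        if np.dot(q[i], q[i - 1]) < 0:
            q[i] = -q[i]
    q_ref = q[np.argmax(np.all(np.isfinite(q), axis=1))]

    cal = session.calibration
    out: dict[str, np.ndarray] = {"q": q}
    for name in LANDMARKS:
        p_cam = session.landmark(name)
        p_dejit = dejitter_landmark(p_cam, q, q_ref=q_ref) if compensate else p_cam
        out[name] = to_world(p_dejit, cal.R_ext, cal.t_ext)
    return out
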