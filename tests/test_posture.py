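"""Postural compensation indices, axis-wise anisotropy and
anthropometric consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from seatvib.errors import ConfigError, ContractError, SessionDataError
from seatvib.posture import (
    anthropometrics,
    axis_energy_body,
    axis_energy_landmark,
    reference_pose,
    rotational_pci,
    rtv,
    translational_pci,
)
from tests.test_vibration import brute_force_rms


class TestRotationalPci:
    def test_rigid_following_scores_zero(self, rng):
        w_seat = rng.normal(size=(100, 3))
        series = rotational_pci(1.3 * w_seat, w_seat, fs=20.0, k_rot=1.3)
        np.testing.assert_allclose(series.value, 0.0, atol=1e-12)

    def test_sinusoidal_difference_reaches_a_over_sqrt2(self):
        fs, amp = 100.0, 0.4
        t = np.arange(4000) / fs
        w_body = np.zeros((t.size, 3))
        w_body[:, 2] = amp * np.sin(2 * np.pi * 2.0 * t)
        series = rotational_pci(w_body, np.zeros_like(w_body), fs=fs, window=10.0)
        mid = series.value[~series.truncated]
        np.testing.assert_allclose(mid, amp / np.sqrt(2), rtol=0.01)

    def test_matches_brute_force_loop(self, rng):
        w_body = rng.normal(size=(9, 3))
        w_seat = rng.normal(size=(9, 3))
        k_rot = 0.7
        series = rotational_pci(w_body, w_seat, fs=10.0, k_rot=k_rot, window=0.5)
        expected = brute_force_rms(w_body - k_rot * w_seat, 2, detrend=False)
        np.testing.assert_allclose(series.value, expected, atol=1e-9)

    def test_scaling_difference_scales_pci(self, rng):
        w_body = rng.normal(size=(60, 3))
        base = rotational_pci(w_body, np.zeros_like(w_body), fs=20.0).value
        scaled = rotational_pci(-2.5 * w_body, np.zeros_like(w_body), fs=20.0).value
        np.testing.assert_allclose(scaled, 2.5 * base, rtol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            rotational_pci(np.zeros((5, 3)), np.zeros((4, 3)), fs=10.0)


def traj_dict(nose, lsh=None, rsh=None):
    z = np.zeros_like(nose)
    return {"nose": nose, "lsh": lsh if lsh is not None else z, "rsh": rsh if rsh is not None else z}


class TestReferencePose:
    def test_constant_trajectory(self):
        p = np.tile([0.1, 0.2, 0.3], (40, 1))
        t = np.arange(40) / 20.0
        ref = reference_pose(traj_dict(p, p, p), t, interval=(0.0, 2.0))
        np.testing.assert_allclose(ref.p_nose, [0.1, 0.2, 0.3])

    def test_symmetric_oscillation_averages_to_centre(self):
        fs = 100.0
        t = np.arange(int(2 * fs)) / fs  # exactly 2 periods of 1 Hz
        p = np.tile([0.0, 0.5, 1.0], (t.size, 1))
        p[:, 0] += 0.05 * np.sin(2 * np.pi * 1.0 * t)
        ref = reference_pose(traj_dict(p, p, p), t, interval=(0.0, 2.0))
        np.testing.assert_allclose(ref.p_nose, [0.0, 0.5, 1.0], atol=1e-3)

    def test_two_samples_average(self):
        p = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 3.0]])
        ref = reference_pose(traj_dict(p, p, p), np.array([0.0, 0.1]), interval=(0.0, 0.2))
        np.testing.assert_allclose(ref.p_nose, [0.0, 0.0, 2.0])

    def test_no_valid_samples_suggests_other_interval(self):
        p = np.full((10, 3), np.nan)
        with pytest.raises(SessionDataError, match="interval"):
            reference_pose(traj_dict(p, p, p), np.arange(10) / 10.0, interval=(0.0, 1.0))


class TestRtv:
    def test_static_landmark_zero_velocity(self):
        p = np.tile([0.1, 0.2, 0.3], (20, 1))
        v = rtv(p, np.arange(20) / 10.0, ref=p[0])
        np.testing.assert_allclose(v[1:], 0.0, atol=1e-12)
        assert np.isnan(v[0]).all()

    def test_linear_drift_constant_velocity(self):
        t = np.arange(50) / 10.0
        p = np.zeros((50, 3))
        p[:, 0] = 0.01 * t
        v = rtv(p, t, ref=np.zeros(3))
        np.testing.assert_allclose(v[1:], [[0.01, 0.0, 0.0]] * 49, atol=1e-9)

    def test_reference_shift_does_not_change_velocity(self, rng):
        t = np.arange(30) / 10.0
        p = rng.normal(size=(30, 3))
        v1 = rtv(p, t, ref=np.zeros(3))
        v2 = rtv(p, t, ref=np.array([5.0, -3.0, 2.0]))
        np.testing.assert_allclose(v2[1:], v1[1:], atol=1e-9)

    def test_no_difference_across_mask_gaps(self, rng):
        t = np.arange(40) / 10.0
        p = rng.normal(size=(40, 3))
        valid = np.ones(40, dtype=bool)
        valid[10:20] = False
        v = rtv(p, t, ref=np.zeros(3), valid=valid)
        assert np.isnan(v[10:20]).all()
        assert np.isnan(v[20]).all()  # first sample after the gap restarts the run
        assert np.isfinite(v[21:]).all()

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(SessionDataError):
            rtv(np.zeros((3, 3)), np.array([0.0, 0.1, 0.1]), ref=np.zeros(3))


class TestTranslationalPci:
    def test_static_landmarks_zero(self):
        p = np.tile([0.0, 0.5, 1.0], (60, 1))
        t = np.arange(60) / 20.0
        v = rtv(p, t, ref=p[0])
        series = translational_pci(v, fs=20.0)
        np.testing.assert_allclose(series.value[np.isfinite(series.value)], 0.0, atol=1e-12)

    def test_lateral_oscillation_matches_analytic_derivative(self):
        fs, amp, f = 100.0, 0.02, 1.0
        t = np.arange(int(40 * fs)) / fs
        p = np.zeros((t.size, 3))
        p[:, 0] = amp * np.sin(2 * np.pi * f * t)
        v = rtv(p, t, ref=np.zeros(3))
        series = translational_pci(v, fs=fs, window=20.0)
        mid = series.value[~series.truncated]
        np.testing.assert_allclose(mid, 2 * np.pi * f * amp / np.sqrt(2), rtol=0.01)


class TestAxisEnergy:
    def test_single_axis_signal_takes_all_energy(self):
        t = np.arange(400) / 20.0
        a = np.zeros((t.size, 3))
        a[:, 2] = np.sin(2 * np.pi * 2.0 * t)
        summary = axis_energy_body(a, fs=20.0)
        np.testing.assert_allclose(summary.P, [0.0, 0.0, 100.0], atol=1e-9)
        assert summary.dominant_axis == "z"

    def test_equal_amplitudes_split_evenly(self):
        t = np.arange(2000) / 100.0
        a = np.column_stack(
            [
                np.sin(2 * np.pi * 3.0 * t),
                np.sin(2 * np.pi * 5.0 * t + 0.5),
                np.sin(2 * np.pi * 7.0 * t + 1.1),
            ]
        )
        summary = axis_energy_body(a, fs=100.0)
        np.testing.assert_allclose(summary.P, [100 / 3] * 3, atol=1.0)

    def test_two_to_one_amplitude_gives_half_share(self):
        t = np.arange(4000) / 100.0
        a = np.column_stack(
            [
                np.sin(2 * np.pi * 4.0 * t),
                np.sin(2 * np.pi * 4.0 * t + 2.0),
                2.0 * np.sin(2 * np.pi * 4.0 * t + 0.7),
            ]
        )
        summary = axis_energy_body(a, fs=100.0)
        assert summary.P[2] == pytest.approx(50.0, abs=1.0)

    def test_all_zero_signal_undefined(self):
        summary = axis_energy_body(np.zeros((100, 3)), fs=20.0)
        assert not summary.defined
        assert np.isnan(summary.P).all()

    def test_landmark_energy_pure_lateral_sway(self):
        t = np.arange(400) / 20.0
        v = np.zeros((t.size, 3))
        v[:, 0] = 0.05 * np.sin(2 * np.pi * 0.5 * t)
        summary = axis_energy_landmark(v, fs=20.0)
        np.testing.assert_allclose(summary.P, [100.0, 0.0, 0.0], atol=1e-9)

    def test_landmark_percentages_sum_to_100(self, rng):
        v = rng.normal(size=(300, 3))
        summary = axis_energy_landmark(v, fs=20.0)
        assert summary.P.sum() == pytest.approx(100.0, abs=1e-6)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(seed=st.integers(0, 500), perm_i=st.integers(0, 5))
def test_axis_percentages_permutation_equivariant(seed, perm_i):
    from itertools import permutations

    perm = list(permutations(range(3)))[perm_i]
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(200, 3)) * np.array([1.0, 2.0, 0.5])
    p1 = axis_energy_body(a, fs=20.0).P
    p2 = axis_energy_body(a[:, perm], fs=20.0).P
    np.testing.assert_allclose(p2, p1[list(perm)], atol=1e-9)


class TestAnthropometrics:
    def test_exact_geometry_zero_deviation(self):
        n = 10
        traj = {
            "lsh": np.tile([-0.2, 0.0, 1.0], (n, 1)),
            "rsh": np.tile([0.2, 0.0, 1.0], (n, 1)),
            "nose": np.tile([0.0, 0.3, 1.0], (n, 1)),
        }
        rep = anthropometrics(traj, d_sh_real=0.4, d_nm_real=0.3)
        np.testing.assert_allclose(rep.e_sh, 0.0, atol=1e-9)
        np.testing.assert_allclose(rep.e_nm, 0.0, atol=1e-9)

    def test_nose_distance_uses_shoulder_midpoint(self):
        n = 4
        traj = {
            "lsh": np.tile([-0.2, 0.0, 1.0], (n, 1)),
            "rsh": np.tile([0.2, 0.0, 1.0], (n, 1)),
            "nose": np.tile([0.0, 0.3, 1.0], (n, 1)),
        }
        rep = anthropometrics(traj, d_sh_real=0.4, d_nm_real=0.25)
        # d_nm = ||(0,0.3,1)-(0,0,1)|| = 0.3 m -> 50 mm deviation
        np.testing.assert_allclose(rep.e_nm, 50.0, atol=1e-9)

    def test_nonpositive_nominals_rejected(self):
        traj = {k: np.zeros((3, 3)) for k in ("nose", "lsh", "rsh")}
        with pytest.raises(ConfigError):
            anthropometrics(traj, d_sh_real=0.0, d_nm_real=0.3)

    def test_rigid_geometry_survives_full_dejitter_pipeline(self):
        from seatvib.pipeline import run_pipeline
        from seatvib.simulate import simulate_session
        from tests.conftest import noiseless_params

        params = noiseless_params(jitter=(2.0, 3.0, "y"))
        session, _ = simulate_session(params)
        res = run_pipeline(session)
        assert res.anthro.summary["e_sh"]["max_abs"] < 1e-6  # mm
        assert res.anthro.summary["e_nm"]["max_abs"] < 1e-6


def test_global_rotation_invariance(rng):
    """One world rotation applied to all landmarks leaves distances and
    PCI magnitudes unchanged."""
    t = np.arange(100) / 20.0
    traj = {
        "nose": np.tile([0.0, 0.65, 0.1], (100, 1)) + 0.01 * rng.normal(size=(100, 3)),
        "lsh": np.tile([-0.2, 0.45, 0.0], (100, 1)) + 0.01 * rng.normal(size=(100, 3)),
        "rsh": np.tile([0.2, 0.45, 0.0], (100, 1)) + 0.01 * rng.normal(size=(100, 3)),
    }
    R = Rotation.from_rotvec([0.4, -0.3, 0.9]).as_matrix()
    rot = {k: v @ R.T for k, v in traj.items()}

    rep1 = anthropometrics(traj, 0.4, 0.25)
    rep2 = anthropometrics(rot, 0.4, 0.25)
    np.testing.assert_allclose(rep2.e_sh, rep1.e_sh, atol=1e-9)
    np.testing.assert_allclose(rep2.e_nm, rep1.e_nm, atol=1e-9)

    for name in ("nose", "lsh", "rsh"):
        v1 = rtv(traj[name], t, ref=traj[name][:10].mean(axis=0))
        v2 = rtv(rot[name], t, ref=(traj[name][:10].mean(axis=0)) @ R.T)
        p1 = translational_pci(v1, fs=20.0).value
        p2 = translational_pci(v2, fs=20.0).value
        np.testing.assert_allclose(p2, p1, atol=1e-9)


def test_stronger_nose_compensation_orders_pci(rng):
    """Nose compensation 3x the shoulders' shows up as ordered medians."""
    from seatvib.pipeline import run_pipeline
    from seatvib.simulate import ScenarioParams, simulate_session

    comp = {
        "nose": (("x", 0.015, 0.5),),
        "lsh": (("z", 0.005, 0.4),),
        "rsh": (("z", 0.005, 0.4),),
    }
    params = ScenarioParams(duration=30.0, compensation=comp, seed=11)
    session, _ = simulate_session(params)
    res = run_pipeline(session)
    med = {n: np.nanmedian(res.pci_trans[n].value) for n in ("nose", "lsh", "rsh")}
    assert med["nose"] > med["lsh"] and med["nose"] > med["rsh"]
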