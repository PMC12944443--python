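import numpy as np
import pytest

from seatvib.simulate import ScenarioParams

NO_COMP = {"nose": (), "lsh": (), "rsh": ()}


def noiseless_params(**overrides) -> ScenarioParams:
    """A scenario with every noise source and artefact switched off."""
    base = dict(
        duration=10.0,
        compensation=dict(NO_COMP),
        torso_angular=(),
        jitter=(0.0, 3.0, "y"),
        seat_noise_sd=0.0,
        accel_noise_sd=0.0,
        gyro_noise_sd=0.0,
        landmark_noise_sd=0.0,
        events=(),
    )
    base.update(overrides)
    return ScenarioParams(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def degenerate_session():
    """Zero compensation/jitter/noise, unity gains: every metric has an
    exact expected value."""
    from seatvib.simulate import simulate_session

    params = noiseless_params(
        k_true=1.0, cam_gain=1.0, mount_resonance=(6.0, 0.0, "x")
    )
    return simulate_session(params)
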