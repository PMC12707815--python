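import numpy as np
import pytest

from hopdyn.config import PipelineConfig, SmoothingSpec
from hopdyn.leverage import MomentArmProfile
from hopdyn.synthgen import SyntheticTrialSpec, generate_trial
from hopdyn.trial_io import MarkerSet, REQUIRED_MARKERS


@pytest.fixture(scope="session")
def interp_config():
    """Pipeline config with interpolating splines (for noise-free input)."""
    return PipelineConfig(smoothing=SmoothingSpec(method="fixed_spline",
                                                  param=0.0))


@pytest.fixture(scope="session")
def profile():
    return MomentArmProfile()


@pytest.fixture(scope="session")
def noisefree_trial(interp_config):
    """One noise-free synthetic hop (20 kg, 2.5 m/s) with ground truth."""
    spec = SyntheticTrialSpec(body_mass=20.0, speed=2.5,
                              marker_noise_sigma=0.0, seed=11)
    return generate_trial(spec, config=interp_config)


@pytest.fixture(scope="session")
def noisy_trial():
    spec = SyntheticTrialSpec(body_mass=20.0, speed=3.1,
                              marker_noise_sigma=0.001, seed=23)
    return generate_trial(spec)


def static_markers(positions_2d: dict, n: int = 40, rate: float = 200.0,
                   z: float = 0.0) -> MarkerSet:
    """A MarkerSet holding a fixed pose for ``n`` frames."""
    time = np.arange(n) / rate
    pos = {}
    for name in REQUIRED_MARKERS:
        x, y = positions_2d.get(name, positions_2d.get("ilium", (0.0, 0.0)))
        pos[name] = np.tile([x, y, z], (n, 1)).astype(float)
    return MarkerSet(positions=pos, rate=rate, time=time)
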