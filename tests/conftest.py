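import numpy as np
import pytest

from oxygait.core import LatentGaitProfile
from oxygait.synthetic import SimulationConfig, generate_subject


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free, drift-free generator configuration for exact oracles."""
    return SimulationConfig(
        n_subjects=1,
        trial_duration=30.0,
        noise_sd=0.0,
        drift_slope=0.0,
        gait_noise_sd=0.0,
        latent_jitter=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def default_subject():
    """One subject under default (noisy) study conditions, 30 s trial."""
    config = SimulationConfig(n_subjects=1, trial_duration=30.0, seed=7)
    return config, generate_subject(config, 0, "speed")


def constant_latent(duration: float, rate: float, level: float = 0.6) -> LatentGaitProfile:
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    return LatentGaitProfile(
        time=t,
        speed_intensity=np.full(n, level),
        stride_intensity=np.full(n, level),
        mode="speed",
    )
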