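import numpy as np
import pytest

from cpcrquant.densitometry import LaneProfile
from cpcrquant.synthetic import SimConfig


def gaussian_profile(centers, areas, sigma=1.2, baseline=0.0, n=512, length=100.0,
                     lane_id="lane"):
    """Analytic multi-Gaussian lane used as a densitometry oracle."""
    x = np.linspace(0.0, length, n)
    y = np.full_like(x, float(baseline))
    for c, a in zip(centers, areas):
        y += a * np.exp(-0.5 * ((x - c) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    return LaneProfile(lane_id, x, y)


@pytest.fixture
def noiseless_cfg():
    """Generator config with every stochastic term switched off."""
    return SimConfig(
        seed=0, intensity_noise_cv=0.0, gas_noise_sd=0.0, profile_noise_sd=0.0
    )


@pytest.fixture
def noisy_cfg():
    """The study conditions: densitometry CV 0.1, gas noise 2 mL."""
    return SimConfig(seed=0)
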