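import numpy as np
import pytest
from hypothesis import settings

from monodplate.simulate import KineticTruth, SimulationConfig, simulate_plate

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def p_truth():
    """Ground-truth P kinetics of a representative culture."""
    return KineticTruth(mu_max=0.55, k_s=3.58)


@pytest.fixture
def p_plate(p_truth):
    """One noisy triplicate P plate for a single axenic culture."""
    cfg = SimulationConfig(
        truths={("PCC 7806 dmcyB", "axenic"): p_truth}, nutrient="P", seed=7
    )
    return simulate_plate(cfg)


@pytest.fixture
def noiseless_p_plate(p_truth):
    cfg = SimulationConfig(
        truths={("PCC 7806 dmcyB", "axenic"): p_truth},
        nutrient="P",
        seed=7,
        noise_sigma=0.0,
    )
    return simulate_plate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
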