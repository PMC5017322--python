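import numpy as np
import pytest
from hypothesis import settings

from gaittool.simulate import GaitSimParams, simulate_walk

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_walk():
    """Noise-free, symmetric walk at the default regime (cadence 140.87,
    step length 0.5683 m, 5 m window) with its ground truth."""
    params = GaitSimParams(noise_sd_g=0.0, asymmetry=0.0)
    session, truth = simulate_walk(params)
    return params, session, truth


@pytest.fixture(scope="session")
def noisy_walk():
    """Default walk with mild sensor noise (0.01 g SD)."""
    params = GaitSimParams(seed=42)
    session, truth = simulate_walk(params)
    return params, session, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
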