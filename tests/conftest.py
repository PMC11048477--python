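import numpy as np
import pytest

from nirsox import (
    NoiseModel,
    default_extinction_table,
    simulate_recording,
)


@pytest.fixture(scope="session")
def table():
    return default_extinction_table()


@pytest.fixture(scope="session")
def silent_exact_sim():
    """Noiseless recording under the Beer–Lambert-exact forward model."""
    return simulate_recording(noise=NoiseModel.silent(0), mode="mbll-exact")


@pytest.fixture(scope="session")
def silent_diffusion_sim():
    """Noiseless recording under the diffusion forward model."""
    return simulate_recording(noise=NoiseModel.silent(0), mode="diffusion")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
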