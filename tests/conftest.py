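import numpy as np
import pytest

from iplorg import synth


@pytest.fixture(scope="session")
def small_config():
    """Reduced grid for fast unit tests; physics identical to desk scale."""
    return synth.SystemConfig(nx=96, ny=80, nz=48)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One seeded small continuous-stimulation dataset, shared across tests."""
    return synth.generate_dataset(config=small_config, seed=7, n_volumes=30)


@pytest.fixture(scope="session")
def static_dataset(small_config):
    """Noise-free dynamics: no decorrelation, no bulk motion."""
    phantom = synth.default_phantom(small_config)
    phantom.decorrelation_times = [1e9] * len(phantom.decorrelation_times)
    return synth.generate_dataset(
        config=small_config, phantom=phantom, seed=5, n_volumes=16, motion=None,
        background=None,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
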