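import numpy as np
import pytest

from mediseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """One deterministic noise-free phantom shared across tests."""
    spec = PhantomSpec(volume_shape=(96, 96, 48), noise_sd=0.0, seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom():
    """A small noise-free phantom for geometry-heavy tests."""
    spec = PhantomSpec(volume_shape=(64, 64, 32), noise_sd=0.0, seed=3)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
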