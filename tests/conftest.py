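import numpy as np
import pytest

from mhseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom with its truth mask and spec."""
    return generate_phantom(PhantomSpec(speckle_looks=None, blur_sigma=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom (speckle looks 8, blur 1 px)."""
    return generate_phantom(PhantomSpec(seed=7))
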