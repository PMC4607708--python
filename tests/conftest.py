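import numpy as np
import pytest

from octpath.phantom import device_a_spec, generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default geometry, speckle and jitter disabled."""
    return generate_phantom(device_a_spec(speckle=False, jitter_max_px=0), seed=0)


@pytest.fixture(scope="session")
def speckled_phantom():
    """Default single-look phantom (speckle on, jitter ±3 px)."""
    return generate_phantom(device_a_spec(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
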