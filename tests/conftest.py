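import numpy as np
import pytest

from spikedeconv import make_exponential_kernel
from spikedeconv.simulate import SimParams, simulate_cell

FS = 100.0


@pytest.fixture(scope="session")
def kernel_1s():
    return make_exponential_kernel(1.0, FS)


@pytest.fixture(scope="session")
def noisy_cell():
    """One 100 s cell with moderate bursting and both noise sources."""
    params = SimParams(duration=100.0, r0=0.5, alpha=0.3, beta=0.01,
                       gamma=0.005, seed=11)
    return simulate_cell(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
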