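import numpy as np
import pytest

from diffsurrogate import GridSpec, generate_dataset


@pytest.fixture(scope="session")
def grid32() -> GridSpec:
    return GridSpec(L=32)


@pytest.fixture(scope="session")
def small_dataset(grid32):
    """A small 32x32 paired dataset shared across metric/training tests."""
    return generate_dataset(24, 1234, grid=grid32, radius=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
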