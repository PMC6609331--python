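import numpy as np
import pytest

from ornfidelity.encoder import (
    FiringFilter,
    sample_adaptation_params,
    sample_repertoire,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def repertoire():
    """A full-size (M=50, N=150) repertoire shared across tests."""
    return sample_repertoire(rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def adaptation():
    return sample_adaptation_params(rng=np.random.default_rng(1))


@pytest.fixture(scope="session")
def small_repertoire():
    """A small (M=10) repertoire for dynamics-heavy tests."""
    return sample_repertoire(m=10, rng=np.random.default_rng(2))


@pytest.fixture(scope="session")
def small_adaptation():
    return sample_adaptation_params(m=10, rng=np.random.default_rng(3))


@pytest.fixture(scope="session")
def firing_filter():
    return FiringFilter()
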