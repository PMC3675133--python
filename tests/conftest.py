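import numpy as np
import pytest

from thetahippo.dynamics import DynamicsParams
from thetahippo.network import ArchitectureConfig, build_network
from thetahippo.patterns import generate_vocabulary, make_training_set


@pytest.fixture(scope="session")
def default_params() -> DynamicsParams:
    return DynamicsParams()


@pytest.fixture(scope="session")
def small_vocab():
    """A 30-entry vocabulary at the default slot geometry (fast to build)."""
    return generate_vocabulary(n=30, rng=101)


@pytest.fixture(scope="session")
def full_vocab():
    """The default 100-entry vocabulary."""
    return generate_vocabulary(rng=202)


@pytest.fixture()
def tiny_network():
    """A small circuit (CA3=20, DG=100) for fast integration tests."""
    return build_network(ArchitectureConfig(n_ca3=20), rng=7)


@pytest.fixture()
def tiny_training_set(small_vocab):
    return make_training_set(small_vocab, 6, 8, rng=11)
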