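import numpy as np
import pytest

from aifcorr.grid import TimeGrid
from aifcorr.sequence_signal import build_dictionary
from aifcorr.data_factory import DatasetSpec, make_dataset


@pytest.fixture
def grid() -> TimeGrid:
    return TimeGrid()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dictionary():
    """The nominal signal dictionary at default sequence settings."""
    return build_dictionary()


@pytest.fixture(scope="session")
def small_splits():
    """A small but fully realistic dataset shared across tests."""
    spec = DatasetSpec(n_train=60, n_val=20, n_test=40, n_tissue=10, seed=99)
    return make_dataset(spec), spec
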