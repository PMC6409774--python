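import numpy as np
import pytest

from mapkminer import load_table2_fixture
from mapkminer.synthetic_data import make_proteome, make_reference_set


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def reference_set():
    return make_reference_set(seed=0)


@pytest.fixture(scope="session")
def small_proteome():
    """10 planted MPKs, 5 MKKs, 20 kinase decoys, 200 shuffles (seed 2)."""
    return make_proteome(10, 5, 20, 200, divergence=0.15, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
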