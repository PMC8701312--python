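import numpy as np
import pytest

from longicort import make_icosphere


@pytest.fixture(scope="session")
def small_mesh():
    """162-vertex icosphere (fast unit-test template)."""
    return make_icosphere(2, 100.0)


@pytest.fixture(scope="session")
def analysis_mesh():
    """2562-vertex icosphere at the analysis resolution."""
    return make_icosphere(4, 100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
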