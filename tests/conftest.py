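import numpy as np
import pytest

from standiff.connectome import Connectome, build_laplacian
from standiff.synthetic import make_connectome


@pytest.fixture(scope="session")
def small_conn():
    """12-region random geometric connectome."""
    return make_connectome(12, density=0.5, rng_seed=1)


@pytest.fixture(scope="session")
def small_lap(small_conn):
    return build_laplacian(small_conn)


@pytest.fixture(scope="session")
def conn78():
    """Full-size 78-region connectome shared by inference tests."""
    return make_connectome(78, density=0.3, rng_seed=2)


@pytest.fixture(scope="session")
def lap78(conn78):
    return build_laplacian(conn78)


@pytest.fixture
def two_node_lap():
    c = Connectome.from_array(np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"])
    return build_laplacian(c)
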