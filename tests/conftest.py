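import numpy as np
import pytest

from handdx.fixtures import example_graph
from handdx.qa import build_dictionary
from handdx.skeleton import default_topology
from handdx.synthetic import HandGeometry


@pytest.fixture(scope="session")
def topo():
    return default_topology()


@pytest.fixture(scope="session")
def geom():
    return HandGeometry()


@pytest.fixture(scope="session")
def graph():
    return example_graph()


@pytest.fixture(scope="session")
def dictionary(graph):
    return build_dictionary(graph)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240321)


def random_rotation(rng):
    """Uniform-ish random rotation matrix via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
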