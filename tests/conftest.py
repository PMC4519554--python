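import numpy as np
import pytest

from geohet.regionalization import SpatialWeights
from geohet.synthetic import reference_fixture, rook_lattice_weights


def path_weights(n: int) -> SpatialWeights:
    """Binary weights of a path graph 1-2-...-n."""
    W = np.zeros((n, n))
    for i in range(n - 1):
        W[i, i + 1] = W[i + 1, i] = 1.0
    return SpatialWeights(unit_ids=[f"p{i}" for i in range(n)], W=W)


@pytest.fixture(scope="session")
def path4() -> SpatialWeights:
    return path_weights(4)


@pytest.fixture(scope="session")
def pair_weights() -> SpatialWeights:
    return SpatialWeights(unit_ids=["a", "b"], W=np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture(scope="session")
def rook5x5() -> SpatialWeights:
    return rook_lattice_weights(5, 5)


@pytest.fixture(scope="session")
def rook6x6() -> SpatialWeights:
    return rook_lattice_weights(6, 6)


@pytest.fixture(scope="session")
def study_fixture():
    """Counts-exact 13-unit reference fixture (region, subject records)."""
    return reference_fixture()
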