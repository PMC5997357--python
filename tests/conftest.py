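import numpy as np
import pytest
import scipy.sparse as sp

from msping.connectivity import ConnectivityGraph, GridGeometry


@pytest.fixture(scope="session")
def geometry():
    return GridGeometry()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_unconnected_graph(n_exc: int = 1, n_inh: int = 1) -> ConnectivityGraph:
    """Minimal graph with no synapses, for single-neuron dynamics tests."""
    n = n_exc + n_inh
    is_exc = np.zeros(n, dtype=bool)
    is_exc[:n_exc] = True
    return ConnectivityGraph(
        weights=sp.csr_matrix((n, n)),
        is_exc=is_exc,
        area=np.zeros(n, dtype=np.int8),
        positions=np.zeros((n, 2)),
        geometry=GridGeometry(),
    )


@pytest.fixture()
def unconnected_pair():
    return make_unconnected_graph(1, 1)


@pytest.fixture(scope="session")
def small_v1_graph():
    """Full-size V1 graph built once per session (default projections)."""
    from msping.connectivity import build_v1_network

    return build_v1_network(GridGeometry(), rng=np.random.default_rng(7))
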