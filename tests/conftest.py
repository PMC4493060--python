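import numpy as np
import pytest

from netreconfig import Network, NodeTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def node_table4():
    return NodeTable(
        roi_id=np.arange(4),
        label=np.array([f"R{i}" for i in range(4)], dtype=object),
        coords=np.array([[0.0, 0, 0], [3, 4, 0], [0, 0, 2], [0, 0, 4]]),
        module=np.array(["A", "A", "B", "B"], dtype=object),
    )


def binary_net(adjacency, node_table=None) -> Network:
    return Network(np.asarray(adjacency, dtype=float), mode="binary", node_table=node_table)


def net_from_edges(n, edges, node_table=None, weights=None) -> Network:
    a = np.zeros((n, n))
    for idx, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[idx]
        a[i, j] = a[j, i] = w
    mode = "binary" if weights is None else "weighted"
    return Network(a, mode=mode, node_table=node_table)


@pytest.fixture
def complete4():
    a = np.ones((4, 4)) - np.eye(4)
    return binary_net(a)


@pytest.fixture
def path4():
    return net_from_edges(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def triangle_pendant():
    # triangle {0,1,2} plus pendant node 3 attached to node 0
    return net_from_edges(4, [(0, 1), (0, 2), (1, 2), (0, 3)])


@pytest.fixture
def star4():
    # center 0 with 3 leaves
    return net_from_edges(4, [(0, 1), (0, 2), (0, 3)])
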