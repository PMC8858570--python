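import numpy as np
import pytest

from ganlink.network_io import InteractionNetwork, canon_pair


def net_from_edges(edge_iter, extra_nodes=(), name="") -> InteractionNetwork:
    edges = {canon_pair(a, b) for a, b in edge_iter}
    nodes = {n for e in edges for n in e} | set(extra_nodes)
    return InteractionNetwork(nodes=nodes, edges=edges, name=name)


def path_network(n: int) -> InteractionNetwork:
    labels = [f"v{i:03d}" for i in range(n)]
    return net_from_edges(zip(labels, labels[1:]), name=f"path{n}")


def random_network(rng: np.random.Generator, n_nodes: int, n_edges: int):
    labels = [f"r{i:03d}" for i in range(n_nodes)]
    edges = set()
    while len(edges) < n_edges:
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            edges.add(canon_pair(labels[i], labels[j]))
    return net_from_edges(edges, extra_nodes=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def thousand_edge_network():
    """A fixed synthetic network with exactly 1000 edges."""
    gen = np.random.default_rng(7)
    labels = [f"n{i:03d}" for i in range(200)]
    edges = set()
    while len(edges) < 1000:
        i, j = gen.integers(0, 200, size=2)
        if i != j:
            edges.add(canon_pair(labels[i], labels[j]))
    return net_from_edges(edges, extra_nodes=labels)
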