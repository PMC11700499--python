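import networkx as nx
import numpy as np
import pytest

from hyperbrain.connectivity import BrainGraph


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def graph_from_adjacency(adj, prob=None):
    adj = np.asarray(adj, dtype=int)
    if prob is None:
        prob = adj.astype(float)
    return BrainGraph(adj, np.asarray(prob, dtype=float), threshold=0.5)


@pytest.fixture()
def path_graph5():
    return graph_from_adjacency(nx.to_numpy_array(nx.path_graph(5), dtype=int))


@pytest.fixture()
def random_graph(rng):
    """Connected-ish 12-node random graph with graded edge targets."""
    n = 12
    adj = (rng.uniform(size=(n, n)) < 0.35).astype(int)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    adj[0, 1] = adj[1, 0] = 1  # ensure at least one edge
    prob = adj * rng.uniform(0.3, 1.0, size=(n, n))
    prob = np.triu(prob, 1)
    prob = prob + prob.T
    return graph_from_adjacency(adj, prob)
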