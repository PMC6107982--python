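import networkx as nx
import numpy as np
import pytest

from muxcom import Layer, MultiplexNetwork, Partition


@pytest.fixture
def two_triangles():
    """Two unit-weight triangles joined by one bridge edge (6 vertices)."""
    edges = [("a", "b"), ("a", "c"), ("b", "c"),
             ("d", "e"), ("d", "f"), ("e", "f"), ("c", "d")]
    net = MultiplexNetwork([Layer.from_edges(edges)])
    part = Partition.from_communities([["a", "b", "c"], ["d", "e", "f"]])
    return net, part


@pytest.fixture
def triangle_net():
    return MultiplexNetwork([Layer.from_edges([(1, 2), (2, 3), (1, 3)])])


def random_layer(rng, n=7, p=0.5, weighted=False, ensure_edge=True):
    """Random G(n, p) layer on vertices 0..n-1, optionally with weights."""
    while True:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    w = float(rng.integers(1, 6)) if weighted else 1.0
                    g.add_edge(i, j, weight=w)
        if g.number_of_edges() > 0 or not ensure_edge:
            return Layer(g)


def random_multiplex(rng, n=7, n_layers=2, p=0.5, weighted=False):
    return MultiplexNetwork(
        [random_layer(rng, n=n, p=p, weighted=weighted)
         for _ in range(n_layers)])


def random_partition(rng, vertices, k):
    labels = rng.integers(0, k, size=len(vertices))
    return Partition({v: int(l) for v, l in zip(vertices, labels)})
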