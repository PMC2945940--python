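"""Shared fixtures: tiny hand-built networks and seeded random graphs."""

import networkx as nx
import numpy as np
import pytest

from netprio.network import Network, build_matrices


def make_network(edges, extra_nodes=(), name="fixture"):
    """Build a Network from (a, b, w) triples, nodes in first-seen order."""
    g = nx.Graph()
    order = []
    seen = set()
    for a, b, w in edges:
        for x in (a, b):
            if x not in seen:
                seen.add(x)
                order.append(x)
        g.add_edge(a, b, weight=float(w))
    for x in extra_nodes:
        if x not in seen:
            seen.add(x)
            order.append(x)
            g.add_node(x)
    return Network(tuple(order), g, name=name)


def random_network(n, p=0.3, seed=0, connected=False):
    """Seeded Erdos-Renyi network with uniform weights in (0.1, 1]."""
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        if not connected or nx.is_connected(g):
            break
    edges = [
        (f"g{a:03d}", f"g{b:03d}", float(rng.uniform(0.1, 1.0)))
        for a, b in sorted(g.edges())
    ]
    return make_network(edges, extra_nodes=[f"g{i:03d}" for i in range(n)])


@pytest.fixture
def single_edge_net():
    return make_network([("g1", "g2", 1.0)])


@pytest.fixture
def single_edge_mats(single_edge_net):
    return build_matrices(single_edge_net)


@pytest.fixture
def triangle_mats():
    return build_matrices(
        make_network([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
    )
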