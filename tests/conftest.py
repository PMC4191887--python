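"""Shared fixtures: small hand-built networks and planted universes."""

from itertools import combinations

import pytest

from modulin.network import AnnotatedNetwork, InteractionRecord
from modulin.synthetic import PlantedModel, generate_universe


def build_network(edges):
    """Network from (a, b) or (a, b, label) or (a, b, label, n_sources) tuples."""
    net = AnnotatedNetwork()
    for edge in edges:
        a, b = edge[0], edge[1]
        label = edge[2] if len(edge) > 2 else "unclassified"
        n_sources = edge[3] if len(edge) > 3 else 1
        net.add_edge(InteractionRecord(a=a, b=b, label=label, n_sources=n_sources))
    return net


def clique_edges(names, label="unclassified"):
    return [(a, b, label) for a, b in combinations(names, 2)]


@pytest.fixture
def two_cliques():
    """Two 5-cliques joined by a single bridge edge."""
    a = [f"A{i}" for i in range(5)]
    b = [f"B{i}" for i in range(5)]
    return build_network(clique_edges(a) + clique_edges(b) + [("A0", "B0")])


@pytest.fixture
def triangle_ring():
    """Ring of 4 triangles: triangles joined corner-to-corner in a cycle."""
    edges = []
    for t in range(4):
        n = [f"T{t}a", f"T{t}b", f"T{t}c"]
        edges += clique_edges(n)
    for t in range(4):
        edges.append((f"T{t}c", f"T{(t + 1) % 4}a"))
    return build_network(edges)


@pytest.fixture(scope="session")
def small_universe():
    """A small planted universe with inventories (session-cached)."""
    model = PlantedModel(module_sizes=(12, 12, 12), p_in=0.4, p_out=0.05,
                         beta_within_ddi=0.9, beta_between_dli=0.9, seed=101)
    return generate_universe(model)
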