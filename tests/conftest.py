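"""Shared fixtures: tiny hand-built networks and planted benchmarks."""

import networkx as nx
import numpy as np
import pytest

from netboxpy import (
    AlteredGeneSet,
    InteractionNetwork,
    PlantedConfig,
    generate_planted,
)


def net_from_edges(edges, extra_nodes=()):
    """Build an InteractionNetwork from an edge list of string pairs."""
    net = InteractionNetwork()
    for u, v in edges:
        net.add_node(u)
        net.add_node(v)
        net.add_edge(u, v)
    for n in extra_nodes:
        net.add_node(n)
    return net


def random_network(rng, n_nodes=10, p=0.3):
    g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
    net = InteractionNetwork()
    for n in g.nodes:
        net.add_node(f"g{n}")
    for u, v in g.edges:
        net.add_edge(f"g{u}", f"g{v}")
    return net


@pytest.fixture
def two_triangles_bridge():
    """Two triangles joined by a single bridge edge: the classic two-module graph."""
    return net_from_edges(
        [("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
         ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
         ("a1", "b1")]
    )


@pytest.fixture
def path_alb():
    """Path A - L - B, with A and B altered: L is the canonical linker."""
    net = net_from_edges([("A", "L"), ("L", "B")])
    altered = AlteredGeneSet.from_genes(["A", "B"], net)
    return net, altered


@pytest.fixture(scope="session")
def planted_default():
    """One draw of the reference planted-module benchmark."""
    return generate_planted(PlantedConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
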