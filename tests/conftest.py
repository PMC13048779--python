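"""Shared fixtures: hand-built and randomly seeded EDA-graphs."""

from __future__ import annotations

import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from edagraph.graph import EdaGraph

#: Dyadic edge weights whose reciprocals (edge lengths) are exactly
#: representable in binary, so shortest-path sums are exact and tie
#: detection is order-independent in both implementation and oracle.
DYADIC_WEIGHTS = (1.0, 2.0, 4.0, 8.0)


def make_edagraph(weighted_edges, n_nodes: int | None = None, Q: float = 0.05,
                  k: int = 8) -> EdaGraph:
    """Build an EdaGraph directly from ``(u, v, weight)`` tuples on nodes
    0..n-1; edge length is 1/weight."""
    if n_nodes is None:
        n_nodes = 1 + max((max(u, v) for u, v, _ in weighted_edges), default=0)
    g = nx.Graph()
    for i in range(n_nodes):
        g.add_node(i, value=i * Q)
    for u, v, w in weighted_edges:
        g.add_edge(u, v, weight=float(w), distance=1.0 / float(w))
    return EdaGraph(graph=g, Q=Q, k=k, node_order=np.arange(n_nodes))


def random_edagraph(seed: int, max_nodes: int = 8) -> EdaGraph:
    """Random small weighted graph with dyadic weights (may be disconnected
    or edgeless; single-node graphs occur)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, max_nodes + 1))
    p = rng.choice([0.25, 0.5, 0.8])
    edges = []
    for u in range(n):
        for v in range(u + 1, n):
            if rng.uniform() < p:
                edges.append((u, v, float(rng.choice(DYADIC_WEIGHTS))))
    return make_edagraph(edges, n_nodes=n)


@pytest.fixture
def k3() -> EdaGraph:
    """Unweighted triangle."""
    return make_edagraph([(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])


@pytest.fixture
def p3() -> EdaGraph:
    """Unweighted 3-node path."""
    return make_edagraph([(0, 1, 1.0), (1, 2, 1.0)])


@pytest.fixture
def star4() -> EdaGraph:
    """Star: center node 0 plus 3 leaves, unweighted."""
    return make_edagraph([(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)])


@pytest.fixture
def c4() -> EdaGraph:
    """Unweighted 4-cycle (vertex-transitive)."""
    return make_edagraph([(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 0, 1.0)])


@pytest.fixture
def single_node() -> EdaGraph:
    return make_edagraph([], n_nodes=1)
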