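"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from pknet.interactome import Interactome


def make_net(edges, provenance="test") -> Interactome:
    g = nx.Graph()
    g.add_edges_from(edges)
    return Interactome(graph=g, provenance=provenance)


def floyd_warshall(net: Interactome) -> dict[tuple[str, str], float]:
    """Independent all-pairs shortest paths by explicit Floyd–Warshall
    (no networkx shortest-path machinery)."""
    nodes = sorted(net.graph.nodes)
    inf = float("inf")
    d = {(u, v): (0.0 if u == v else inf) for u in nodes for v in nodes}
    for u, v in net.graph.edges:
        d[(u, v)] = d[(v, u)] = 1.0
    for k, i, j in itertools.product(nodes, nodes, nodes):
        via = d[(i, k)] + d[(k, j)]
        if via < d[(i, j)]:
            d[(i, j)] = via
    return d


def brute_force_separation(net: Interactome, a: set, b: set) -> float:
    """S_AB recomputed from a full distance matrix, independently of the
    implementation under test."""
    d = floyd_warshall(net)

    def mean_internal(s):
        if len(s) == 1:
            return 0.0
        return float(np.mean([min(d[(x, y)] for y in s if y != x) for x in s]))

    def mean_cross(s, t):
        vals = [min(d[(x, y)] for y in t) for x in s]
        vals += [min(d[(y, x)] for x in s) for y in t]
        return float(np.mean(vals))

    return mean_cross(a, b) - (mean_internal(a) + mean_internal(b)) / 2.0


def random_connected_net(rng: np.random.Generator, max_nodes: int = 25) -> Interactome:
    """Erdos–Renyi graph resampled until connected."""
    while True:
        n = int(rng.integers(4, max_nodes + 1))
        p = float(rng.uniform(0.15, 0.5))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        if nx.is_connected(g) and g.number_of_edges() > 0:
            return Interactome(
                graph=nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes}),
                provenance="random",
            )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20221104)
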