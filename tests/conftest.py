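"""Shared fixtures and independent oracles for the test suite.

The betweenness oracle here deliberately avoids the Brandes accumulation
used by the implementation: shortest-path counts come from adjacency-matrix
powers (a walk whose length equals the graph distance is necessarily a
simple shortest path), and pair dependencies are summed explicitly over all
node pairs.  It is exact for small graphs and O(n^4), which is fine at the
sizes the tests use.
"""

from __future__ import annotations

import numpy as np
import pytest

from msmt_netpharm.graph import PPIGraph, build_graph


def matrix_power_bc(graph: PPIGraph) -> dict[str, float]:
    """Exhaustive betweenness via adjacency-matrix path counting."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adjacency = np.zeros((n, n), dtype=np.int64)
    for a, b in graph.edges:
        adjacency[index[a], index[b]] = adjacency[index[b], index[a]] = 1
    powers = [np.eye(n, dtype=np.int64)]
    for _ in range(n):
        powers.append(powers[-1] @ adjacency)
    dist = np.full((n, n), -1, dtype=np.int64)
    np.fill_diagonal(dist, 0)
    for length in range(1, n + 1):
        newly = (dist < 0) & (powers[length] > 0)
        dist[newly] = length
    bc = dict.fromkeys(nodes, 0.0)
    for s in range(n):
        for t in range(s + 1, n):
            d = dist[s, t]
            if d <= 0:
                continue
            total = powers[d][s, t]
            for v in range(n):
                if v in (s, t):
                    continue
                d1, d2 = dist[s, v], dist[v, t]
                if d1 > 0 and d2 > 0 and d1 + d2 == d:
                    bc[nodes[v]] += powers[d1][s, v] * powers[d2][v, t] / total
    return bc


def random_simple_graph(rng: np.random.Generator, n_max: int = 12) -> PPIGraph:
    """A random simple graph on at most ``n_max`` nodes (possibly
    disconnected), for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.6))
    symbols = [f"N{i:02d}" for i in range(n)]
    rows = [
        (symbols[i], symbols[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    if not rows:  # keep at least one edge so the graph is non-empty
        rows = [(symbols[0], symbols[1])]
    return build_graph(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def path_graph() -> PPIGraph:
    return build_graph([("A", "B"), ("B", "C")])


@pytest.fixture
def star_graph() -> PPIGraph:
    return build_graph([("X", "L1"), ("X", "L2"), ("X", "L3")])


@pytest.fixture
def cycle4_graph() -> PPIGraph:
    return build_graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
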