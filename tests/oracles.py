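"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: exhaustive edge relaxation for shortest paths and
direct summation for network efficiency, kept free of any scipy/networkx
shortest-path machinery so they constitute a second route.
"""

from __future__ import annotations

import numpy as np


def brute_force_distances(nodes, edges):
    """All-pairs shortest-path lengths by exhaustive Bellman-Ford relaxation.

    ``edges`` are (a, b, weight); each edge contributes length 1/weight.
    """
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    lengths = [(idx[a], idx[b], 1.0 / w) for a, b, w in edges]
    for _ in range(n):  # n rounds guarantee convergence
        changed = False
        for i, j, ell in lengths:
            for s in range(n):
                if D[s, i] + ell < D[s, j]:
                    D[s, j] = D[s, i] + ell
                    changed = True
                if D[s, j] + ell < D[s, i]:
                    D[s, i] = D[s, j] + ell
                    changed = True
        if not changed:
            break
    return D


def brute_force_efficiency(nodes, edges):
    """Sum over ordered pairs of inverse shortest-path length."""
    D = brute_force_distances(nodes, edges)
    total = 0.0
    n = len(nodes)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                total += 1.0 / D[i, j]
    return total


def random_weighted_graph(rng, max_nodes=8, unit_weights=False):
    """A random simple graph (node list, edge list) for oracle comparisons."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = list(range(1, n + 1))
    edges = []
    for a in range(1, n + 1):
        for b in range(a + 1, n + 1):
            if rng.random() < 0.45:
                w = 1.0 if unit_weights else float(rng.uniform(0.1, 2.0))
                edges.append((a, b, w))
    return nodes, edges
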