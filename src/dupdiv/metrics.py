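"""Damage metrics: network efficiency, average ego edges, isolated count.

Network efficiency (NE) is the sum over ordered node pairs i != j of
1/d_ij, where d_ij is the weighted shortest-path length with each edge
contributing length 1/weight, and disconnected pairs contribute 0. The
1/weight convention means halving an edge weight doubles that edge's
length, so attenuation attacks strictly damage NE. For unit weights NE
reduces to the hop-count version, and NE(K_n) = n(n-1). No normalisation
by n(n-1) is applied.

The average ego-edge count is the mean over ALL nodes (isolated nodes
included, contributing 0) of the number of edges inside the closed 1-step
ego network — the ego, its alters, and every edge among them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import ConfigError, EmptyGraphError
from .graph import WeightedGraph

__all__ = [
    "DamageMetrics",
    "network_efficiency",
    "avg_ego_edges",
    "count_isolated",
    "damage",
    "damage_metrics",
    "path_length_matrix",
    "METRIC_NAMES",
]

METRIC_NAMES = ("ne", "avg_ego_edges", "n_isolated")


@dataclass(frozen=True)
class DamageMetrics:
    """The three damage measures evaluated on one graph state."""

    ne: float
    avg_ego_edges: float
    n_isolated: int


def _core_distance_matrix(G: WeightedGraph) -> np.ndarray | None:
    """All-pairs shortest-path lengths over the positive-degree core.

    Isolated nodes are excluded — they are at infinite distance from
    everything and contribute 0 to NE. Returns None for an empty core.
    """
    edges = G.edges()
    if not edges:
        return None
    core: dict[int, int] = {}
    rows, cols, data = [], [], []
    for a, b, w in edges:
        ia = core.setdefault(a, len(core))
        ib = core.setdefault(b, len(core))
        rows.append(ia)
        cols.append(ib)
        data.append(1.0 / w)
    k = len(core)
    A = csr_matrix((data, (rows, cols)), shape=(k, k))
    return shortest_path(A, method="D", directed=False)


def network_efficiency(G: WeightedGraph) -> float:
    """Sum of 1/d_ij over ordered pairs i != j (1/inf := 0)."""
    D = _core_distance_matrix(G)
    if D is None:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum())


def path_length_matrix(G: WeightedGraph) -> pd.DataFrame:
    """Pairwise shortest-path lengths (edge length = 1/weight) for all nodes.

    Unreachable pairs hold ``inf``; the diagonal is 0. Intended for small
    graphs and oracle comparisons; NE uses a faster internal path.
    """
    nodes = list(G.nodes)
    n = len(nodes)
    full = np.full((n, n), np.inf)
    np.fill_diagonal(full, 0.0)
    D = _core_distance_matrix(G)
    if D is not None:
        core_nodes = []
        seen = set()
        for a, b, _ in G.edges():
            for v in (a, b):
                if v not in seen:
                    seen.add(v)
                    core_nodes.append(v)
        pos = {v: i for i, v in enumerate(nodes)}
        idx = np.array([pos[v] for v in core_nodes])
        full[np.ix_(idx, idx)] = D
    return pd.DataFrame(full, index=nodes, columns=nodes)


def avg_ego_edges(G: WeightedGraph) -> float:
    """Mean internal edge count of the closed 1-step ego networks of all nodes."""
    if G.n_nodes == 0:
        raise EmptyGraphError("average ego edges is undefined on an empty node set")
    nbrs = {v: set(G.neighbors(v)) for v in G.nodes}
    total = 0
    for v, nv in nbrs.items():
        internal = len(nv)  # ego-alter edges
        for u in nv:
            internal += sum(1 for w in nbrs[u] if w > u and w in nv)
        total += internal
    return total / G.n_nodes


def count_isolated(G: WeightedGraph) -> int:
    """Number of degree-0 nodes (only weight > 0 edges exist at all)."""
    return len(G.isolated_nodes())


def damage_metrics(G: WeightedGraph) -> DamageMetrics:
    """Evaluate all three damage measures on the current graph state."""
    return DamageMetrics(
        ne=network_efficiency(G),
        avg_ego_edges=avg_ego_edges(G),
        n_isolated=count_isolated(G),
    )


def damage(before: DamageMetrics, after: DamageMetrics, which: str) -> float:
    """Signed damage of an attack: positive numbers always mean more harm.

    NE and the ego-edge average drop under attack (damage = before - after);
    the isolated count rises (damage = after - before).
    """
    if which == "ne":
        return before.ne - after.ne
    if which == "avg_ego_edges":
        return before.avg_ego_edges - after.avg_ego_edges
    if which == "n_isolated":
        return after.n_isolated - before.n_isolated
    raise ConfigError(f"unknown metric {which!r}; expected one of {METRIC_NAMES}")
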