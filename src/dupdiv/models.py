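"""Generative network models.

Three stochastic models produce :class:`~dupdiv.graph.WeightedGraph`
instances with unit edge weights:

* ``sample_gnm`` — the Bernoulli random graph G(n, M), drawn uniformly from
  all simple graphs on n nodes with exactly M edges;
* ``dd_generate`` — the standard duplication–divergence model DD(t0, p):
  start from the complete graph on ``t0`` nodes, then repeatedly duplicate a
  uniformly chosen parent, giving the copy a candidate edge to each parent
  neighbour, each retained independently with probability ``p``. No
  parent–child edge is ever created.
* ``dd_nodeloss_generate`` — the duplication–divergence model with node
  loss: after every duplication-and-divergence step, isolated nodes are
  removed with probability ``q`` each, mimicking gene loss. Removed ids are
  retired, never reused.

All generators are bit-reproducible given (params, seed), and the node-loss
model with ``q = 0`` replays the exact same duplication history as the
standard model under the same seed (independent named substreams; see
:mod:`dupdiv._rng`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .errors import ConfigError
from .graph import WeightedGraph

__all__ = [
    "GnmParams",
    "DDParams",
    "NodeLossParams",
    "sample_gnm",
    "dd_generate",
    "dd_nodeloss_generate",
    "LOSS_MODES",
]

LOSS_MODES = ("all_isolated", "newest_only")


@dataclass(frozen=True)
class GnmParams:
    """Size parameters of the uniform G(n, M) random graph."""

    n: int
    M: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        if not 0 <= self.M <= self.N:
            raise ConfigError(f"M must lie in [0, {self.N}], got {self.M}")

    @property
    def N(self) -> int:
        """Number of unordered node pairs, n(n-1)/2."""
        return self.n * (self.n - 1) // 2

    @property
    def p(self) -> float:
        """Edge density M/N (0 for the single-node graph)."""
        return self.M / self.N if self.N else 0.0


@dataclass(frozen=True)
class DDParams:
    """Parameters of the standard duplication–divergence model.

    ``p`` is the divergence retention probability; ``steps`` counts
    duplication events (not the final node count); ``t0`` the size of the
    initial complete graph, 3 by default so generated networks start from a
    triangle and can carry nonzero clustering.
    """

    p: float
    steps: int
    t0: int = field(default=3, kw_only=True)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ConfigError(f"retention probability p must be in [0,1], got {self.p}")
        if self.steps < 0:
            raise ConfigError(f"steps must be >= 0, got {self.steps}")
        if self.t0 < 2:
            raise ConfigError(f"t0 must be >= 2, got {self.t0}")


@dataclass(frozen=True)
class NodeLossParams(DDParams):
    """DD parameters plus a per-step loss probability ``q`` for isolated nodes.

    ``loss_mode`` selects which isolated nodes face the loss trial each step:
    ``newest_only`` (default) tests only the just-added node, so an isolated
    protein that survives its birth step persists — isolated nodes can never
    regain edges in this model, and this reading keeps their long-run
    proportion strictly between 0 and 1; ``all_isolated`` tests every
    currently isolated node independently each step, which eventually purges
    all of them (the proportion collapses back towards 0).
    """

    q: float = 0.0
    loss_mode: str = field(default="newest_only", kw_only=True)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0.0 <= self.q <= 1.0:
            raise ConfigError(f"loss probability q must be in [0,1], got {self.q}")
        if self.loss_mode not in LOSS_MODES:
            raise ConfigError(f"loss_mode must be one of {LOSS_MODES}, got {self.loss_mode!r}")


# ---------------------------------------------------------------------------
# G(n, M)


def _decode_pair(idx: np.ndarray, n: int) -> list[tuple[int, int]]:
    """Map pair indices 0..N-1 to node pairs (i, j), 1 <= i < j <= n.

    Index k counts pairs in lexicographic order: (1,2), (1,3), ..., (2,3), ...
    """
    out = []
    for k in idx:
        k = int(k)
        # first endpoint a in 0-based: largest a with a*n - a*(a+1)/2 <= k
        b2 = 2 * n - 1
        a = int((b2 - math.sqrt(b2 * b2 - 8 * k)) // 2)
        while a * n - a * (a + 1) // 2 > k:
            a -= 1
        while (a + 1) * n - (a + 1) * (a + 2) // 2 <= k:
            a += 1
        offset = k - (a * n - a * (a + 1) // 2)
        out.append((a + 1, a + 2 + offset))
    return out


def sample_gnm(params: GnmParams, seed: int) -> WeightedGraph:
    """Draw a uniform G(n, M) graph on nodes 1..n with unit edge weights.

    M distinct unordered pairs are chosen uniformly without replacement, so
    each of the C(N, M) edge sets is equally likely.
    """
    rng = substream(seed, "gnm-pairs")
    n, M, N = params.n, params.M, params.N
    if M == 0:
        idx = np.empty(0, dtype=np.int64)
    elif N <= 4_000_000 or 3 * M > N:
        idx = rng.choice(N, size=M, replace=False)
    else:  # sparse regime on a huge pair universe: rejection with a seen-set
        seen: set[int] = set()
        while len(seen) < M:
            for k in rng.integers(N, size=M - len(seen)):
                seen.add(int(k))
        idx = np.fromiter(seen, dtype=np.int64)
    pairs = _decode_pair(np.sort(idx), n)
    return WeightedGraph.from_edges(range(1, n + 1), [(a, b, 1.0) for a, b in pairs])


# ---------------------------------------------------------------------------
# duplication–divergence growth


def _grow(params: DDParams, q: float, loss_mode: str, seed: int) -> WeightedGraph:
    rng_parent = substream(seed, "dd-parent")
    rng_keep = substream(seed, "dd-retention")
    rng_loss = substream(seed, "dd-loss")
    p = params.p

    adj: dict[int, set[int]] = {v: set() for v in range(1, params.t0 + 1)}
    for a in range(1, params.t0 + 1):
        for b in range(a + 1, params.t0 + 1):
            adj[a].add(b)
            adj[b].add(a)
    next_id = params.t0 + 1
    removed: set[int] = set()

    for _ in range(params.steps):
        nodes = sorted(adj)
        parent = nodes[int(rng_parent.integers(len(nodes)))]
        child = next_id
        next_id += 1
        candidates = sorted(adj[parent])  # parent itself excluded: no parent-child edge
        adj[child] = set()
        if candidates:
            keep = rng_keep.random(len(candidates)) < p
            for nb, k in zip(candidates, keep):
                if k:
                    adj[child].add(nb)
                    adj[nb].add(child)
        if q > 0.0:
            if loss_mode == "all_isolated":
                trial = [v for v in sorted(adj) if not adj[v]]
            else:  # newest_only
                trial = [child] if not adj[child] else []
            if trial:
                lost = rng_loss.random(len(trial)) < q
                for v, dead in zip(trial, lost):
                    if dead:
                        del adj[v]
                        removed.add(v)

    g = WeightedGraph()
    for v in sorted(adj):
        g.add_node(v)
    for a in sorted(adj):
        for b in adj[a]:
            if a < b:
                g.add_edge(a, b, 1.0)
    # retire lost ids and remember the highest id ever assigned
    g._retired.update(removed)
    g._max_id = max(g._max_id, next_id - 1)
    return g


def dd_generate(params: DDParams, seed: int) -> WeightedGraph:
    """Grow a standard duplication–divergence network DD(t0, p).

    The result has exactly ``t0 + steps`` nodes; a new node is never linked
    to its parent at creation time.
    """
    return _grow(params, q=0.0, loss_mode="all_isolated", seed=seed)


def dd_nodeloss_generate(params: NodeLossParams, seed: int) -> WeightedGraph:
    """Grow a duplication–divergence network with node loss.

    After each duplication-and-divergence step, isolated nodes (per
    ``params.loss_mode``) are independently removed with probability ``q``;
    the just-added node participates in the loss step of its own iteration.
    Final node count is at most ``t0 + steps``.
    """
    return _grow(params, q=params.q, loss_mode=params.loss_mode, seed=seed)
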