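"""Weighted undirected graph substrate.

:class:`WeightedGraph` is the single container on which generative models,
attacks and damage metrics operate. It is a simple undirected graph with
strictly positive real edge weights (dimensionless interaction strengths,
initialised to 1 for all generated and loaded networks) and an explicit node
set, so that isolated proteins are representable. Three invariants are
enforced at every mutation:

* no self-loops, at most one edge per unordered pair;
* an edge exists iff its weight is > 0 — attenuation (weight halving) can
  therefore never delete an edge or isolate a node, while knockout removes
  the edge entry entirely;
* node identifiers are integers that are never reused after deletion within
  one graph's lifetime, which keeps simulated gene-loss trajectories
  auditable.

The adjacency structure is backed by :class:`networkx.Graph`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx

from .errors import (
    DuplicateEdgeError,
    NonPositiveWeightError,
    RetiredNodeError,
    SelfLoopError,
    UnknownFixtureError,
    UnknownNodeError,
)

__all__ = ["WeightedGraph", "EgoNetwork", "build_graph", "make_fixture"]


@dataclass(frozen=True)
class EgoNetwork:
    """The 1-step (closed-neighbourhood) ego network of a focal node.

    ``members`` is the ego plus its alters; ``internal_edges`` are all parent
    edges with both endpoints among the members, ego-alter edges included.
    An isolated ego yields ``members == {ego}`` and no internal edges.
    """

    ego: int
    members: frozenset[int]
    internal_edges: tuple[tuple[int, int, float], ...]

    @property
    def n_edges(self) -> int:
        return len(self.internal_edges)


class WeightedGraph:
    """Simple undirected graph with positive edge weights and stable node ids."""

    __slots__ = ("_g", "_retired", "_max_id")

    def __init__(self) -> None:
        self._g = nx.Graph()
        self._retired: set[int] = set()
        self._max_id = 0

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        node_ids: Iterable[int],
        weighted_edges: Iterable[tuple[int, int, float]] = (),
    ) -> "WeightedGraph":
        """Build a graph from an explicit node universe and weighted edge list.

        Rejects self-loops, non-positive weights, duplicate unordered pairs
        and endpoints outside ``node_ids``, each with a distinct exception.
        """
        g = cls()
        for v in node_ids:
            g.add_node(int(v))
        for a, b, w in weighted_edges:
            g.add_edge(a, b, w)
        return g

    def copy(self) -> "WeightedGraph":
        new = WeightedGraph()
        new._g = self._g.copy()
        new._retired = set(self._retired)
        new._max_id = self._max_id
        return new

    # -- nodes -------------------------------------------------------------

    def add_node(self, v: int | None = None) -> int:
        """Add a node; with ``v=None`` the next unused id is assigned."""
        if v is None:
            v = self._max_id + 1
        v = int(v)
        if v in self._retired:
            raise RetiredNodeError(f"node id {v} was retired and cannot be reused")
        if self._g.has_node(v):
            raise DuplicateEdgeError(f"node {v} already present")
        self._g.add_node(v)
        self._max_id = max(self._max_id, v)
        return v

    def remove_node(self, v: int) -> None:
        """Delete a node and its incident edges; the id is retired for good."""
        self._require(v)
        self._g.remove_node(v)
        self._retired.add(v)

    @property
    def node_ids(self) -> frozenset[int]:
        return frozenset(self._g.nodes)

    @property
    def nodes(self) -> tuple[int, ...]:
        return tuple(sorted(self._g.nodes))

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def retired_ids(self) -> frozenset[int]:
        return frozenset(self._retired)

    def __contains__(self, v: int) -> bool:
        return self._g.has_node(v)

    def __iter__(self) -> Iterator[int]:
        return iter(self.nodes)

    def _require(self, v: int) -> None:
        if not self._g.has_node(v):
            raise UnknownNodeError(f"node {v} is not in the graph")

    # -- edges -------------------------------------------------------------

    def add_edge(self, a: int, b: int, weight: float = 1.0) -> None:
        a, b = int(a), int(b)
        if a == b:
            raise SelfLoopError(f"self-loop on node {a}")
        for v in (a, b):
            self._require(v)
        if self._g.has_edge(a, b):
            raise DuplicateEdgeError(f"edge {{{a},{b}}} supplied twice")
        w = float(weight)
        if not w > 0.0:
            raise NonPositiveWeightError(f"edge {{{a},{b}}} has weight {w} <= 0")
        self._g.add_edge(a, b, weight=w)

    def remove_edge(self, a: int, b: int) -> None:
        if not self._g.has_edge(a, b):
            raise UnknownNodeError(f"edge {{{a},{b}}} is not in the graph")
        self._g.remove_edge(a, b)

    def set_weight(self, a: int, b: int, weight: float) -> None:
        """Reassign an edge weight; weights <= 0 are rejected (use remove_edge)."""
        if not self._g.has_edge(a, b):
            raise UnknownNodeError(f"edge {{{a},{b}}} is not in the graph")
        w = float(weight)
        if not w > 0.0:
            raise NonPositiveWeightError(
                f"weight {w} <= 0; edges are removed, never zero-weighted"
            )
        self._g[a][b]["weight"] = w

    def has_edge(self, a: int, b: int) -> bool:
        return self._g.has_edge(a, b)

    def weight(self, a: int, b: int) -> float:
        if not self._g.has_edge(a, b):
            raise UnknownNodeError(f"edge {{{a},{b}}} is not in the graph")
        return self._g[a][b]["weight"]

    def edges(self) -> list[tuple[int, int, float]]:
        """All edges as (a, b, weight) with a < b, sorted — deterministic order."""
        out = [
            (a, b, d["weight"]) if a < b else (b, a, d["weight"])
            for a, b, d in self._g.edges(data=True)
        ]
        out.sort()
        return out

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, v: int) -> int:
        self._require(v)
        return self._g.degree(v)

    def neighbors(self, v: int) -> tuple[int, ...]:
        self._require(v)
        return tuple(sorted(self._g.neighbors(v)))

    def isolated_nodes(self) -> tuple[int, ...]:
        return tuple(sorted(v for v in self._g.nodes if self._g.degree(v) == 0))

    # -- derived views -----------------------------------------------------

    def ego_network(self, v: int) -> EgoNetwork:
        """The closed 1-step ego network of ``v`` (see :class:`EgoNetwork`)."""
        self._require(v)
        members = {v, *self._g.neighbors(v)}
        internal = []
        for a in members:
            for b in self._g.neighbors(a):
                if a < b and b in members:
                    internal.append((a, b, self._g[a][b]["weight"]))
        internal.sort()
        return EgoNetwork(ego=v, members=frozenset(members), internal_edges=tuple(internal))

    def to_networkx(self) -> nx.Graph:
        """A detached networkx copy (weights in the ``weight`` edge attribute)."""
        return self._g.copy()

    # -- comparison --------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges() == other.edges()

    def __hash__(self) -> None:  # mutable container
        raise TypeError("WeightedGraph is unhashable")

    def __repr__(self) -> str:
        return (
            f"<WeightedGraph n={self.n_nodes} m={self.n_edges} "
            f"isolated={len(self.isolated_nodes())}>"
        )


def build_graph(
    node_ids: Iterable[int],
    weighted_edges: Iterable[tuple[int, int, float]] = (),
) -> WeightedGraph:
    """Functional alias for :meth:`WeightedGraph.from_edges`."""
    return WeightedGraph.from_edges(node_ids, weighted_edges)


_FIXTURE_RE = re.compile(r"^(empty|complete)_(n|\d+)$")


def make_fixture(name: str, n: int | None = None) -> WeightedGraph:
    """Deterministic unit-weight toy graphs used throughout tests and examples.

    Known labels: ``triangle``, ``path3``, ``star5``, ``matching4``,
    ``empty_n`` and ``complete_n`` (the latter two take the node count either
    embedded in the label, e.g. ``empty_4``, or via the ``n`` argument).
    """
    unit = lambda pairs: [(a, b, 1.0) for a, b in pairs]  # noqa: E731
    if name == "triangle":
        return build_graph([1, 2, 3], unit([(1, 2), (2, 3), (1, 3)]))
    if name == "path3":
        return build_graph([1, 2, 3], unit([(1, 2), (2, 3)]))
    if name == "star5":
        return build_graph(range(1, 7), unit([(1, k) for k in range(2, 7)]))
    if name == "matching4":
        return build_graph([1, 2, 3, 4], unit([(1, 2), (3, 4)]))
    m = _FIXTURE_RE.match(name)
    if m:
        kind, size = m.groups()
        if size != "n":
            n = int(size)
        if n is None or n < 1:
            raise UnknownFixtureError(f"fixture {name!r} needs a node count n >= 1")
        if kind == "empty":
            return build_graph(range(1, n + 1))
        pairs = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]
        return build_graph(range(1, n + 1), unit(pairs))
    raise UnknownFixtureError(f"unknown fixture {name!r}")
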