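"""Attack primitives, greedy maximal-damage targeting, and campaigns.

Five attack strategies are implemented, mirroring the pharmaceutical
interpretation of drugs acting on a protein interaction network:

* ``complete_knockout``    — delete every edge of one node (high-affinity,
  high-specificity drug); the node stays in the graph, isolated.
* ``partial_knockout``     — delete a uniformly random half (rounded down)
  of one node's edges; a node partially attacked once is never re-attacked.
* ``partial_attenuation``  — halve the weight of every edge of one node
  (low-affinity drug); the no-reattack rule is applied here too, else a
  greedy campaign would keep halving the same hub.
* ``distributed_knockout`` — delete one uniformly random edge.
* ``distributed_attenuation`` — halve one uniformly random edge, sampled
  without replacement across a campaign.

Node-targeted strategies pick their target by greedy successive maximal
damage: every candidate's attack is simulated on a copy and the one
maximising the configured damage metric is committed, ties broken by the
smallest node id. The greedy total over several attacks is only an estimate
of the true maximal damage; exhaustive multi-target search is combinatorially
infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .errors import ConfigError, NoEligibleTargetError
from .graph import WeightedGraph
from .metrics import (
    METRIC_NAMES,
    avg_ego_edges,
    count_isolated,
    network_efficiency,
)

__all__ = [
    "COMPLETE_KNOCKOUT",
    "PARTIAL_KNOCKOUT",
    "PARTIAL_ATTENUATION",
    "DISTRIBUTED_KNOCKOUT",
    "DISTRIBUTED_ATTENUATION",
    "NODE_STRATEGIES",
    "DISTRIBUTED_STRATEGIES",
    "STRATEGIES",
    "CampaignConfig",
    "Trajectory",
    "attack_complete",
    "attack_partial_knockout",
    "attack_attenuate",
    "attack_distributed",
    "greedy_select",
    "run_campaign",
    "damage_trajectory",
    "average_trajectories",
    "equivalence_point",
]

COMPLETE_KNOCKOUT = "complete_knockout"
PARTIAL_KNOCKOUT = "partial_knockout"
PARTIAL_ATTENUATION = "partial_attenuation"
DISTRIBUTED_KNOCKOUT = "distributed_knockout"
DISTRIBUTED_ATTENUATION = "distributed_attenuation"

NODE_STRATEGIES = (COMPLETE_KNOCKOUT, PARTIAL_KNOCKOUT, PARTIAL_ATTENUATION)
DISTRIBUTED_STRATEGIES = (DISTRIBUTED_KNOCKOUT, DISTRIBUTED_ATTENUATION)
STRATEGIES = NODE_STRATEGIES + DISTRIBUTED_STRATEGIES

_METRIC_FN = {
    "ne": network_efficiency,
    "avg_ego_edges": avg_ego_edges,
    "n_isolated": count_isolated,
}


def _metric_value(G: WeightedGraph, metric: str) -> float:
    try:
        return float(_METRIC_FN[metric](G))
    except KeyError:
        raise ConfigError(f"unknown metric {metric!r}; expected one of {METRIC_NAMES}")


def _signed_damage(metric: str, before: float, after: float) -> float:
    return after - before if metric == "n_isolated" else before - after


# ---------------------------------------------------------------------------
# primitives (mutate the given graph in place and return it)


def attack_complete(G: WeightedGraph, v: int) -> WeightedGraph:
    """Type A: eliminate all interactions of node ``v``; ``v`` stays, isolated."""
    for u in G.neighbors(v):
        G.remove_edge(v, u)
    return G


def attack_partial_knockout(G: WeightedGraph, v: int, rng: np.random.Generator) -> WeightedGraph:
    """Type B1: remove floor(degree/2) uniformly chosen edges of node ``v``."""
    nbrs = G.neighbors(v)
    k = len(nbrs) // 2
    if k:
        chosen = rng.choice(len(nbrs), size=k, replace=False)
        for i in sorted(int(c) for c in chosen):
            G.remove_edge(v, nbrs[i])
    return G


def attack_attenuate(G: WeightedGraph, v: int) -> WeightedGraph:
    """Type B2: halve the weight of every edge of node ``v``; edge set unchanged."""
    for u in G.neighbors(v):
        G.set_weight(v, u, G.weight(v, u) * 0.5)
    return G


def attack_distributed(
    G: WeightedGraph,
    mode: str,
    rng: np.random.Generator,
    excluded_edges: frozenset[tuple[int, int]] = frozenset(),
) -> tuple[int, int]:
    """Type C: delete (``knockout``) or halve (``attenuation``) one random edge.

    The edge is chosen uniformly among present edges not in
    ``excluded_edges``; the chosen pair is returned so attenuation campaigns
    can sample without replacement.
    """
    if mode not in ("knockout", "attenuation"):
        raise ConfigError(f"distributed mode must be knockout/attenuation, got {mode!r}")
    eligible = [(a, b) for a, b, _ in G.edges() if (a, b) not in excluded_edges]
    if not eligible:
        raise NoEligibleTargetError("no eligible edge remains for a distributed attack")
    a, b = eligible[int(rng.integers(len(eligible)))]
    if mode == "knockout":
        G.remove_edge(a, b)
    else:
        G.set_weight(a, b, G.weight(a, b) * 0.5)
    return (a, b)


# ---------------------------------------------------------------------------
# greedy targeting


def _b1_rng(seed: int, step, v: int) -> np.random.Generator:
    # one committed draw per candidate: the half evaluated is the half applied
    return substream(seed, "b1-half", step, v)


def _apply_node_attack(G: WeightedGraph, v: int, strategy: str, seed: int, step) -> None:
    if strategy == COMPLETE_KNOCKOUT:
        attack_complete(G, v)
    elif strategy == PARTIAL_KNOCKOUT:
        attack_partial_knockout(G, v, _b1_rng(seed, step, v))
    elif strategy == PARTIAL_ATTENUATION:
        attack_attenuate(G, v)
    else:  # pragma: no cover - guarded by callers
        raise ConfigError(f"{strategy!r} is not a node-targeted strategy")


def greedy_select(
    G: WeightedGraph,
    strategy: str,
    metric: str = "ne",
    excluded_nodes: frozenset[int] | set[int] = frozenset(),
    seed: int = 0,
    step=0,
) -> int:
    """Pick the non-excluded node whose single attack maximises damage.

    Damage is evaluated by simulating the attack on a copy and measured
    against the *current* graph state; ties are broken by the smallest node
    id. For ``partial_knockout`` each candidate's random half is drawn from
    a substream keyed by (seed, step, node id), and the identical draw is
    replayed when the winning attack is applied.
    """
    if strategy not in NODE_STRATEGIES:
        raise ConfigError(f"greedy selection needs a node-targeted strategy, got {strategy!r}")
    candidates = [v for v in G.nodes if v not in excluded_nodes]
    if not candidates:
        raise NoEligibleTargetError("all nodes are excluded from attack")
    before = _metric_value(G, metric)
    best_v, best_d = None, -np.inf
    for v in candidates:  # ascending id: strict > keeps the smallest id on ties
        if G.degree(v) == 0:
            d = 0.0
        else:
            H = G.copy()
            _apply_node_attack(H, v, strategy, seed, step)
            d = _signed_damage(metric, before, _metric_value(H, metric))
        if d > best_d:
            best_v, best_d = v, d
    return best_v


# ---------------------------------------------------------------------------
# campaigns


@dataclass(frozen=True)
class CampaignConfig:
    """Description of a multi-attack campaign.

    ``nodes_per_attack`` (k) applies to partial strategies: k nodes are
    chosen sequentially within one attack, each maximising marginal damage
    given the within-step state. Distributed strategies and complete
    knockout use k = 1. ``bernoulli_edge_prob`` switches distributed attacks
    from the default one-edge-per-attack granularity to system-wide Bernoulli
    thinning where every eligible edge is independently hit with the given
    probability per attack (an extension; see the methods note).
    """

    strategy: str
    n_attacks: int = 25
    nodes_per_attack: int = 1
    metric: str = "ne"
    seed: int = 0
    allow_reattack: bool = field(default=False, kw_only=True)
    bernoulli_edge_prob: float | None = field(default=None, kw_only=True)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if self.n_attacks < 0:
            raise ConfigError("n_attacks must be >= 0")
        if self.nodes_per_attack < 1:
            raise ConfigError("nodes_per_attack must be >= 1")
        if self.metric not in METRIC_NAMES:
            raise ConfigError(f"unknown metric {self.metric!r}")
        if self.nodes_per_attack != 1 and self.strategy not in (
            PARTIAL_KNOCKOUT,
            PARTIAL_ATTENUATION,
        ):
            raise ConfigError("nodes_per_attack > 1 is only valid for partial strategies")
        if self.bernoulli_edge_prob is not None:
            if self.strategy not in DISTRIBUTED_STRATEGIES:
                raise ConfigError("bernoulli_edge_prob applies to distributed strategies only")
            if not 0.0 < self.bernoulli_edge_prob <= 1.0:
                raise ConfigError("bernoulli_edge_prob must lie in (0, 1]")


@dataclass(frozen=True)
class Trajectory:
    """Per-attack metric values (index 0 = pre-attack) and attacked targets."""

    values: tuple[float, ...]
    targets: tuple[tuple, ...]
    strategy: str
    metric: str
    stopped_at: int | None = None  # attack index after which no target remained

    def __len__(self) -> int:
        return len(self.values)


def run_campaign(G: WeightedGraph, config: CampaignConfig) -> Trajectory:
    """Run a full attack campaign on a copy of ``G`` and record the metric.

    Node-targeted strategies select targets greedily; partially attacked
    nodes join the exclusion set unless ``allow_reattack``. Distributed
    knockout samples uniformly among present edges; distributed attenuation
    samples without replacement across the campaign. If no eligible target
    remains the campaign stops early and the trajectory is padded with the
    last value.
    """
    work = G.copy()
    values = [_metric_value(work, config.metric)]
    targets: list[tuple] = []
    excluded_nodes: set[int] = set()
    attenuated: set[tuple[int, int]] = set()
    rng_dist = substream(config.seed, "distributed-edges")
    stopped: int | None = None

    for attack in range(config.n_attacks):
        if stopped is not None:
            values.append(values[-1])
            targets.append(())
            continue
        if config.strategy in NODE_STRATEGIES:
            hit: list[int] = []
            for j in range(config.nodes_per_attack):
                step = (attack, j)
                try:
                    v = greedy_select(
                        work, config.strategy, config.metric,
                        excluded_nodes, config.seed, step,
                    )
                except NoEligibleTargetError:
                    stopped = attack
                    break
                _apply_node_attack(work, v, config.strategy, config.seed, step)
                if config.strategy != COMPLETE_KNOCKOUT and not config.allow_reattack:
                    excluded_nodes.add(v)
                hit.append(v)
            targets.append(tuple(hit))
        else:
            mode = "knockout" if config.strategy == DISTRIBUTED_KNOCKOUT else "attenuation"
            try:
                if config.bernoulli_edge_prob is not None:
                    hit_edges = _bernoulli_distributed(
                        work, mode, rng_dist, config.bernoulli_edge_prob, attenuated
                    )
                    targets.append(tuple(hit_edges))
                else:
                    excl = frozenset(attenuated) if mode == "attenuation" else frozenset()
                    edge = attack_distributed(work, mode, rng_dist, excl)
                    if mode == "attenuation":
                        attenuated.add(edge)
                    targets.append((edge,))
            except NoEligibleTargetError:
                stopped = attack
                targets.append(())
        values.append(_metric_value(work, config.metric))

    return Trajectory(
        values=tuple(values),
        targets=tuple(targets),
        strategy=config.strategy,
        metric=config.metric,
        stopped_at=stopped,
    )


def _bernoulli_distributed(
    G: WeightedGraph,
    mode: str,
    rng: np.random.Generator,
    prob: float,
    attenuated: set[tuple[int, int]],
) -> list[tuple[int, int]]:
    """System-wide thinning: each eligible edge is hit independently."""
    if mode == "attenuation":
        eligible = [(a, b) for a, b, _ in G.edges() if (a, b) not in attenuated]
    else:
        eligible = [(a, b) for a, b, _ in G.edges()]
    if not eligible:
        raise NoEligibleTargetError("no eligible edge remains for a distributed attack")
    mask = rng.random(len(eligible)) < prob
    hit = [e for e, m in zip(eligible, mask) if m]
    for a, b in hit:
        if mode == "knockout":
            G.remove_edge(a, b)
        else:
            G.set_weight(a, b, G.weight(a, b) * 0.5)
            attenuated.add((a, b))
    return hit


# ---------------------------------------------------------------------------
# trajectory arithmetic


def damage_trajectory(traj: Trajectory) -> np.ndarray:
    """Cumulative signed damage relative to the pre-attack state."""
    vals = np.asarray(traj.values, dtype=float)
    if traj.metric == "n_isolated":
        return vals - vals[0]
    return vals[0] - vals


def average_trajectories(damages: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of damage curves, padding shorter ones with their last value."""
    if not damages:
        raise ConfigError("no trajectories to average")
    length = max(len(d) for d in damages)
    padded = [
        np.concatenate([d, np.full(length - len(d), d[-1])]) if len(d) < length else np.asarray(d)
        for d in damages
    ]
    return np.mean(padded, axis=0)


def equivalence_point(damages: np.ndarray, threshold: float) -> int | None:
    """Smallest attack index whose cumulative damage first reaches ``threshold``.

    Returns None if the curve never reaches it ("not reached").
    """
    hits = np.nonzero(np.asarray(damages, dtype=float) >= threshold)[0]
    return int(hits[0]) if hits.size else None
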