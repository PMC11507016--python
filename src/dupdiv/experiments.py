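"""Reproducible experiment harness.

Ties model generation, attack campaigns and the damage metrics into seeded,
logged runs: per-repeat trajectories, averaged trajectories, and for
distributed strategies the equivalence point against one greedy complete
knockout. Configurations come either from :class:`RunConfig` built in code
or from a YAML file (see :func:`load_run_config`).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import metadata as _im
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import derive_seed
from .attacks import (
    COMPLETE_KNOCKOUT,
    DISTRIBUTED_STRATEGIES,
    CampaignConfig,
    Trajectory,
    attack_complete,
    average_trajectories,
    damage_trajectory,
    equivalence_point,
    greedy_select,
    run_campaign,
)
from .attacks import _metric_value, _signed_damage  # shared metric plumbing
from .errors import ConfigError
from .graph import WeightedGraph
from .io import read_string_edges, write_graph_tsv, write_trajectories_tsv
from .models import DDParams, GnmParams, NodeLossParams, dd_generate, dd_nodeloss_generate, sample_gnm

__all__ = [
    "RunConfig",
    "load_run_config",
    "run_experiment",
    "knockout_reference_damage",
    "EquivalenceResult",
    "distributed_equivalence",
    "loss_rate_sweep",
]

logger = logging.getLogger(__name__)

_MODELS = {"gnm", "dd", "dd_nodeloss"}


@dataclass(frozen=True)
class RunConfig:
    """One experiment: a graph source, an attack campaign, and repeats.

    Exactly one of ``model`` (name/params/seed) or ``input`` (edge-list
    path, optional universe path, threshold, score scale) must be present.
    """

    campaign: CampaignConfig
    repeats: int = 1
    model: dict | None = None
    input: dict | None = None
    outdir: str | None = None
    seed: int = field(default=0, kw_only=True)

    def __post_init__(self) -> None:
        if (self.model is None) == (self.input is None):
            raise ConfigError("exactly one of model/input must be configured")
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")
        if self.model is not None:
            name = self.model.get("name")
            if name not in _MODELS:
                raise ConfigError(f"unknown model {name!r}; expected one of {sorted(_MODELS)}")


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        campaign = CampaignConfig(**raw.pop("campaign"))
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: invalid campaign block: {exc}") from None
    try:
        return RunConfig(campaign=campaign, **raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def _build_graph(config: RunConfig, repeat: int) -> WeightedGraph:
    if config.input is not None:
        return read_string_edges(
            config.input["edges"],
            threshold=config.input["threshold"],
            score_scale=config.input["score_scale"],
            node_universe_path=config.input.get("universe"),
        )
    name = config.model["name"]
    params = dict(config.model.get("params", {}))
    model_seed = int(config.model.get("seed", config.seed))
    seed = derive_seed(model_seed, "model-repeat", repeat)
    if name == "gnm":
        return sample_gnm(GnmParams(**params), seed)
    if name == "dd":
        return dd_generate(DDParams(**params), seed)
    return dd_nodeloss_generate(NodeLossParams(**params), seed)


def knockout_reference_damage(G: WeightedGraph, metric: str, seed: int = 0) -> float:
    """Damage of one greedy complete knockout on ``G`` in the given metric."""
    v = greedy_select(G, COMPLETE_KNOCKOUT, metric, seed=seed)
    before = _metric_value(G, metric)
    H = G.copy()
    attack_complete(H, v)
    return _signed_damage(metric, before, _metric_value(H, metric))


def format_targets(targets: tuple) -> str:
    """Compact text form of one attack's targets: node ids or a-b edge pairs."""
    return "|".join(
        "-".join(map(str, t)) if isinstance(t, tuple) else str(t) for t in targets
    )


def _tidy_frame(trajs: list[Trajectory], config: RunConfig) -> pd.DataFrame:
    rows = []
    for r, traj in enumerate(trajs):
        for i, value in enumerate(traj.values):
            target = "" if i == 0 else format_targets(
                traj.targets[i - 1] if i - 1 < len(traj.targets) else ()
            )
            rows.append(
                {
                    "repeat": r,
                    "attack_index": i,
                    "strategy": traj.strategy,
                    "k": config.campaign.nodes_per_attack,
                    "metric_name": traj.metric,
                    "value": value,
                    "target": target,
                }
            )
    return pd.DataFrame(rows)


def run_experiment(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run all repeats of a configured campaign and write result files.

    Writes per-attack trajectory rows (``trajectories.tsv``), the averaged
    trajectory (``averaged.tsv``), run metadata with enough seeds to re-run
    any row (``metadata.json``), the generated graph of each repeat, and —
    for distributed strategies — the equivalence point against one greedy
    complete knockout computed on the same graphs (``equivalence.json``).
    Returns the metadata record.
    """
    outdir = Path(outdir or config.outdir or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    trajs: list[Trajectory] = []
    knockout_damages: list[float] = []
    for r in range(config.repeats):
        G = _build_graph(config, r)
        write_graph_tsv(G, outdir / f"graph_rep{r}.tsv", outdir / f"graph_rep{r}.nodes")
        cfg = CampaignConfig(
            **{
                **asdict(config.campaign),
                "seed": derive_seed(config.campaign.seed, "campaign-repeat", r),
            }
        )
        try:
            trajs.append(run_campaign(G, cfg))
        except Exception:
            logger.error("repeat %d failed", r)
            raise
        if config.campaign.strategy in DISTRIBUTED_STRATEGIES:
            knockout_damages.append(
                knockout_reference_damage(
                    G, config.campaign.metric, derive_seed(config.seed, "knockout-ref", r)
                )
            )

    frame = _tidy_frame(trajs, config)
    write_trajectories_tsv(frame, outdir / "trajectories.tsv")
    avg = average_trajectories([np.asarray(t.values, dtype=float) for t in trajs])
    pd.DataFrame({"attack_index": np.arange(len(avg)), "mean_value": avg}).to_csv(
        outdir / "averaged.tsv", sep="\t", index=False
    )

    meta = {
        "config": _config_dict(config),
        "config_hash": _config_hash(config),
        "package_version": _version(),
        "repeat_model_seeds": [
            derive_seed(int((config.model or {}).get("seed", config.seed)), "model-repeat", r)
            for r in range(config.repeats)
        ]
        if config.model
        else [],
        "repeat_campaign_seeds": [
            derive_seed(config.campaign.seed, "campaign-repeat", r) for r in range(config.repeats)
        ],
    }
    if knockout_damages:
        damages = average_trajectories([damage_trajectory(t) for t in trajs])
        threshold = float(np.mean(knockout_damages))
        eq = equivalence_point(damages, threshold)
        record = {
            "one_knockout_damage": threshold,
            "per_repeat_knockout_damage": knockout_damages,
            "equivalence_point": eq,
        }
        (outdir / "equivalence.json").write_text(json.dumps(record, indent=2))
        meta["equivalence"] = record
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
    return meta


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(json.dumps(_config_dict(config), sort_keys=True).encode()).hexdigest()[:16]


def _version() -> str:
    try:
        return _im.version("dupdiv")
    except _im.PackageNotFoundError:  # pragma: no cover
        return "unknown"


# ---------------------------------------------------------------------------
# the distributed-vs-complete equivalence experiment


@dataclass(frozen=True)
class EquivalenceResult:
    """Averaged distributed-damage curve and its crossing of one knockout's damage."""

    crossing: int | None
    knockout_damage: float
    per_repeat_knockout: tuple[float, ...]
    mean_damage: np.ndarray
    repeats: int


def distributed_equivalence(
    strategy: str,
    params: DDParams,
    repeats: int = 5,
    seed: int = 0,
    metric: str = "ne",
    n_attacks: int | None = None,
) -> EquivalenceResult:
    """How many single-edge distributed attacks match one complete knockout.

    Grows ``repeats`` independent duplication-divergence networks, measures
    the damage of one greedy complete knockout on each, runs the distributed
    campaign on the same (pre-knockout) graphs, averages both over repeats,
    and returns the smallest attack count whose averaged cumulative damage
    reaches the averaged one-knockout damage. By default the campaign may
    run through every edge of each network, so the crossing is found
    wherever it lies.
    """
    if strategy not in DISTRIBUTED_STRATEGIES:
        raise ConfigError(f"strategy must be distributed, got {strategy!r}")
    damage_curves = []
    knockouts = []
    for r in range(repeats):
        G = dd_generate(params, derive_seed(seed, "net", r))
        knockouts.append(
            knockout_reference_damage(G, metric, derive_seed(seed, "greedy", r))
        )
        na = n_attacks if n_attacks is not None else G.n_edges
        traj = run_campaign(
            G,
            CampaignConfig(
                strategy=strategy,
                n_attacks=na,
                metric=metric,
                seed=derive_seed(seed, "campaign", r),
            ),
        )
        damage_curves.append(damage_trajectory(traj))
    mean_damage = average_trajectories(damage_curves)
    threshold = float(np.mean(knockouts))
    return EquivalenceResult(
        crossing=equivalence_point(mean_damage, threshold),
        knockout_damage=threshold,
        per_repeat_knockout=tuple(knockouts),
        mean_damage=mean_damage,
        repeats=repeats,
    )


def loss_rate_sweep(
    qs: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
    p: float = 0.4,
    steps: int = 1000,
    strategy: str = "distributed_knockout",
    n_attacks: int = 25,
    repeats: int = 10,
    seed: int = 0,
    metric: str = "ne",
) -> pd.DataFrame:
    """Averaged attack trajectories of the node-loss model across loss rates q.

    One averaged metric trajectory per q; returned tidy (q, attack_index,
    mean_value). The monotone effect of q is reported, not asserted — it is
    a stochastic trend.
    """
    rows = []
    for q in qs:
        params = NodeLossParams(p=p, steps=steps, q=q)
        trajs = []
        for r in range(repeats):
            G = dd_nodeloss_generate(params, derive_seed(seed, "sweep-net", q, r))
            trajs.append(
                run_campaign(
                    G,
                    CampaignConfig(
                        strategy=strategy,
                        n_attacks=n_attacks,
                        metric=metric,
                        seed=derive_seed(seed, "sweep-campaign", q, r),
                    ),
                )
            )
        avg = average_trajectories([np.asarray(t.values, dtype=float) for t in trajs])
        rows.extend(
            {"q": q, "attack_index": i, "mean_value": v} for i, v in enumerate(avg)
        )
    return pd.DataFrame(rows)
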