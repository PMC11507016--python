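"""Attack primitives, greedy targeting, campaigns: examples and oracle checks."""

import math

import numpy as np
import pytest

from dupdiv import (
    CampaignConfig,
    attack_attenuate,
    attack_complete,
    attack_distributed,
    attack_partial_knockout,
    average_trajectories,
    build_graph,
    damage_trajectory,
    dd_generate,
    DDParams,
    equivalence_point,
    greedy_select,
    make_fixture,
    network_efficiency,
    run_campaign,
)
from dupdiv.errors import ConfigError, NoEligibleTargetError
from oracles import brute_force_efficiency, random_weighted_graph


def bridge_graph():
    """Two triangles joined only through a bridge node (id 4, two anchors
    on each side, so its knockout — and only its knockout — disconnects them)."""
    return build_graph(
        range(1, 9),
        [(1, 2, 1.0), (2, 3, 1.0), (1, 3, 1.0),
         (6, 7, 1.0), (7, 8, 1.0), (6, 8, 1.0),
         (2, 4, 1.0), (3, 4, 1.0), (4, 6, 1.0), (4, 7, 1.0)],
    )


class TestPrimitives:
    def test_complete_knockout_star(self, star5):
        attack_complete(star5, 1)
        assert star5.n_edges == 0
        assert len(star5.isolated_nodes()) == 6

    def test_complete_knockout_k3_ne(self, triangle):
        attack_complete(triangle, 1)
        assert network_efficiency(triangle) == pytest.approx(2.0)

    def test_knockout_of_isolated_node_is_noop(self):
        g = build_graph([1, 2, 3], [(1, 2, 1.0)])
        attack_complete(g, 3)
        assert g.n_edges == 1

    @pytest.mark.parametrize("degree, removed", [(1, 0), (2, 1), (4, 2), (5, 2)])
    def test_partial_knockout_removes_floor_half(self, degree, removed, rng):
        g = build_graph(range(0, degree + 1), [(0, k, 1.0) for k in range(1, degree + 1)])
        attack_partial_knockout(g, 0, rng)
        assert g.degree(0) == degree - removed

    def test_attenuation_halves_weights_keeps_edges(self, triangle):
        attack_attenuate(triangle, 1)
        assert triangle.weight(1, 2) == 0.5 and triangle.weight(1, 3) == 0.5
        assert triangle.weight(2, 3) == 1.0
        assert network_efficiency(triangle) == pytest.approx(4.0)  # 2*1 + 4*(1/2)

    def test_double_attenuation_quarters_shared_edge(self, triangle):
        attack_attenuate(triangle, 1)
        attack_attenuate(triangle, 2)
        assert triangle.weight(1, 2) == 0.25

    def test_distributed_knockout_and_attenuation(self, rng):
        g = build_graph([1, 2], [(1, 2, 1.0)])
        edge = attack_distributed(g, "attenuation", rng)
        assert edge == (1, 2) and g.weight(1, 2) == 0.5
        g2 = make_fixture("triangle")
        attack_distributed(g2, "knockout", rng)
        assert g2.n_edges == 2

    def test_distributed_on_empty_graph_raises(self, rng):
        with pytest.raises(NoEligibleTargetError):
            attack_distributed(make_fixture("empty_n", n=3), "knockout", rng)

    def test_distributed_choice_is_uniform(self):
        counts = {}
        for seed in range(1500):
            g = make_fixture("triangle")
            e = attack_distributed(g, "knockout", np.random.default_rng(seed))
            counts[e] = counts.get(e, 0) + 1
        from scipy import stats

        assert len(counts) == 3
        assert stats.chisquare(list(counts.values())).pvalue > 0.001


class TestGreedySelect:
    def test_star_center_maximises_ne_damage(self, star5):
        assert greedy_select(star5, "complete_knockout", "ne") == 1

    def test_symmetric_tie_broken_by_smallest_id(self, triangle):
        assert greedy_select(triangle, "complete_knockout", "ne") == 1

    def test_bridge_node_is_the_best_target(self):
        assert greedy_select(bridge_graph(), "complete_knockout", "ne") == 4

    @pytest.mark.parametrize("strategy", ["complete_knockout", "partial_attenuation"])
    def test_first_step_matches_exhaustive_optimum(self, strategy, rng):
        """Greedy's first choice achieves the exhaustive single-target maximum,
        verified against an independent brute-force efficiency oracle."""
        for _ in range(25):
            nodes, edges = random_weighted_graph(rng, max_nodes=6, unit_weights=True)
            g = build_graph(nodes, edges)
            base = brute_force_efficiency(nodes, edges)
            best = -math.inf
            for v in nodes:
                h = g.copy()
                (attack_complete if strategy == "complete_knockout" else attack_attenuate)(h, v)
                best = max(best, base - brute_force_efficiency(h.nodes, h.edges()))
            chosen = greedy_select(g, strategy, "ne")
            h = g.copy()
            (attack_complete if strategy == "complete_knockout" else attack_attenuate)(h, chosen)
            achieved = base - brute_force_efficiency(h.nodes, h.edges())
            assert achieved == pytest.approx(best, rel=1e-9, abs=1e-9)

    def test_two_step_greedy_never_beats_exhaustive_pair(self, rng):
        """Greedy damage is only an estimate of the maximum: over two knockouts
        it cannot exceed the best unordered pair's damage."""
        for _ in range(12):
            nodes, edges = random_weighted_graph(rng, max_nodes=6, unit_weights=True)
            if len(nodes) < 3:
                continue
            g = build_graph(nodes, edges)
            base = network_efficiency(g)
            traj = run_campaign(
                g, CampaignConfig(strategy="complete_knockout", n_attacks=2, metric="ne")
            )
            greedy_damage = traj.values[0] - traj.values[2]
            best_pair = -math.inf
            for i, u in enumerate(nodes):
                for v in nodes[i + 1:]:
                    h = g.copy()
                    attack_complete(h, u)
                    attack_complete(h, v)
                    best_pair = max(best_pair, base - network_efficiency(h))
            assert greedy_damage <= best_pair + 1e-9

    def test_all_excluded_raises(self, triangle):
        with pytest.raises(NoEligibleTargetError):
            greedy_select(triangle, "partial_attenuation", "ne", excluded_nodes={1, 2, 3})


class TestCampaigns:
    def test_k3_complete_knockout_trajectory(self, triangle):
        traj = run_campaign(
            triangle, CampaignConfig(strategy="complete_knockout", n_attacks=3, metric="ne")
        )
        assert traj.values == (6.0, 2.0, 0.0, 0.0)

    def test_zero_attacks(self, triangle):
        traj = run_campaign(
            triangle, CampaignConfig(strategy="complete_knockout", n_attacks=0, metric="ne")
        )
        assert traj.values == (6.0,)

    def test_knockout_raises_isolated_count(self):
        g = build_graph(range(1, 6), [(1, 2, 1.0), (2, 3, 1.0), (1, 3, 1.0)])
        traj = run_campaign(
            g, CampaignConfig(strategy="complete_knockout", n_attacks=1, metric="n_isolated")
        )
        assert traj.values == (2.0, 3.0)

    def test_input_graph_is_untouched(self, triangle):
        run_campaign(triangle, CampaignConfig(strategy="complete_knockout", n_attacks=2))
        assert triangle.n_edges == 3

    def test_knockout_trajectories_non_increasing(self, rng):
        for _ in range(5):
            g = dd_generate(DDParams(p=0.5, steps=25), seed=int(rng.integers(1000)))
            for strategy in ("complete_knockout", "partial_knockout", "distributed_knockout"):
                traj = run_campaign(
                    g, CampaignConfig(strategy=strategy, n_attacks=6, metric="ne", seed=1)
                )
                assert all(a >= b - 1e-9 for a, b in zip(traj.values, traj.values[1:]))

    def test_attenuation_campaign_keeps_edges_and_dyadic_weights(self):
        g = dd_generate(DDParams(p=0.7, steps=15), seed=4)
        m0 = g.n_edges
        traj = run_campaign(
            g, CampaignConfig(strategy="partial_attenuation", n_attacks=5, metric="ne", seed=2)
        )
        assert traj.values[0] >= traj.values[-1]
        # campaign runs on a copy; rerun manually to inspect weights
        h = g.copy()
        for ts in traj.targets:
            for v in ts:
                attack_attenuate(h, v)
        assert h.n_edges == m0
        for _, _, w in h.edges():
            k = math.log2(1.0 / w)
            assert k == pytest.approx(round(k), abs=1e-12) and k >= 0

    def test_partial_strategies_never_reattack_by_default(self):
        g = make_fixture("star5")
        traj = run_campaign(
            g, CampaignConfig(strategy="partial_attenuation", n_attacks=6, metric="ne")
        )
        hit = [v for ts in traj.targets for v in ts]
        assert len(hit) == len(set(hit)) == 6

    def test_multi_node_attacks_select_k_per_step(self):
        g = dd_generate(DDParams(p=0.6, steps=20), seed=9)
        traj = run_campaign(
            g,
            CampaignConfig(
                strategy="partial_knockout", n_attacks=3, nodes_per_attack=2, metric="ne", seed=3
            ),
        )
        assert all(len(ts) == 2 for ts in traj.targets)

    def test_distributed_attenuation_without_replacement(self):
        g = make_fixture("complete_5")
        traj = run_campaign(
            g,
            CampaignConfig(strategy="distributed_attenuation", n_attacks=10, metric="ne", seed=6),
        )
        edges = [ts[0] for ts in traj.targets if ts]
        assert len(edges) == len(set(edges)) == 10

    def test_early_stop_pads_with_last_value(self):
        g = make_fixture("matching4")
        traj = run_campaign(
            g, CampaignConfig(strategy="distributed_knockout", n_attacks=5, metric="ne", seed=0)
        )
        assert len(traj.values) == 6
        assert traj.stopped_at == 2
        assert traj.values[2] == traj.values[3] == traj.values[4] == traj.values[5] == 0.0

    def test_reproducible(self):
        g = dd_generate(DDParams(p=0.5, steps=30), seed=21)
        cfg = CampaignConfig(strategy="partial_knockout", n_attacks=5, metric="ne", seed=13)
        assert run_campaign(g, cfg) == run_campaign(g, cfg)

    def test_bernoulli_extension_hits_every_edge_at_prob_one(self):
        g = make_fixture("complete_5")
        traj = run_campaign(
            g,
            CampaignConfig(
                strategy="distributed_knockout", n_attacks=1, metric="ne",
                bernoulli_edge_prob=1.0,
            ),
        )
        assert traj.values[-1] == 0.0 and len(traj.targets[0]) == 10

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(strategy="complete_knockout", nodes_per_attack=2),
            dict(strategy="distributed_knockout", nodes_per_attack=3),
            dict(strategy="complete_knockout", metric="degree"),
            dict(strategy="nuke"),
            dict(strategy="complete_knockout", bernoulli_edge_prob=0.5),
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ConfigError):
            CampaignConfig(**kwargs)


class TestTrajectoryArithmetic:
    def test_equivalence_point_examples(self):
        assert equivalence_point(np.array([0.0, 1.0, 2.0, 3.0]), 2.5) == 3
        assert equivalence_point(np.array([0.0, 1.0, 2.0, 3.0]), 0.0) == 0
        assert equivalence_point(np.array([0.0, 1.0, 2.0, 3.0]), 9.0) is None

    def test_damage_trajectory_signs(self, triangle):
        tk = run_campaign(
            triangle, CampaignConfig(strategy="complete_knockout", n_attacks=1, metric="ne")
        )
        assert damage_trajectory(tk).tolist() == [0.0, 4.0]
        ti = run_campaign(
            triangle,
            CampaignConfig(strategy="complete_knockout", n_attacks=1, metric="n_isolated"),
        )
        assert damage_trajectory(ti).tolist() == [0.0, 1.0]

    def test_average_pads_shorter_curves(self):
        avg = average_trajectories([np.array([0.0, 2.0]), np.array([0.0, 1.0, 3.0])])
        assert avg.tolist() == [0.0, 1.5, 2.5]
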