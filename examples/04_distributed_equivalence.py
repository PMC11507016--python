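"""How many distributed attacks equal one complete knockout?

Grows duplication-divergence networks (scaled to 300 steps so the script
runs in seconds), measures the network-efficiency damage of one greedy
complete knockout, and finds the attack count at which the averaged
distributed campaigns first match it. With one random edge hit per attack
the crossing sits far beyond the attack counts a small campaign explores,
because a greedy knockout removes a whole hub; the Bernoulli variant,
where each attack hits every edge with a small probability, shows how
multi-edge distributed attacks close that gap much sooner.
"""

import numpy as np

from dupdiv import (
    CampaignConfig,
    DDParams,
    damage_trajectory,
    dd_generate,
    distributed_equivalence,
    equivalence_point,
    knockout_reference_damage,
    run_campaign,
)

params = DDParams(p=0.4, steps=300)

for strategy in ("distributed_knockout", "distributed_attenuation"):
    res = distributed_equivalence(strategy, params, repeats=5, seed=11)
    print(f"{strategy}: one greedy knockout destroys NE {res.knockout_damage:.1f};")
    print(f"  single-edge attacks need {res.crossing} hits to match it "
          f"(averaged over {res.repeats} networks)")

# Bernoulli variant: every attack hits each remaining edge with prob 0.05
print("\nBernoulli distributed knockout (each attack hits each edge w.p. 0.05):")
crossings = []
for r in range(5):
    G = dd_generate(params, seed=100 + r)
    thr = knockout_reference_damage(G, "ne")
    traj = run_campaign(
        G,
        CampaignConfig(
            strategy="distributed_knockout", n_attacks=40, metric="ne",
            seed=r, bernoulli_edge_prob=0.05,
        ),
    )
    crossings.append(equivalence_point(damage_trajectory(traj), thr))
print(f"  per-network crossings: {crossings} "
      f"(mean {np.mean([c for c in crossings if c is not None]):.1f} attacks)")
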