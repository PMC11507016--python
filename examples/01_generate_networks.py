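"""Grow networks under the three generative models and compare their shape.

The G(n, M) baseline spreads edges uniformly, the standard
duplication-divergence (DD) model grows hubs but drifts towards a graph
that is almost all isolated nodes, and the node-loss model prunes isolated
proteins (gene loss) so their proportion stays strictly between 0 and 1.
"""

from dupdiv import (
    DDParams,
    GnmParams,
    NodeLossParams,
    damage_metrics,
    dd_generate,
    dd_nodeloss_generate,
    sample_gnm,
)

SEED = 1

for label, graph in [
    ("G(n=500, M=600)", sample_gnm(GnmParams(n=500, M=600), SEED)),
    ("DD(t0=3, p=0.4), 500 steps", dd_generate(DDParams(p=0.4, steps=500), SEED)),
    (
        "DD + node loss (p=0.4, q=0.2), 500 steps",
        dd_nodeloss_generate(NodeLossParams(p=0.4, steps=500, q=0.2), SEED),
    ),
]:
    m = damage_metrics(graph)
    frac = m.n_isolated / graph.n_nodes
    print(f"{label}:")
    print(f"  nodes={graph.n_nodes}  edges={graph.n_edges}  "
          f"isolated={m.n_isolated} ({frac:.1%} of nodes)")
    print(f"  network efficiency={m.ne:.1f}  mean ego edges={m.avg_ego_edges:.2f}")

print(
    "\nThe node-loss model ends smaller (lost genes) and denser, with an"
    "\nisolated fraction away from both 0 and 1 - unlike the standard DD"
    "\nmodel, whose isolated fraction keeps climbing towards 1 at p=0.4."
)
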