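# Methods

This note records the models, conventions and design choices behind
`dupdiv`, in enough detail to re-derive every number the package prints.

## Graph substrate

All models and attacks operate on a simple undirected graph with strictly
positive edge weights (dimensionless interaction strengths, initialised to
1 everywhere). Edge existence is *defined* as weight > 0: attenuation
(halving a weight) can therefore never delete an edge or isolate a node,
while knockout removes the edge entry. Node identifiers are integers
assigned in creation order and are retired on deletion, never reused, so a
simulated gene-loss history remains auditable from the final graph (its
`retired_ids`). Isolated nodes are first-class members of the node set —
in PPI data an isolated protein is an observation, not an absence.

## Generative models

**G(n, M).** Drawn uniformly over all simple graphs with `n` nodes and `M`
edges by sampling `M` distinct pair indices without replacement and
decoding them to node pairs. This guarantees exact uniformity over the
C(N, M) edge sets (N = n(n−1)/2), which the test-suite verifies by a
chi-square test over all 15 two-edge graphs on four nodes.

**DD(t0, p).** Growth starts from the complete graph on `t0` nodes
(default 3: starting from a triangle lets the model carry nonzero
clustering; `t0 = 2` is supported for comparison runs). Each of `steps`
iterations duplicates a uniformly chosen parent: the new node receives a
candidate edge to each parent neighbour, each kept independently with
probability `p`; the parent itself is never a candidate (no parent–child
edge). `steps` counts duplication events, so the final node count is
exactly `t0 + steps`.

**Node loss.** After every duplication-and-divergence step a loss step
runs: an isolated node is removed with probability `q`. Two readings of
"a node can be lost if it is isolated" are implemented, because isolated
nodes can never regain edges under duplication-divergence growth (a copy
only links to its parent's neighbours), and the two readings differ
qualitatively:

* `newest_only` (default) — only the just-added node, if isolated, faces
  the q-trial, in the loss step of its own iteration. An isolated protein
  that survives its birth step persists. Measured at p = 0.4, q = 0.2 and
  1000 steps, the final isolated fraction lies in 0.52–0.89 across 30
  seeds — strictly inside (0, 1), the behaviour that motivates the model.
* `all_isolated` — every currently isolated node is independently tested
  each step. Because isolation is permanent, this purges isolated nodes
  geometrically: the same settings leave a mean isolated fraction of 0.002
  and end with exactly zero isolated nodes in roughly 30% of runs. The
  mode is kept because it has clean steady-state behaviour (with p = 0
  every newborn is isolated and the isolated count balances at 1/q − 1)
  and because the verbal model description admits it.

Raising `q` removes more isolated material and, by concentrating parents
on connected nodes, yields denser, more connected networks; the
`loss_rate_sweep` helper reports this trend over q ∈ {0.2, 0.4, 0.6, 0.8}
without asserting it (it is stochastic).

**Randomness contract.** Every generator draws from independent named
substreams of one master seed (parent choice, edge retention, loss trials,
pair sampling), derived via `SeedSequence` spawn keys from CRC32 stream
names. Toggling `q` therefore cannot perturb the duplication history:
the node-loss model with `q = 0` is bitwise identical to the standard
model under the same seed, which the suite asserts directly, alongside a
KS test on edge-count distributions across disjoint seed ranges.

## Damage metrics

* **Network efficiency** `NE = Σ_{i≠j} 1/d_ij` over *ordered* pairs, with
  `d_ij` the shortest-path length when each edge contributes length
  `1/weight`, and `1/∞ := 0` for disconnected pairs. The 1/weight
  convention is deliberate: reading "path weight" literally would make
  attenuation *shorten* paths and increase efficiency, turning an attack
  into a benefit; with lengths `1/weight`, halving a weight doubles that
  edge's length and attenuation damages NE, consistent with its use as a
  weak attack. No `1/(n(n−1))` normalisation is applied, and the ordered
  sum is twice the unordered one; both constants cancel in every
  comparison the package makes, but absolute NE values elsewhere may
  differ by such factors. Shortest paths run through Dijkstra on the
  positive-degree core (isolated nodes contribute nothing); agreement with
  an exhaustive-relaxation oracle is tested to 1e−12 on hundreds of random
  weighted graphs.
* **Average ego edges** — the mean over *all* nodes (isolated included,
  each contributing 0) of the edge count of the closed 1-step ego network
  (ego, alters, and all edges among them, ego–alter edges included). This
  is the variant that attacks can only decrease.
* **Isolated count** — degree-0 nodes. Knockouts can raise it;
  attenuation never can.

Damage is always signed so that larger = worse: `before − after` for NE
and ego edges, `after − before` for the isolated count, and greedy
selection always measures damage against the *current* graph state.

## Attacks and campaigns

Greedy successive maximal damage simulates every candidate's attack on a
copy and commits the best, ties broken by the smallest node id (which also
makes symmetric cases deterministic). For partial knockout, the removed
half — `floor(degree/2)` uniformly chosen incident edges — is drawn from a
substream keyed by (campaign seed, step, node id) and the identical draw
is replayed when the winner is committed, so evaluated and applied damage
coincide. Greedy multi-node attacks (k = 2, 5) choose k nodes
sequentially within one attack, each maximising marginal damage given the
within-step state; exhaustive k-subset search is rejected as infeasible
(choosing 5 of 1000 edges already means ~8.25×10¹² cases). The
no-reattack rule for partially attacked nodes is applied to both partial
knockout and partial attenuation (otherwise a greedy campaign would halve
the same hub forever); `allow_reattack=True` restores repeat attacks for
sensitivity checks. Two-step greedy damage is verified never to exceed
the exhaustive best pair on small graphs — greedy is an estimate of
maximal damage, not the maximum.

Distributed attacks hit edges, not nodes, and use no greedy search. The
default granularity is **one uniformly random edge per attack**: knockout
deletes it (sampling from currently present edges), attenuation halves it
(sampling without replacement across the campaign, so 13 attacks touch 13
distinct edges). This makes "number of distributed attacks" well defined
as an integer. A flagged alternative, `bernoulli_edge_prob`, makes each
attack a system-wide thinning in which every eligible edge is hit
independently with the given probability — a natural model for an
unspecific low-dose perturbation. The two granularities differ enormously
in strength: a greedy complete knockout removes a hub (often 10–50 edges,
~20% of all NE in a 1000-step DD network), so single-edge distributed
campaigns need on the order of 50–200 attacks to match one knockout,
while Bernoulli attacks at a few percent per edge match it within roughly
5–20 attacks. The equivalence experiment (`distributed_equivalence`)
averages damage trajectories and the one-knockout reference over repeats
before locating the crossing, and reports "not reached" rather than
extrapolating.

## Poisson analytics for isolated nodes

With `π = C(N−(n−1), M)/C(N, M)` the probability that a fixed node is
isolated and `λ = nπ`, the isolated count `W` is approximately Po(λ). The
total-variation bound computed here is the Stein–Chen estimate

    Δ = min(1, 1/λ) · ( n²π² + n(n−1)π₂ ),   π₂ = C(N−(2n−3), M)/C(N, M),

the classical `b1 + b2` bound for sums of dependent indicators, taking the
whole index set as each indicator's dependence neighbourhood (every edge
in G(n, M) competes for the same budget of M edges, so no smaller
neighbourhood is exact). π₂ is the probability that two fixed nodes are
both isolated, i.e. that all 2n−3 pairs touching them are empty. The
bound is provably valid, vanishes as the density M/N → 1 (π, π₂ → 0), and
is checked in the suite against the exact distribution of W — obtained by
enumerating all C(N, M) edge sets — on every instance with n ≤ 6. All
binomial coefficients are evaluated through log-gamma; at PPI scale
(n ≈ 6000, M ≈ 1.4×10⁵) π is of order 10⁻²¹ and λ ≈ 10⁻¹⁷, far below what
naive arithmetic survives. Poisson pmfs are truncated where their
cumulative mass exceeds 1 − 10⁻¹⁵ and the truncated mass is reported as an
explicit error-budget term, never silently dropped. Observed isolated
counts are assessed through the clamped interval
`[P(Z≥k) − Δ, P(Z≥k) + Δ]`.

A Monte-Carlo variant (`montecarlo_postattack_dtv`) estimates the
post-attack law of W empirically: it simulates G(n, M) replicates, runs
the configured attack campaign on each, and reports the empirical pmf,
its total variation distance to a mean-matched Poisson, and a multinomial
standard-error estimate. It stands in for closed-form post-attack bounds,
which are out of scope here.

The critical divergence rate `p*` (root of `p·e^p = 1`, ≈ 0.5671432904)
is found by Brent's method to ~1e−15 residual and cross-checked against
the Lambert-W identity `p* = W(1)` in the tests.

## Problem sizes and defaults

The equivalence experiments grow DD(3, 0.4) networks for 1000 duplication
steps with 5 repeats — the study conditions for the standard model — and
the node-loss analyses use p = 0.4 (the value estimated for several real
PPI networks, and safely below p*), q ∈ {0.2, …, 0.8}, 1000 steps, 10
repeats. Distribution-level tests use 30 000 G(n, M) draws, 2×2000 growth
runs for the KS comparison at 50 steps, and 20 000 replicates for the
empirical-vs-exact pmf check on G(4, 2); these sizes give Monte-Carlo
standard errors an order of magnitude below the asserted tolerances.

## What the synthetic generators do and do not capture

The generators reproduce the structural mechanisms under study —
duplication, divergence, gene loss, uniform random wiring — with unit
interaction strengths. They do not emulate measurement noise, false
positive/negative interactions, STRING evidence-channel structure,
weighted confidence scores, or any biological covariates; passing tests
therefore validate the algorithms and their stated distributional
properties, not the fidelity of any particular organism's network. Real
STRING-style edge lists can be loaded (score thresholding with the
pre-threshold node universe, so thresholding creates isolated proteins),
but attacks always run on unit weights.

## Known limitations

* The loss-step semantics of the node-loss model are a modelling choice
  (see above); both implemented readings are simulable but only
  `newest_only` keeps the isolated fraction away from 0.
* Distributed-attack granularity changes equivalence-point magnitudes by
  an order of magnitude; any comparison across implementations must fix
  the granularity (and, for Bernoulli thinning, the per-edge probability)
  explicitly.
* The Stein–Chen bound is conservative in the sparse regime (it does not
  exploit the negative part of the edge-budget dependence); it is tight
  enough for the significance statements made here, where λ is
  astronomically small anyway.
* Exhaustive enumeration of L(W) is limited to ~10⁶ edge sets; beyond
  that, the Monte-Carlo estimator is the only oracle.
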