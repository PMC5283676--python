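# Methods

## Model

`ordbs` works with linear Gaussian causal DAG models over p nodes. In a
causal (topological) order, every node carries

    X_j = m_j + sum_{i in parents(j)} w_ij X_i + eps_j,    eps_j ~ N(0, sigma_j^2),

so `W = (w_ij)` holds the direct causal effects, `m` the baseline means and
`sigma` the baseline noise levels. An experiment is one joint draw of all
nodes; an intervention (knock-out) clamps a node to a fixed value — 0
throughout the benchmark — and the clamped value still feeds the node's
descendants. The total-effects matrix `L = (I − W)^{-1} = I + W + … +
W^{p−1}` accumulates direct and mediated effects along all paths.

Given data `x^k` (k = 1..N) with per-experiment intervention sets `J_k`,
node j's likelihood terms run only over `K_j = {k : j ∉ J_k}`: an experiment
that clamps j carries no information about j's own parameters, but does
inform its descendants.

## Ordering-conditional maximum likelihood

Conditional on a causal ordering `o`, the MLE has a closed form. Centering
all columns by their `K_j`-mean profiles out `m_j`; the weights into the
node at position b solve one least-squares problem against the columns at
positions < b, restricted to `K_j`; the variance estimate is the mean
squared residual (ML convention, divisor `N_j`). The joint normal-equation
system over all p(p−1)/2 weights is block-diagonal across target nodes, so
the per-node solves are mathematically identical to the literal joint solve
(asserted to 1e−10 in the tests) while costing O(p^4) instead of O(p^6).

Numerical choices:

- **Variance floor** `sigma_floor = 1e−8` (configurable) on fitted standard
  deviations keeps the log-likelihood finite on noiseless or interpolating
  fixtures; the likelihood is then evaluated at the floored value, so the
  reported `ell_max` is always the likelihood actually attained.
- **Ridge fallback**: a singular predecessor Gram block gets `1e−10` added
  to its diagonal before the solve; only a still-singular system raises.
- **Minimum data**: full-model fits require `N_j ≥ 2` for every node
  (mean plus variance need two residual degrees of freedom in the ML sense).

`OrderingLikelihood` precomputes the per-node centered Gram matrices once
per dataset, after which each ordering costs p small solves; this is what
makes exhaustive enumeration at p = 8 (40 320 orderings) and the
full-likelihood Metropolis sampler affordable.

## Pair and triplet preference estimation

The pair preference `pi[i, j]` — the probability that i precedes j — is the
likelihood-ratio weight of the two orientations of the complete two-node
subgraph on the data restricted to columns {i, j}:
`pi[i,j] = 1 / (1 + exp(l(j,i) − l(i,j)))` with `l(·)` the subgraph maximum
log-likelihood. Triplet preferences soft-max the six ordered complete
three-node subgraph likelihoods of every unordered triple. By default,
experiments intervening on nodes *outside* the subgraph are excluded before
fitting (`exclude_external_interventions=True`); the flag is exposed since
this is an empirical choice, not a structural one.

A consequence worth knowing: on purely observational rows both orientations
of a two-node subgraph are saturated bivariate Gaussian models, so their
maximum likelihoods coincide exactly and `pi = 1/2`. All directional signal
in pair preferences comes from the intervention rows. Triplets retain some
observational signal (the three-node model is not saturated across
orderings), which is one reason they outperform pairs.

Implementation: subgraph fits reduce to centered second-moment blocks
accumulated per intervention pattern (experiments grouped by their
intervention node set), so building all C(p,3) tables costs seconds at
p = 20 for any N. Probabilities are clamped to `[1e−300, 1 − 1e−16]` before
logs — subgraph log-likelihoods at benchmark noise levels reach magnitudes
whose literal exponentials overflow. The Babington-Smith score of a full
ordering is the sum of `log pi` (or `log rho`) over all internal pairs
(triples); swap deltas are available in O(p) / O(p²) closed form and are
verified against from-scratch differences.

## Metropolis sampling over orderings

Chains propose swapping two uniformly chosen positions and accept with
`min(1, exp(delta))` where delta is the change in the target log-score:
the full `ell_max` or a Babington-Smith surrogate. Defaults mirror the
benchmark schedules: surrogate chains run 100 chains × 10100 steps (15200
at p ≥ 50) recording the trailing 100 states; full-likelihood chains run
10 × 50 (25 at p ≥ 50) with every visited state recorded, reflecting the
vastly higher per-step cost. Recorded states are pooled across chains,
deduplicated (the sample collection is a set), and the `n_incl = 100` best
by surrogate score are kept; their true `ell_max` values are then computed
and estimates averaged with weights proportional to `exp(ell_max)`
(max-shifted, hence exactly invariant to constant shifts). Surrogate-score
ties at the selection boundary break lexicographically so runs are
reproducible.

The production pair/triplet sampler evaluates each proposal's score from
scratch with vectorized preference-table gathers, batched across chains; at
the p ≤ 50 scales this package targets that is faster in NumPy than
incremental per-chain updates in the interpreter, and it cannot drift. The
generic single-chain `metropolis_chain` accepts an incremental swap-delta
function with periodic from-scratch refresh, and is what the stationarity
tests exercise. Per-chain generators are spawned from the master seed, so
any chain is reproducible in isolation.

## Greedy ordering construction

Starting from the pair (triple) with the largest preference, nodes are
inserted one at a time at the (node, gap) choice maximizing the partial
Babington-Smith log-likelihood over the placed nodes; all gaps are scanned,
and ties resolve to the lowest (node index, position). Prefix-sum
bookkeeping keeps the total table traffic at O(p³) for pairs and O(p⁴) for
triplets (instrumented and asserted in tests). The construction verifiably
maximizes each insertion step (brute-force cross-checked), so its output
quality is bounded by the quality of the preference tables, not the search.

## Evaluation metrics

- `bad_edge_fraction`: over all p(p−1) ordered off-diagonal pairs, a
  truly-zero edge is bad iff |ŵ| > w0; a truly-nonzero edge is bad iff the
  absolute relative deviation |(w − ŵ)/ŵ| > w1, with ŵ = 0 counted bad (the
  limit of the ratio). The estimate-denominator reading follows the printed
  formula; `relative_to="truth"` switches the denominator. Defaults
  w0 = 0.1, w1 = 0.5.
- `roc_curve`: edges are called nonzero when |ŵ| ≥ w2; sweeping w2 over all
  distinct magnitudes gives TPR/FPR and the trapezoidal AUROC (bounded by
  one). A `normalize="p2"` variant divides raw counts by p² instead, for
  strict replication of that convention.
- `kendall_tau`: number of node pairs ordered oppositely in two orderings
  (bubble-sort distance), 0 … p(p−1)/2.

## Synthetic ensemble

`generate_random_dag` draws the benchmark ensemble: each ordered pair i < j
receives an edge with probability q (q = 1 for complete graphs,
q = c/(p−1) for c expected neighbours); weights are uniform in magnitude on
[0.4, 1] with random sign, so present edges are well separated from absent
ones; m_j = 1/2; sigma_j uniform on [0.01, 0.1] (an alternative strong-noise
interval [0.1, 1] is preset). Datasets have N = 10p experiments; the first
r carry one knock-out each, assigned round-robin so every node is clamped
either floor(r/p) or ceil(r/p) times.

What the generator does *not* emulate about real expression data: latent
confounders, non-Gaussian noise, measurement error on clamped nodes
(knock-outs are exact zeros), cyclic feedback and time dynamics. Passing
benchmarks therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to their violation; the generic
expression/intervention TSV inputs exist precisely so real compendium data
(e.g. yeast knock-out collections) can be pushed through the same pipeline.

## Benchmark scales and reproducibility

The bundled acceptance script and test suite run the ensemble at desk
scale on one CPU: 1000 replicates for the exact-ordering estimator, 50
replicates with 20 chains for the pair/triplet samplers, 200 replicates for
the full sampler, and 30–50 replicates per cell for the ranking and greedy
studies. Replicates are seeded as (master seed, r, replicate index) through
a spawning seed sequence, so every replicate and chain is independently
reproducible and results do not depend on execution order. Aggregates
report means with standard errors across replicates; method comparisons use
paired per-replicate differences, which share the DAG draw and are much
tighter than unpaired ones.

## Known limitations

- The bad-edge fraction of the full-likelihood sampler is sensitive to its
  step budget: 50-step chains at p = 20 are still far from equilibrated, so
  small implementation differences (proposal mix, arithmetic) shift its
  score noticeably. Treat its absolute value as schedule-specific.
- Pair preferences carry no observational directional signal (saturation,
  above); with few interventions and strong confounding they can be
  confidently wrong, and the greedy construction then optimizes a
  misdirected score. The triplet tables mitigate but do not remove this.
- All estimators condition on a linear Gaussian acyclic model without
  latent variables; nothing here tests for those assumptions.
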