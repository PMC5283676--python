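# ordbs

Causal ordering and causal-effect estimation for **linear Gaussian DAG
models** from mixed observational/interventional expression data — e.g.
gene-expression compendia combining wild-type profiles with knock-out
experiments.

## The problem and the method

A causal Bayesian network over p genes with weights `W`, baseline means `m`
and noise levels `σ` generates each expression vector by

    X_j = m_j + Σ_{i ∈ pa(j)} w_ij X_i + ε_j,   ε_j ~ N(0, σ_j²),

visiting nodes in an (unknown) causal order; a knock-out clamps a gene to 0
and feeds that value to its targets. Learning the DAG is equivalent to
learning the **causal ordering** `o`: conditional on `o`, the maximum
likelihood estimates `(Ŵ, m̂, σ̂)` and the maximized log-likelihood
`ℓ_max(o)` have closed forms (per-node least squares over the experiments
that did not intervene on that node). The posterior over orderings,
`P(o) ∝ exp ℓ_max(o)`, lives on p! permutations, so it is explored by
Metropolis sampling with position-swap proposals — either scoring with
`ℓ_max` itself (expensive per step) or with cheap **Babington-Smith
surrogate scores** built from pairwise preferences

    π_ij = exp ℓ²max(i,j) / (exp ℓ²max(i,j) + exp ℓ²max(j,i)),

estimated from two-node subgraph fits, or from their triplet-wise
generalization `ρ_ijk` (six-way soft-max of three-node subgraph fits). The
best sampled orderings are re-scored with the true `ℓ_max` and estimates —
weight matrices `Ŵ`, total effects `L = (I−W)⁻¹` — are averaged with
weights `∝ exp ℓ_max(o)`. A deterministic greedy construction over the
preference tables provides a single high-preference ordering in O(p³)
(pairs) or O(p⁴) (triplets).

The package contains the model and ensemble generator (`dag_model`), the
closed-form MLE (`likelihood`), preference tables and BS scores
(`preferences`), the samplers (`sampling`), the greedy builder (`greedy`),
quality metrics — bad-edge fraction, AUROC, Kendall tau — (`evaluation`),
a benchmark harness (`bench`) and TSV/JSON readers and writers
(`io_formats`), plus the `ordbs` command line.

## Worked example

Simulate an 8-gene complete network with 40 knock-outs, sample orderings
with the triplet surrogate, and score the averaged weights against the
generating model:

```sh
ordbs simulate --p 8 --q 1 --interventions 40 --seed 7 --out-dir demo
cd demo
ordbs sample   --expr expression.tsv --interv interventions.tsv \
               --method triplet --chains 10 --steps 2000 --record 100 \
               --n-incl 50 --seed 7 --out-dir .
ordbs evaluate --truth-model model.json --w-est W_avg.tsv
ordbs greedy   --expr expression.tsv --interv interventions.tsv \
               --mode triplet --truth-model model.json
```

prints

```
kept 2 orderings; top: n0,n2,n1,n3,n4,n5,n6,n7
{
 "auroc": 1.0,
 "n_bad": 0.08928571428571429,
 "w0": 0.1,
 "w1": 0.5
}
ordering: n0,n2,n1,n3,n4,n5,n6,n7
triplet BS log-likelihood: -20.1076
Kendall tau to generating order: 1
```

Reading this: the ten chains collapsed onto two high-scoring orderings; the
likelihood-weighted weight estimate separates true edges from absent ones
perfectly (AUROC = 1.0) and 8.9% of the 56 ordered gene pairs miss the
weight-accuracy thresholds (w0 = 0.1 absolute for absent edges, w1 = 0.5
relative for present ones). The greedy ordering differs from the generating
one by a single adjacent transposition (Kendall tau 1).

Real datasets enter as a tab-separated expression matrix (header = gene
labels, one row per experiment) plus an intervention table
(`experiment<TAB>GENE=value;...`), and can be subset to a gene panel with
`--genes`; see `ordbs <command> --help`.

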