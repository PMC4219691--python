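# Methods

## Model and assumptions

`labnet` treats network inference as *p* local regression problems: gene
*i*'s expression is modelled as a sparse linear function of the remaining
genes, and the selected predictors become *i*'s neighbours. Linearity is
assumed only locally, per response gene, which is the standard justification
for neighbourhood selection on expression data. Self-interactions and edge
direction are outside the model: the response is never among its own
predictors, and the final adjacency is symmetrised, so the output is the
undirected skeleton of the main associations, not a causal or signed graph.

The per-response objective is

    (1/2n) * ||y - X beta||^2 + lambda * ||beta||_1

with no intercept. Data are standardized once (per-gene mean 0, sd 1,
denominator n) before any fit; an intercept-free Lasso on uncentred data
would be biased, and unit scaling makes one λ meaningful across responses.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `cv_folds` | 3 | folds of the λ cross-validation |
| `lambda_subset_fraction` | 0.10 | fraction of genes used as CV responses |
| `grid_size` | 100 | log-spaced λ grid, λ_max → 10⁻³·λ_max |
| `best_fraction` | 0.80 | fraction of non-zero step-1 coefficients kept as candidates |
| `fanout` | 1 | stable neighbours retained per response |
| `permutations` (B) | 500 | response permutations per gene |
| `significance_level` | 0.05 | empirical-null gate on the smallest counter |
| `gate_enabled` | true | whether the gate is applied (needs B ≥ 20) |
| `symmetrise_rule` | or | OR / AND / mean / max / min |
| `seed` | 0 | seeds every random choice |
| `workers` | 1 | gene-level parallelism (never changes results) |

λ is estimated once and reused everywhere, including all permutation
re-fits; per-response per-gene λ's are aggregated by the median, which
resists the occasional response whose CV curve bottoms out at the grid
floor. `lambda_max` for a response is `max_j |x_j' y| / n`, the smallest λ
with an all-zero solution.

## Permutation stability and the empirical-null gate

Counters are collected only for step-1 candidates ("selected again" =
non-zero coefficient in the permuted re-fit). Selection sorts candidates by
counter ascending, breaking ties by step-1 |coefficient| descending and then
gene index — the only other ranking signals available, and a deterministic
order is required by the parallelism contract.

The gate tests the *smallest* counter against the empirical distribution of
the other candidates' counters: its p-value is the fraction of those
counters ≤ it. A well-separated minimum gives p ≈ 0 and survives;
near-uniform counters — what a group of interchangeable, highly correlated
candidates produces, since the Lasso picks one member of the group
essentially at random in each permutation — give p ≈ 1 and the entire
selection for that response is discarded. The gate acts on the selection as
a whole, not per edge, and only when B ≥ 20 so the counter distribution has
support. With B = 0 the pipeline degenerates to pure step-1 fanout
truncation, with the gate off.

## Synthetic benchmark

The generator emulates the statistical shape of in-silico expression
benchmarks at desk scale, not their mechanistic kinetics:

* **topology** — Barabási–Albert preferential attachment (undirected,
  connected, right-skewed degree distribution); one edge per new node gives
  the 49-edge tree used by the 50-gene benchmark;
* **expression** — a linear structural equation model over a seeded random
  acyclic orientation: roots are standard normal, every other gene is the
  signed-coefficient sum of its parents plus N(0, noise_sd²) noise,
  coefficient magnitudes uniform in [coef_low, coef_high] with random sign
  (defaults ±[0.5, 1.5], noise_sd 0.1, n = 100 — strong but not trivial
  signal at benchmark scale);
* **multicollinearity** — optional clone genes, each ρ-correlated with a
  randomly chosen source gene.

Because the inference model is locally linear, a linear generator is the
matching null ecosystem: passing tests show the pipeline recovers linear
local structure under noise and collinearity. They do not show robustness
to the nonlinear kinetics, saturation, or measurement models of real
microarray data, and the gold standards here are undirected by
construction.

## Numerical choices

* The Lasso is solved by Gram-matrix cyclic coordinate descent
  (`labnet._solver`, numba-compiled); soft-thresholding yields exact zeros,
  so supports (and therefore counters) are well defined. Convergence is
  declared when the largest coefficient update in a sweep is ≤ 1e-7
  (step-1 fits). The Gram matrix `X'X/n` is computed once per response and
  shared by all of its permutation re-fits.
* Permutation re-fits only contribute their support, never coefficient
  values, and run at tolerance 1e-5 with a 2000-sweep cap; at the
  benchmark's smallest CV-chosen λ this changes well under 1% of support
  entries versus the tight setting and is ~5× faster. The test suite
  cross-checks the kernel against an independent reference implementation
  at tolerance 1e-6.
* λ cross-validation uses path-wise fits per fold; non-convergence warnings
  at the smallest grid λ's are suppressed as immaterial to ranking λ's by
  held-out error.
* Per-response RNG substreams are derived from `(seed, response index)`, so
  results are independent of scheduling and worker count; B-grid sweeps
  reuse the sequential permutation stream, making checkpointed counters
  bit-identical to independent runs at each B.
* Degenerate inputs: zero-variance genes are rejected by name at
  standardization; an identically-zero predictor column can never be
  selected; empty step-1 fits propagate to empty selections; undefined
  centrality correlations (constant vector) return NaN with a warning
  rather than raising.

## Benchmark problem sizes

The acceptance suite runs the full pipeline on 50-gene, 100-sample
benchmarks: topology conservation as the median over 5 seeded replicates at
B = 500, and connectivity growth as the median predicted edge count over 10
replicates across B ∈ {0, 50, 200, 500}. `scripts/acceptance.py` reports
medians over 9 replicates for a steadier estimate of the same quantities.
Observed behaviour at these sizes: degree correlations typically 0.8–0.93,
betweenness correlations 0.55–0.85, MCC 0.15–0.5, with the weaker
replicates being those whose cross-validated λ lands near the grid floor.
Betweenness, a global path statistic, is consistently more sensitive than
degree to the handful of false edges that bridge distant parts of the gold
tree.

## Known limitations

* Interaction magnitude and direction are deliberately ignored; activation
  vs inhibition is not represented.
* The elastic-net penalty (useful when a too-small λ excludes whole
  correlated groups) is not implemented.
* Performance scales with p × B Lasso solves per run; very small
  cross-validated λ's (near-OLS fits) are the slow case.
* The empirical-null gate is coarse for small candidate sets, where the
  left-tail p-value takes few distinct values.
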