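# Methods

`biafs` implements a two-stage hybrid feature-selection method for
bioimpedance body-composition tables: a kernel-dependence *filter* that
removes features irrelevant to a continuous target, followed by an
improved Chameleon *clustering* stage that removes redundant features.
This note records the model, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Data model and feature expansion

A sample table holds, per subject, five segmental impedances
R1..R5 (ohms; left/right arm, trunk, left/right leg, one frequency band
per table), age A (years), height H (cm), weight W (kg), a binary sex
indicator G, and one or more continuous targets (BFM, TBW; kg).
`expand_features` augments the primaries with the segmental conductance
terms 1/Ri, all ten pairwise products RiRj and the five squares Ri²,
in a fixed order, giving 29 columns with sex included. The reciprocal
and square terms matter because bioimpedance practice models fat-free
mass as proportional to H²/R, so informative relationships are often in
the reciprocal/product space rather than in R itself.

Columns are z-scored (sample sd, n−1) before dependence scoring; this
makes rbf bandwidths comparable across columns and is an exact,
invertible transform (stored means/sds). Constant columns are flagged
and excluded from scoring rather than scaled.

## Stage 1 — HSIC relevance filter

The Hilbert–Schmidt Independence Criterion of a feature f and target c
is the squared HS-norm of the cross-covariance operator between their
kernel embeddings; it is zero iff f ⊥ c for characteristic kernels. We
use the standard biased plug-in estimator

    HSIC_b(f, c) = tr(K H L H) / (n − 1)²,   H = I − (1/n)·11ᵀ,

with Gaussian kernels k(x, x') = exp(−(x−x')²/2σ²) on both sides by
default and the median heuristic σ = median of non-zero pairwise
absolute differences. The median heuristic makes scores invariant to
affine rescaling of a feature, so raw-unit disparities (ohms vs ohm²)
cannot distort the ranking. A linear target kernel is available by
configuration. Note the algebraic identity tr(KHLH) = ΣK̃L̃ expansion
holds with 1/n² normalization; the estimator's (n−1)² denominator is the
conventional finite-sample choice and differs from the raw expansion by
the factor n²/(n−1)².

Significance is assessed by a permutation test (default 999 shuffles,
seeded): p = (1 + #{permuted ≥ observed}) / (n_perm + 1). Permuting a
feature's sample labels permutes both axes of its Gram matrix, so each
shuffle is an O(n²) re-indexing, not a kernel recomputation. The "80 %
confidence" filter keeps features with p ≤ 0.20; the test is calibrated
(measured null rejection 0.208 at nominal 0.20 over 500 replicates).
Ranking ties break by original column order; with `top_k` the filter
becomes a fixed-size ranking cut and no permutations run.

## Stage 2 — improved Chameleon redundancy removal

Survivors are clustered on a sparse feature graph: vertices are
features, edge weights are |Pearson r| across subjects, edges exist
between union-symmetrized k nearest neighbours (default k=3; tie at the
k-th neighbour goes to the lexicographically smaller name). For cluster
pairs (c1, c2):

* EC{c1,c2} — total cross-edge weight; S̄EC{c1,c2} — mean cross-edge weight;
* |EC|_c, S̄EC_c — cut weight and mean cut-edge weight of the *balanced
  minimum bisection* of c (halves differing by ≤ 1 vertex);
* RI = EC{c1,c2} / ((|EC|_c1 + |EC|_c2)/2) — relative interconnectivity;
* RC = S̄EC{c1,c2} / ( |c1|/(|c1|+|c2|)·S̄EC_c1 + |c2|/(|c1|+|c2|)·S̄EC_c2 )
  — relative closeness (standard Chameleon size weighting);
* merge score S = RI · RC^α, α = 1 by default.

Agglomeration starts from `k_init` clusters (default: all singletons)
produced by recursive balanced min-bisection of the graph, and merges
the highest-S pair until `k_target` clusters remain (default 4). The
"improvement" over classical Chameleon is that *all* current cluster
pairs — including clusters created by earlier merges — are re-scored
after every merge. A literal smallest-S merge rule is kept behind
`merge_rule="min"` for auditability only.

Numerical choices: bisection is exhaustive for clusters of ≤ 14 vertices
(the optimum is certain) and a seeded best-improvement pairwise-swap
local search with 10 restarts above that; per-cluster rngs are derived
from the run seed and the cluster's sorted names so cached quantities
are exactly reproducible. Singleton clusters have no bisection; their
|EC| and S̄EC fall back to the vertex's mean incident edge weight, which
keeps RI/RC finite and singletons mergeable. A zero RI/RC denominator
with a positive numerator is treated as maximal (ε = 1e-12 divisor). If
every pairwise S is zero the pair with the largest raw EC merges; if all
EC are zero, the two smallest clusters merge (logged).

Redundancy removal then takes one of two forms:

* `prune_farthest` (default, matching the source experiment's 14→10
  reduction): within each final cluster, remove the `m_remove` features
  (default 1) with the largest Euclidean distance between their z-scored
  vector and the z-scored target, never emptying a cluster. Note this
  distance is sign-sensitive: d² = 2n(1 − r), so anti-correlated
  features are "far" even when strongly dependent.
* `representatives`: keep the single maximum-HSIC feature per cluster
  (ties by rank).

## Evaluation

Model quality uses the standard OLS summary (R, R², adjusted R², SEE)
on a deterministic file-order split: first 80 rows train, remainder
test, plus per-subject held-out relative errors |ŷ−y|/|y| (zero actuals
flagged and excluded). The rank check standardizes design columns
before testing singularity, because raw columns span ~1e-3 (1/R) to
~1e5 (Ri²) and a unit-sensitive tolerance would reject every legitimate
bioimpedance design. Three published body-fat equations (BFM1–BFM3)
ship as fixtures and are applied to raw feature values as printed;
reproducing the original study's figures additionally requires the
study's measurement spreadsheet, which is not redistributable here.

## Synthetic cohort generator

The generator emulates the structure of a segmental multi-frequency
body-composition dataset for n adults (default 100, the study's size):

* G ~ Bernoulli(0.5); A ~ U(18, 65) years; H ~ N(163 + 12G, 6) cm;
  W = BMI·(H/100)² with BMI ~ N(23, 3);
* legs: latent R̄leg = 320 − 1.5(H−170) − 7(BMI−23) − 10G + N(0, 15),
  with R4, R5 = R̄leg + N(0, 3) — a bilateral pair with r ≈ 0.99
  (planted redundancy) carrying the conductance signal;
* arms: latent 340 + N(0, 30), R1, R2 = latent + N(0, 4) — a bilateral
  pair *independent of the target* (planted irrelevant block);
* trunk: R3 = 30 + 0.04(arm latent − 340) + N(0, 3.8) — weakly
  correlated with the arm limbs (r ≈ 0.3), independent of the target;
* BFM = −12 + 0.75W − 7G + 0.18A − 0.20·H²/R̄leg + N(0, 1.5);
  TBW = 1 + 0.30·H²/R̄leg + 0.10W + 2G − 0.02A + N(0, 1);
* per-band impedance scaling 1.15 / 1.00 / 0.88 for 1 kHz / 250 kHz /
  500 kHz (impedance falls with frequency); targets are generated from
  the band-independent latents.

The coefficients were chosen so each planted signal is *marginally*
detectable at n=100 (population correlations with BFM: W 0.60, G −0.32,
A 0.37, R4 −0.40, arms/trunk ≈ 0) — a filter method can only be
benchmarked on signals a marginal statistic can see. Height is
deliberately marginal-null (its weight-mediated and conductance paths
cancel), which exercises the known blind spot of marginal filters.
Rare slightly negative BFM values in the far tail are an accepted
artifact of the linear form.

What the generator does **not** emulate: real measurement error
structure, device quantization, inter-segment couplings beyond the
planted ones, non-Gaussian anthropometric tails, or any attempt to
match a specific analyzer's population. Passing recovery tests
therefore shows the algorithmic machinery behaves as designed on known
structure, not that it reproduces any particular device's feature sets.

## Known limitations

* The recovery benchmark (50 cohorts, default settings) shows a
  structural tension in the method itself: a calibrated level-0.20
  filter admits each collinear noise *block* with probability ≈ 0.2,
  and prune-farthest removes only one feature per cluster, so several
  redundant or irrelevant features can survive together; conversely the
  one-representative-per-cluster rule cannot cover more signal groups
  than there are clusters. The acceptance suite documents the measured
  rates rather than hiding them.
* HSIC is computed feature-by-feature (marginal); jointly relevant but
  marginally independent features (e.g. height here) are invisible to
  stage 1 by design.
* Sign-sensitive pruning distance: strongly anti-correlated relevant
  features (sex, leg impedances here) are systematically "far" from the
  target and may be pruned before weaker but positively correlated ones.
* Problem sizes: all shipped studies use n=100 subjects, 29 features,
  999-permutation tests and 50-seed replications, which run in a couple
  of minutes on one CPU; the clustering stage is exact (exhaustive
  bisection) at these feature counts.
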