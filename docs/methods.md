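# Methods

This note records the modeling choices, defaults and numerical conventions
behind braingraph, and what the synthetic benchmarks do and do not show.

## Network construction

Structural mode correlates regional values *across subjects*, giving one
association matrix per group; functional mode takes one association matrix
per subject (optionally supplied as Fisher z-scores and back-transformed
with tanh). Diagonals are zeroed and symmetry is enforced by averaging with
the transpose.

Nuisance covariates are removed per region by ordinary least squares on
[intercept + all covariates]; residuals replace the raw values. An intercept
is always included (otherwise residuals retain the group mean and the
subsequent correlations are distorted). Interaction terms are the caller's
responsibility: the covariate table is used as given.

Partial correlations come from the inverse of the full correlation matrix
without regularization, and are refused when subjects ≤ regions (singular
matrix) with a warning below 2× regions, where the estimates are unstable.

**Thresholding.** At target density D the E = round(D·N(N−1)/2) node pairs
with the largest *signed* correlation become edges (round half away from
zero; negative correlations enter only at very high densities — an
absolute-value rule is deliberately not offered). Ties at the cutoff are
broken by ascending (i, j) lexicographic node order, so edge sets are
deterministic across runs and platforms, and nested across any density
grid when weights are distinct. `find_dmin` scans the grid (default step
0.01) ascending and returns the first density at which every supplied
network is a single connected component. Analyses below D_min are allowed
but emit a warning (below ~0.2 small-world metrics also become strongly
null-model dependent).

## Graph measures

All measures use standard binary-undirected definitions: per-node
clustering 2t/(k(k−1)) with degree-0/1 nodes scoring 0 and included in the
mean; transitivity 3·triangles/triples; characteristic path length as the
mean BFS distance over pairs; global efficiency as the mean inverse
distance (0 for disconnected pairs); local efficiency as the global
efficiency of each node's neighbor subgraph; betweenness by exact Brandes
accumulation, normalized by (N−1)(N−2)/2 (the normalization cancels in
mean + k·SD hub selection); assortativity as the Pearson correlation of
degrees over edge ends, NaN with a warning on degree-regular graphs.

On fragmented graphs, path length is computed on the largest component and
a `fragmented` flag is carried into results; permutation comparisons record
the fraction of fragmented observed networks. The implementation is
vectorized over dense numpy adjacency matrices (graphs here have at most a
few hundred nodes) so that full permutation runs stay cheap; tests verify
it against networkx and against independent brute-force enumeration on all
small connected graphs.

**Modularity.** Q is maximized best-of-`iterations` (default 100) over
seeded Louvain restarts (greedy agglomeration available); ties are resolved
first-found under the seeded run order. On every connected graph with ≤ 6
nodes the returned Q equals the exhaustive-enumeration optimum.

## Null models and small-worldness

Topology nulls are degree-preserving double-edge swaps (default 10 attempts
per edge); the degree histogram is preserved exactly, and graphs with no
valid swap (stars) are returned unchanged with a warning. Covariance nulls
use a random-factor construction: an N×k Gaussian factor matrix F with
entry mean μ and SD s chosen so the Gram matrix FFᵀ matches the observed
off-diagonal mean and variance in expectation, k chosen so the expected
diagonal is closest to 1, then exact normalization to a correlation matrix.
The output is PSD by construction; the moment match is exact before
normalization and accurate to ~0.01 after it. A negative off-diagonal mean
cannot be represented by this construction; mean 0 is substituted with a
warning. Ensembles derive per-member seeds from one master seed, so they
are reproducible and member-order independent.

σ = (C/C_rand)/(L/L_rand) with ensemble means; covariance-mode members are
thresholded at the same density as the source graph before metric
extraction.

## Statistical comparison

Permutation reassigns subjects to pseudo-groups of the original sizes;
residualized data are reassigned as-is (the nuisance regression is not
redone per repetition). p = (1 + #{null as or more extreme}) / (1 + n_perm)
— the add-one rule is exchangeability-exact and never returns 0. Two-tailed
tests use |difference|. Defaults: 1000 permutations structural, 2000
functional. Confidence bands are percentile intervals of the permutation
null per density. AUC uses the trapezoid rule; FDA is the plain sum of
pointwise differences (a grid-step-weighted variant exists behind a flag).
Regional tests report Benjamini–Hochberg FDR alongside raw p-values.

## Hubs, resilience, degree distribution

Hubs: value > mean + k·sample-SD (N−1 denominator, strict inequality);
k = 2 and betweenness are the defaults. At-density, AUC-of-curve and
FDA-of-curve variants share the rule.

Resilience: node-removal curves record the chosen measure (size, path
length, global/local efficiency) of the surviving largest component after
each deletion. Targeted attack uses a static ordering computed once on the
intact graph (ascending-index tie-break); an adaptive recompute-each-step
option exists. Random failure averages 100 random orders by default.

Degree fits: the complementary cumulative distribution P(k ≥ d) is fitted
by nonlinear least squares on the untransformed values (log-scale option
available); degree-0 points are excluded (the power-law forms are singular
there). Each model carries a free amplitude; the optimizer restarts from a
grid of initial values. Note the truncated power law d^(e−1)·exp(−d/d_c)
nests the exponential exactly at e = 1 and approaches a pure power law as
d_c → ∞, so R² comparisons between nested pairs can tie on noiseless data.
The reported exponent is e in the form above (not e−1).

## Synthetic benchmark

The generator draws subjects from a multivariate normal with a chosen
correlation topology. Defaults emulate a modular structural covariance
study: 20 regions, 20 subjects per group, 5 equal modules, within-module
r = 0.5, between-module r = 0.1, no measurement noise; a group effect
multiplies group B's within-module correlations (0.6 ≡ a 40% attenuation is
the standard effect condition). The lattice topology uses within_r^distance
on a ring (strictly positive definite); the random topology uses weak
unstructured factor correlations. Non-PSD custom matrices are rejected with
the distance to the nearest PSD correlation matrix in the message.

What this emulates: sampling noise of correlation estimates, modular
covariance, diffuse group effects. What it does not: non-Gaussian
morphometry, spatial autocorrelation of parcels, scanner/site effects,
registration error. Passing calibration tests therefore demonstrates the
statistics are exact under exchangeability and sensitive to covariance
topology, not that any particular empirical effect would be detected.

**Power at benchmark scale.** With 20-subject groups, density thresholding
removes the mean correlation difference between groups; a 40% within-module
attenuation survives only as a second-order effect (noisier edge ranking in
the attenuated group), giving observed-effect/replicate-SD ratios near 1.2–1.3
for all global metrics and single-metric permutation power of roughly
0.15–0.3 at α = 0.05. Detecting effects of this kind at conventional power
needs larger samples, stronger effects or pooled evidence across metrics.
The type-I error of the pipeline is calibrated (add-one permutation p-values
are exact under exchangeability; measured 0.04 over 200 null replicates).

## Problem sizes in tests and the acceptance script

Oracle agreement uses the complete atlas of connected graphs to 6 nodes and
100 sampled 7-node classes; thresholding exactness uses 100 random 30-node
matrices; calibration uses 200 replicates × 200 permutations at the default
study conditions; the acceptance script runs 1000 permutations for the main
comparison and 100 null replicates for calibration. These sizes keep every
Monte-Carlo tolerance honest while the whole suite completes in about a
minute.

## Known limitations

Binary undirected graphs only (no weighted or directed variants); two-group
comparisons only; no covariate-adjusted permutation schemes
(Freedman–Lane); no maximum-likelihood power-law fitting with KS cutoff
selection; no image preprocessing (inputs are assumed segmented, normalized
and resliced to the atlas grid).
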