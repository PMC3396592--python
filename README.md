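# braingraph

Construction and between-group statistical comparison of binary undirected
brain networks, for researchers analyzing structural covariance (regional
gray-matter volume, cortical thickness, surface area correlated across
subjects) or functional connectivity (per-subject association matrices).

Univariate voxelwise analyses cannot answer whether the *organization* of a
brain network differs between a patient group and controls. braingraph
builds one network per group (structural mode) or per subject (functional
mode) and tests topology directly: small-worldness, modularity, hubs,
resilience to lesioning, and regional centrality.

## Method

**Construction.** From a subjects × regions table (optionally residualized
against nuisance covariates such as age, gender and total brain volume), an
N×N association matrix *R* is built with entries *r<sub>ij</sub>* — the
Pearson (or partial) correlation of regions *i* and *j* across subjects. A
binary adjacency matrix *A* keeps the *E* strongest correlations as edges,
where *E* is set by a target network density *D* = *E* / [*N*(*N*−1)/2].
Density thresholding guarantees compared networks have equal node and edge
counts. Analyses run over a density grid starting at *D*<sub>min</sub>, the
smallest grid density at which no network is fragmented.

**Small-worldness.** σ = (C/C<sub>rand</sub>) / (L/L<sub>rand</sub>), where
C is the mean clustering coefficient, L the characteristic path length, and
C<sub>rand</sub>, L<sub>rand</sub> are means over *m* benchmark null
networks (default *m* = 20): either degree-preserving edge rewires or random
correlation matrices matched to the observed off-diagonal moments.

**Group comparison.** Structural covariance yields one network per group, so
inference uses a permutation test (default 1000 repetitions): subjects are
randomly reassigned to pseudo-groups of the original sizes, networks are
rebuilt and the measure recomputed, giving the null distribution of the
between-group difference. Per-density differences, the area under the
measure-vs-density curve (AUC, trapezoidal), and a functional-data-analysis
statistic (FDA — the sum of pointwise differences across the grid) are all
tested; p-values use the add-one percentile rule. Regional comparisons
report uncorrected and Benjamini–Hochberg FDR-corrected p-values. Functional
mode has per-subject measures and additionally offers a two-sample t-test
(permutation default 2000 repetitions).

**Characterization.** Hubs are regions whose nodal measure (betweenness by
default) exceeds the network mean by *k* SD (default *k* = 2). Resilience is
simulated by deleting nodes randomly (failure) or in decreasing order of a
nodal measure (attack) while tracking the surviving largest component.
Modularity Q is maximized over repeated seeded community-detection runs
(default 100). The cumulative degree distribution is fitted with an
exponentially truncated power law *P(d)* ∼ *d*^(e−1) · exp(−d/d<sub>c</sub>)
and compared by R² against pure power-law and exponential alternatives.

## Worked example

Two synthetic groups of 20 subjects × 20 regions are drawn from a 5-module
covariance model (within-module r = 0.5, between 0.1); group B's
within-module correlations are attenuated by 40%:

```python
from braingraph import (SyntheticSpec, generate_structural, association_matrix,
                        find_dmin, DensityGrid, threshold_at_density,
                        topology_null_ensemble, small_world, permute_structural,
                        modularity_best_partition)

spec = SyntheticSpec(n_regions=20, n_subjects_a=20, n_subjects_b=20,
                     attenuation_b=0.6, seed=42)
data_a, data_b = generate_structural(spec)
R_a, R_b = association_matrix(data_a), association_matrix(data_b)
dmin = find_dmin([R_a, R_b], DensityGrid(0.05, 0.50, 0.01))
print("D_min =", dmin)

g_a = threshold_at_density(R_a, dmin)
sw = small_world(g_a, topology_null_ensemble(g_a, m=20, seed=0), density=dmin)
print(f"group A: gamma={sw.gamma:.2f} lambda={sw.lam:.2f} sigma={sw.sigma:.2f}")

grid = DensityGrid(0.30, 0.50, 0.05)
cmp = permute_structural(data_a, data_b, "clustering", grid, n_perm=1000, seed=1)
print(f"clustering AUC difference (A-B) = {cmp.observed_auc:.4f}, p = {cmp.p_auc:.4f}")

part = modularity_best_partition(g_a, iterations=100, seed=0)
print(f"group A modularity Q = {part.q:.3f} with {part.n_modules} modules")
```

prints

```
D_min = 0.34
group A: gamma=1.67 lambda=1.09 sigma=1.54
clustering AUC difference (A-B) = 0.0122, p = 0.2458
group A modularity Q = 0.281 with 4 modules
```

Both group networks become fully connected at density 0.34. Group A is
small-world (clustering 1.67× its degree-matched random benchmarks at
near-random path length, σ = 1.54). The intact group's clustering exceeds
the attenuated group's across the grid, though at these sample sizes the
difference does not reach significance for this seed — single-metric
permutation tests on 20-subject groups have modest power (see
`docs/methods.md`).

The same pipeline is scriptable from the shell:

```
braingraph simulate --regions 20 --subjects 20 --attenuation 0.6 --seed 42 --out data/
braingraph compare data/group_A.csv data/group_B.csv --metric clustering \
    --dmin 0.30 --dmax 0.50 --step 0.05 --seed 1
braingraph run config.yaml        # full pipeline from a YAML config
```

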