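"""Between-group statistical comparison of network measures.

Group networks built from structural covariance have one graph per group, so
subject-level variance is not directly available; significance is assessed
with a nonparametric permutation test.  Each repetition randomly reassigns
subjects to two pseudo-groups of the original sizes, rebuilds each
pseudo-group's association matrix, thresholds it across the density grid and
recomputes the measure, yielding the permutation distribution of the
between-group difference under the null hypothesis of exchangeability.

Because per-density tests depend on the (arbitrary) threshold, two
curve-level summaries are also tested: the area under the measure-vs-density
curve (AUC, trapezoidal) and a functional-data-analysis (FDA) statistic, the
plain sum of pointwise differences across the grid.  Regional (per-node)
comparisons report uncorrected and Benjamini-Hochberg FDR-adjusted p-values.

For functional networks, measures exist per subject, so a parametric
two-sample t-test is offered alongside the permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph_construction import (
    DensityGrid,
    edge_count_for_density,
)
from .graph_metrics import global_metric_function, nodal_metric_function
from .roi_extract import RegionalDataTable

__all__ = [
    "MetricCurve",
    "GroupComparison",
    "RegionalComparison",
    "auc",
    "fda_statistic",
    "pvalue_from_null",
    "fdr_correct",
    "t_test",
    "permute_structural",
    "permute_functional",
    "regional_compare",
    "metric_curves",
    "DEFAULT_N_PERM_STRUCTURAL",
    "DEFAULT_N_PERM_FUNCTIONAL",
]

DEFAULT_N_PERM_STRUCTURAL = 1000
DEFAULT_N_PERM_FUNCTIONAL = 2000


@dataclass
class MetricCurve:
    """One network measure evaluated over a density grid."""

    metric: str
    densities: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.densities) <= 0):
            raise ValueError("densities must be strictly increasing")
        if self.y.shape[0] != len(self.densities):
            raise ValueError("y length does not match densities")


@dataclass
class GroupComparison:
    """Observed difference, permutation null, p-values and confidence band."""

    metric: str
    densities: np.ndarray
    observed: np.ndarray          # A - B per density
    observed_auc: float
    observed_fda: float
    null: np.ndarray              # n_perm x n_densities
    null_auc: np.ndarray
    null_fda: np.ndarray
    p: np.ndarray                 # per density
    p_auc: float
    p_fda: float
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_perm: int
    tails: str
    ci_level: float = 0.95
    curve_a: np.ndarray | None = None
    curve_b: np.ndarray | None = None
    fragmented_fraction: float = 0.0


@dataclass
class RegionalComparison:
    """Per-region observed difference, raw and FDR-corrected p-values."""

    metric: str
    mode: str
    region_labels: list
    observed: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    n_perm: int
    tails: str


def auc(curve: MetricCurve | np.ndarray, d_lo: float | None = None,
        d_hi: float | None = None, densities: np.ndarray | None = None) -> float:
    """Trapezoidal area under a metric-vs-density curve on [d_lo, d_hi].

    Curve summaries like this make the comparison insensitive to any single
    threshold; densities above 0.5 are usually excluded upstream since such
    dense anatomical networks are unlikely to be biological.
    """
    if isinstance(curve, MetricCurve):
        x, y = curve.densities, curve.y
    else:
        if densities is None:
            raise ValueError("densities required for a bare array curve")
        x, y = np.asarray(densities, float), np.asarray(curve, float)
    lo = x[0] if d_lo is None else d_lo
    hi = x[-1] if d_hi is None else d_hi
    sel = (x >= lo - 1e-12) & (x <= hi + 1e-12)
    if sel.sum() < 2:
        raise ValueError("need at least 2 grid points inside [d_lo, d_hi]")
    return float(np.trapezoid(y[sel], x[sel]))


def fda_statistic(curve_a: MetricCurve | np.ndarray,
                  curve_b: MetricCurve | np.ndarray,
                  weighted: bool = False) -> float:
    """Sum over the density grid of pointwise differences y_A - y_B.

    ``weighted`` multiplies each term by the grid step (off by default; the
    plain summation is the standard form).
    """
    if isinstance(curve_a, MetricCurve) and isinstance(curve_b, MetricCurve):
        if not np.allclose(curve_a.densities, curve_b.densities):
            raise ValueError("curves are on different density grids")
        ya, yb = curve_a.y, curve_b.y
        x = curve_a.densities
    else:
        ya, yb = np.asarray(curve_a, float), np.asarray(curve_b, float)
        x = None
        if ya.shape != yb.shape:
            raise ValueError("curves are on different density grids")
    d = ya - yb
    if weighted:
        if x is None:
            raise ValueError("weighted FDA needs MetricCurve inputs")
        step = np.gradient(x)
        return float(np.sum(d * step))
    return float(np.sum(d))


def pvalue_from_null(observed: float, null: np.ndarray, tails: str = "two") -> float:
    """Permutation p-value by the add-one (smoothed) percentile rule.

    p = (1 + #{null as or more extreme}) / (1 + n_perm); never exactly 0.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if tails == "two":
        count = np.sum(np.abs(null) >= abs(observed))
    elif tails == "upper":
        count = np.sum(null >= observed)
    elif tails == "lower":
        count = np.sum(null <= observed)
    else:
        raise ValueError("tails must be 'two', 'upper' or 'lower'")
    return float((1 + count) / (1 + null.size))


def fdr_correct(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def t_test(values_a: np.ndarray, values_b: np.ndarray):
    """Two-sample t-test per column of per-subject measure arrays."""
    a = np.atleast_2d(np.asarray(values_a, float))
    b = np.atleast_2d(np.asarray(values_b, float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("t-test needs at least 2 subjects per group")
    res = stats.ttest_ind(a, b, axis=0)
    return np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)


# ---------------------------------------------------------------------------
# fast structural permutation engine
# ---------------------------------------------------------------------------


def _edge_counts(grid: DensityGrid, n: int) -> np.ndarray:
    counts = np.array(
        [edge_count_for_density(d, n) for d in grid.densities], dtype=int
    )
    if np.any(counts == 0):
        raise ValueError("grid contains a density yielding zero edges")
    return counts


def _adjacency_stack(X: np.ndarray, edge_counts: np.ndarray) -> np.ndarray:
    """Threshold one group's data at every grid density.

    X is subjects x regions; returns n_densities x N x N uint8 adjacency
    stack.  Pair ranking is by descending signed correlation with
    lexicographic tie-break, identical to ``threshold_at_density``.
    """
    n = X.shape[1]
    R = np.corrcoef(X, rowvar=False)
    iu, ju = np.triu_indices(n, k=1)
    w = R[iu, ju]
    order = np.lexsort((ju, iu, -w))
    ii, jj = iu[order], ju[order]
    out = np.zeros((len(edge_counts), n, n), dtype=np.uint8)
    for d, ec in enumerate(edge_counts):
        A = out[d]
        A[ii[:ec], jj[:ec]] = 1
        A |= A.T
    return out


def metric_curves(
    data: RegionalDataTable, metric: str, grid: DensityGrid,
    seed: int | None = None,
) -> MetricCurve:
    """A group's global metric evaluated across the density grid."""
    fn = global_metric_function(metric, seed=seed)
    counts = _edge_counts(grid, data.n_regions)
    stack = _adjacency_stack(data.values, counts)
    y = np.array([fn(A.astype(float)) for A in stack])
    return MetricCurve(metric, grid.densities, y)


def permute_structural(
    data_a: RegionalDataTable,
    data_b: RegionalDataTable,
    metric: str,
    grid: DensityGrid,
    n_perm: int = DEFAULT_N_PERM_STRUCTURAL,
    tails: str = "two",
    seed: int | None = None,
    ci_level: float = 0.95,
) -> GroupComparison:
    """Permutation comparison of a global metric between two groups.

    Subjects are pooled and randomly reassigned to pseudo-groups of the
    original sizes each repetition; residualized data are reassigned as-is
    (the nuisance regression is not redone inside the loop).  Returns
    per-density p-values plus AUC and FDA summary tests and a percentile
    confidence band of the null differences.
    """
    if list(data_a.region_labels) != list(data_b.region_labels):
        raise ValueError("groups must share the same regions in the same order")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is small; p-value resolution is coarse",
            stacklevel=2,
        )
    fn = global_metric_function(metric, seed=seed)
    n = data_a.n_regions
    counts = _edge_counts(grid, n)
    na = data_a.n_subjects
    pooled = np.vstack([data_a.values, data_b.values])
    n_total = pooled.shape[0]
    x = grid.densities

    def group_curve(X):
        stack = _adjacency_stack(X, counts)
        return np.array([fn(A.astype(float)) for A in stack])

    curve_a = group_curve(data_a.values)
    curve_b = group_curve(data_b.values)
    observed = curve_a - curve_b
    obs_auc = auc(observed, densities=x)
    obs_fda = float(np.sum(observed))

    from .graph_construction import is_fragmented

    frag = [is_fragmented(A)[0]
            for X in (data_a.values, data_b.values)
            for A in _adjacency_stack(X, counts)]

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(x)))
    for r in range(n_perm):
        perm = rng.permutation(n_total)
        ya = group_curve(pooled[perm[:na]])
        yb = group_curve(pooled[perm[na:]])
        null[r] = ya - yb
    null_auc = np.trapezoid(null, x, axis=1)
    null_fda = null.sum(axis=1)

    p = np.array([pvalue_from_null(observed[d], null[:, d], tails)
                  for d in range(len(x))])
    lo = (1 - ci_level) / 2
    ci_low = np.quantile(null, lo, axis=0)
    ci_high = np.quantile(null, 1 - lo, axis=0)
    return GroupComparison(
        metric=metric, densities=x, observed=observed,
        observed_auc=obs_auc, observed_fda=obs_fda,
        null=null, null_auc=null_auc, null_fda=null_fda,
        p=p,
        p_auc=pvalue_from_null(obs_auc, null_auc, tails),
        p_fda=pvalue_from_null(obs_fda, null_fda, tails),
        ci_low=ci_low, ci_high=ci_high,
        n_perm=n_perm, tails=tails, ci_level=ci_level,
        curve_a=curve_a, curve_b=curve_b,
        fragmented_fraction=float(np.mean(frag)),
    )


def permute_functional(
    metrics_a: np.ndarray,
    metrics_b: np.ndarray,
    n_perm: int = DEFAULT_N_PERM_FUNCTIONAL,
    tails: str = "two",
    seed: int | None = None,
    densities: np.ndarray | None = None,
    metric: str = "metric",
    ci_level: float = 0.95,
) -> GroupComparison:
    """Permutation comparison of per-subject metric curves between groups.

    ``metrics_a``/``metrics_b`` are subjects x densities arrays of one
    measure per subject; reassignment shuffles whole subjects.  The observed
    difference is the difference of group means per density.
    """
    a = np.atleast_2d(np.asarray(metrics_a, float))
    b = np.atleast_2d(np.asarray(metrics_b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("metric arrays must share the density grid")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is small; p-value resolution is coarse",
            stacklevel=2,
        )
    x = (np.asarray(densities, float) if densities is not None
         else np.arange(a.shape[1], dtype=float))
    na = a.shape[0]
    pooled = np.vstack([a, b])
    observed = a.mean(axis=0) - b.mean(axis=0)
    obs_auc = float(np.trapezoid(observed, x))
    obs_fda = float(np.sum(observed))

    rng = np.random.default_rng(seed)
    n_total = pooled.shape[0]
    null = np.empty((n_perm, pooled.shape[1]))
    for r in range(n_perm):
        perm = rng.permutation(n_total)
        null[r] = pooled[perm[:na]].mean(axis=0) - pooled[perm[na:]].mean(axis=0)
    null_auc = np.trapezoid(null, x, axis=1)
    null_fda = null.sum(axis=1)
    p = np.array([pvalue_from_null(observed[d], null[:, d], tails)
                  for d in range(pooled.shape[1])])
    lo = (1 - ci_level) / 2
    return GroupComparison(
        metric=metric, densities=x, observed=observed,
        observed_auc=obs_auc, observed_fda=obs_fda,
        null=null, null_auc=null_auc, null_fda=null_fda,
        p=p,
        p_auc=pvalue_from_null(obs_auc, null_auc, tails),
        p_fda=pvalue_from_null(obs_fda, null_fda, tails),
        ci_low=np.quantile(null, lo, axis=0),
        ci_high=np.quantile(null, 1 - lo, axis=0),
        n_perm=n_perm, tails=tails, ci_level=ci_level,
        curve_a=a.mean(axis=0), curve_b=b.mean(axis=0),
    )


def regional_compare(
    data_a: RegionalDataTable,
    data_b: RegionalDataTable,
    metric: str,
    grid: DensityGrid,
    mode: str = "auc",
    n_perm: int = DEFAULT_N_PERM_STRUCTURAL,
    tails: str = "two",
    seed: int | None = None,
) -> RegionalComparison:
    """Per-region permutation comparison of a nodal measure.

    ``mode``: ``"at_dmin"`` compares the nodal values at the grid's first
    density (intended to be D_min); ``"auc"`` / ``"fda"`` compare the
    trapezoidal area / plain sum of each region's value-vs-density curve.
    Both uncorrected and FDR-adjusted p-values are reported (one test per
    region).
    """
    if list(data_a.region_labels) != list(data_b.region_labels):
        raise ValueError("groups must share the same regions in the same order")
    if mode not in ("at_dmin", "auc", "fda"):
        raise ValueError(f"unknown regional mode: {mode!r}")
    fn = nodal_metric_function(metric)
    n = data_a.n_regions
    x = grid.densities
    counts = _edge_counts(grid, n)

    def summary(X):
        if mode == "at_dmin":
            stack = _adjacency_stack(X, counts[:1])
            return fn(stack[0].astype(float))
        stack = _adjacency_stack(X, counts)
        vals = np.array([fn(A.astype(float)) for A in stack])  # dens x region
        if mode == "auc":
            return np.trapezoid(vals, x, axis=0)
        return vals.sum(axis=0)

    observed = summary(data_a.values) - summary(data_b.values)
    na = data_a.n_subjects
    pooled = np.vstack([data_a.values, data_b.values])
    n_total = pooled.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n))
    for r in range(n_perm):
        perm = rng.permutation(n_total)
        null[r] = summary(pooled[perm[:na]]) - summary(pooled[perm[na:]])
    p = np.array([pvalue_from_null(observed[i], null[:, i], tails)
                  for i in range(n)])
    return RegionalComparison(
        metric=metric, mode=mode,
        region_labels=list(data_a.region_labels),
        observed=observed, p=p, p_fdr=fdr_correct(p),
        n_perm=n_perm, tails=tails,
    )
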