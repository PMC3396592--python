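import numpy as np
import pytest
from scipy import stats

from braingraph import (
    DensityGrid,
    MetricCurve,
    SyntheticSpec,
    auc,
    fda_statistic,
    fdr_correct,
    generate_structural,
    metric_curves,
    permute_functional,
    permute_structural,
    pvalue_from_null,
    regional_compare,
    t_test,
)
from braingraph.roi_extract import RegionalDataTable


GRID = DensityGrid(0.3, 0.5, 0.05)


def null_pair(seed, **kw):
    spec = SyntheticSpec(n_regions=15, n_subjects_a=15, n_subjects_b=15,
                         seed=seed, **kw)
    return generate_structural(spec)


class TestAuc:
    def test_constant_curve_is_rectangle(self):
        x = np.round(np.arange(0.1, 0.501, 0.01), 10)
        curve = MetricCurve("m", x, np.full(len(x), 2.0))
        assert auc(curve) == pytest.approx(0.8)

    def test_linear_curve_exact(self):
        x = np.round(np.arange(0, 1.001, 0.01), 10)
        assert auc(MetricCurve("m", x, x.copy())) == pytest.approx(0.5)

    def test_matches_per_interval_oracle(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 1, size=17))
        y = rng.normal(size=17)
        expected = sum(
            (y[i] + y[i + 1]) / 2 * (x[i + 1] - x[i]) for i in range(16)
        )
        assert auc(MetricCurve("m", x, y)) == pytest.approx(expected)

    def test_subrange_needs_two_points(self):
        curve = MetricCurve("m", np.array([0.1, 0.2, 0.3]), np.ones(3))
        with pytest.raises(ValueError, match="2 grid points"):
            auc(curve, 0.25, 0.28)


class TestFda:
    def test_identical_curves_zero(self):
        x = np.array([0.1, 0.2, 0.3])
        c = MetricCurve("m", x, np.array([1.0, 2.0, 3.0]))
        assert fda_statistic(c, c) == 0.0

    def test_constant_offset_sums(self):
        x = np.round(np.arange(0.22, 0.451, 0.01), 10)
        a = MetricCurve("m", x, np.ones(len(x)) * 5)
        b = MetricCurve("m", x, np.ones(len(x)) * 4)
        assert fda_statistic(a, b) == pytest.approx(len(x))
        assert len(x) == 24

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(1)
        x = np.array([0.1, 0.2, 0.3, 0.4])
        a = MetricCurve("m", x, rng.normal(size=4))
        b = MetricCurve("m", x, rng.normal(size=4))
        assert fda_statistic(a, b) == -fda_statistic(b, a)

    def test_grid_mismatch_rejected(self):
        a = MetricCurve("m", np.array([0.1, 0.2]), np.zeros(2))
        b = MetricCurve("m", np.array([0.1, 0.3]), np.zeros(2))
        with pytest.raises(ValueError, match="grid"):
            fda_statistic(a, b)


class TestPvalue:
    def test_counting_rule(self):
        assert pvalue_from_null(5.0, np.zeros(1000), "upper") == \
            pytest.approx(1 / 1001)

    def test_center_of_symmetric_null(self):
        rng = np.random.default_rng(2)
        null = rng.normal(size=999)
        assert pvalue_from_null(0.0, null, "two") > 0.9
        med = float(np.median(null))
        assert pvalue_from_null(med, null, "upper") == pytest.approx(0.5, abs=0.05)

    def test_never_zero(self):
        assert pvalue_from_null(100.0, np.zeros(10), "two") == 1 / 11


class TestFdr:
    def test_hand_computed_step_up(self):
        # BH: p_(i) * m / i then enforce monotonicity from the largest down
        adj = fdr_correct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_cap(self):
        assert fdr_correct([0.2])[0] == pytest.approx(0.2)
        assert np.all(fdr_correct([1.0, 1.0, 1.0]) == 1.0)

    def test_matches_independent_step_up_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=9)
        order = np.argsort(p)
        m = len(p)
        adj_sorted = p[order] * m / np.arange(1, m + 1)
        adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj_sorted, 1.0)
        assert np.allclose(fdr_correct(p), expected)


class TestStructuralPermutation:
    def test_identical_groups_null_difference(self):
        a, _ = null_pair(0)
        b = RegionalDataTable(a.values.copy(), a.region_labels,
                              [f"b{i}" for i in range(a.n_subjects)], "B")
        cmp = permute_structural(a, b, "clustering", GRID, n_perm=100, seed=1)
        assert np.allclose(cmp.observed, 0.0)
        assert cmp.p_auc > 0.9 and cmp.p_fda > 0.9

    def test_label_swap_negates_observed(self):
        a, b = null_pair(1, attenuation_b=0.5)
        fwd = permute_structural(a, b, "clustering", GRID, n_perm=200, seed=2)
        rev = permute_structural(b, a, "clustering", GRID, n_perm=200, seed=2)
        assert np.allclose(fwd.observed, -rev.observed)
        assert fwd.observed_auc == pytest.approx(-rev.observed_auc)
        assert fwd.p_auc == pytest.approx(rev.p_auc, abs=0.1)

    def test_reproducible_bit_for_bit(self):
        a, b = null_pair(2)
        c1 = permute_structural(a, b, "clustering", GRID, n_perm=50, seed=9)
        c2 = permute_structural(a, b, "clustering", GRID, n_perm=50, seed=9)
        assert np.array_equal(c1.null, c2.null)
        assert c1.p_auc == c2.p_auc

    def test_confidence_band_covers_null(self):
        a, b = null_pair(3)
        cmp = permute_structural(a, b, "clustering", GRID, n_perm=400, seed=4)
        inside = ((cmp.null >= cmp.ci_low) & (cmp.null <= cmp.ci_high)).mean(axis=0)
        assert np.all(np.abs(inside - 0.95) < 0.03)

    def test_small_n_perm_warns(self):
        a, b = null_pair(4)
        with pytest.warns(UserWarning, match="n_perm"):
            permute_structural(a, b, "clustering", GRID, n_perm=50, seed=5)

    def test_observed_curves_match_metric_curves(self):
        a, b = null_pair(5)
        cmp = permute_structural(a, b, "clustering", GRID, n_perm=100, seed=6)
        assert np.allclose(cmp.curve_a, metric_curves(a, "clustering", GRID).y)
        assert np.allclose(cmp.observed, cmp.curve_a - cmp.curve_b)


class TestFunctionalPermutation:
    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            a = rng.normal(size=(10, 4))
            b = rng.normal(size=(10, 4))
            cmp = permute_functional(a, b, n_perm=200,
                                     seed=int(rng.integers(2**31)))
            ps.append(cmp.p_auc)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_for_two_sd_shift(self):
        rng = np.random.default_rng(1)
        rejections = 0
        for _ in range(50):
            a = rng.normal(size=(15, 4))
            b = rng.normal(size=(15, 4)) + 2.0
            cmp = permute_functional(a, b, n_perm=200,
                                     seed=int(rng.integers(2**31)))
            rejections += cmp.p_auc <= 0.05
        assert rejections / 50 > 0.9

    def test_t_test_null_uniform(self):
        rng = np.random.default_rng(2)
        ps = [t_test(rng.normal(size=(12, 1)), rng.normal(size=(12, 1)))[1][0]
              for _ in range(300)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_t_test_needs_two_subjects(self):
        with pytest.raises(ValueError, match="2 subjects"):
            t_test(np.ones((1, 3)), np.ones((5, 3)))


class TestRegionalComparison:
    def test_identical_groups_nothing_significant(self):
        a, _ = null_pair(6)
        b = RegionalDataTable(a.values.copy(), a.region_labels,
                              [f"b{i}" for i in range(a.n_subjects)], "B")
        res = regional_compare(a, b, "degree", GRID, mode="auc",
                               n_perm=100, seed=7)
        assert np.allclose(res.observed, 0.0)
        assert np.all(res.p > 0.9)
        assert np.all(res.p_fdr >= res.p)

    @pytest.mark.parametrize("seed", range(5))
    def test_perturbed_region_ranks_first(self, seed):
        # region 0 is extra-correlated with every other region in group A
        # only; with enough subjects its degree excess dominates the
        # thresholding noise and it ranks first by |difference|
        n = 12
        base = np.full((n, n), 0.3)
        np.fill_diagonal(base, 1.0)
        hot = base.copy()
        hot[0, 1:] = hot[1:, 0] = 0.58
        specs = [
            SyntheticSpec(n_regions=n, n_subjects_a=120, n_subjects_b=120,
                          topology="custom", custom_matrix=m, seed=seed + s)
            for s, m in ((0, hot), (100, base))
        ]
        a, _ = generate_structural(specs[0])
        _, b = generate_structural(specs[1])
        res = regional_compare(a, b, "degree", DensityGrid(0.2, 0.4, 0.05),
                               mode="auc", n_perm=60, seed=seed)
        assert int(np.argmax(np.abs(res.observed))) == 0

    def test_modes_share_interface(self):
        a, b = null_pair(8)
        for mode in ("at_dmin", "auc", "fda"):
            res = regional_compare(a, b, "degree", GRID, mode=mode,
                                   n_perm=60, seed=9)
            assert len(res.p) == a.n_regions
            assert np.all((res.p > 0) & (res.p <= 1))
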