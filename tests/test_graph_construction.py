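import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braingraph import (
    AssociationMatrix,
    DensityGrid,
    RegionalDataTable,
    association_matrix,
    find_dmin,
    is_fragmented,
    threshold_at_density,
    zscores_to_r,
)
from braingraph.graph_construction import edge_count_for_density, max_edges
from oracles import oracle_pearson

from conftest import graph_from_edges


def table(X):
    X = np.asarray(X, float)
    return RegionalDataTable(X, [f"r{i}" for i in range(X.shape[1])])


def symmetric_weights(n, rng):
    R = rng.uniform(-1, 1, size=(n, n))
    R = (R + R.T) / 2
    np.fill_diagonal(R, 0)
    return AssociationMatrix(R)


class TestAssociationMatrix:
    def test_identical_columns_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        data = table(np.column_stack([x, x, rng.normal(size=10)]))
        R = association_matrix(data)
        assert R.R[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(R.R), 0)

    def test_negated_column_anticorrelates(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        data = table(np.column_stack([x, -x, rng.normal(size=10)]))
        assert association_matrix(data).R[0, 1] == pytest.approx(-1.0)

    def test_matches_sum_of_products_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 4))
        R = association_matrix(table(X)).R
        for i, j in itertools.combinations(range(4), 2):
            expected = oracle_pearson(X[:, i].tolist(), X[:, j].tolist())
            assert R[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_region_named(self):
        X = np.random.default_rng(3).normal(size=(8, 3))
        X[:, 1] = 5.0
        with pytest.raises(ValueError, match="r1"):
            association_matrix(table(X))

    def test_partial_requires_more_subjects_than_regions(self):
        X = np.random.default_rng(4).normal(size=(4, 5))
        with pytest.raises(ValueError, match="partial"):
            association_matrix(table(X), method="partial")

    def test_partial_matches_regression_residual_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 4))
        R = association_matrix(table(X), method="partial").R
        # partial corr of (0, 1) given (2, 3): correlate OLS residuals
        design = np.column_stack([np.ones(60), X[:, 2:]])
        r0 = X[:, 0] - design @ np.linalg.lstsq(design, X[:, 0], rcond=None)[0]
        r1 = X[:, 1] - design @ np.linalg.lstsq(design, X[:, 1], rcond=None)[0]
        assert R[0, 1] == pytest.approx(np.corrcoef(r0, r1)[0, 1], abs=1e-10)


class TestThresholding:
    def test_full_density_is_complete_graph(self):
        R = symmetric_weights(4, np.random.default_rng(0))
        g = threshold_at_density(R, 1.0)
        assert g.n_edges == 6
        assert g.density == 1.0

    def test_keeps_exactly_the_largest_pairs(self):
        rng = np.random.default_rng(1)
        R = symmetric_weights(5, rng)
        g = threshold_at_density(R, 0.4)
        assert g.n_edges == 4
        iu, ju = np.triu_indices(5, 1)
        ranked = sorted(zip(R.R[iu, ju], iu, ju), reverse=True)
        expected = {(i, j) for _, i, j in ranked[:4]}
        got = {tuple(p) for p in zip(*np.nonzero(np.triu(g.A, 1)))}
        assert got == expected

    def test_all_equal_weights_resolved_by_tie_rule(self):
        n = 6
        R = AssociationMatrix(0.5 * (1 - np.eye(n)))
        g = threshold_at_density(R, 0.5)
        expected_edges = edge_count_for_density(0.5, n)
        assert g.n_edges == expected_edges
        # documented tie rule: ascending (i, j) lexicographic order
        iu, ju = np.triu_indices(n, 1)
        expected = set(list(zip(iu.tolist(), ju.tolist()))[:expected_edges])
        got = {tuple(p) for p in zip(*np.nonzero(np.triu(g.A, 1)))}
        assert got == expected

    def test_zero_edges_rejected(self):
        R = symmetric_weights(5, np.random.default_rng(2))
        with pytest.raises(ValueError, match="zero edges"):
            threshold_at_density(R, 0.01)

    @pytest.mark.parametrize("seed", range(5))
    def test_edge_sets_nested_across_grid(self, seed):
        R = symmetric_weights(12, np.random.default_rng(seed))
        grid = DensityGrid(0.1, 0.9, 0.1)
        prev = None
        for d in grid:
            g = threshold_at_density(R, d)
            edges = set(map(tuple, np.argwhere(np.triu(g.A, 1))))
            if prev is not None:
                assert prev <= edges
            prev = edges

    @given(st.integers(5, 25), st.floats(0.05, 1.0), st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_achieved_density_within_one_edge(self, n, d, seed):
        R = symmetric_weights(n, np.random.default_rng(seed))
        if edge_count_for_density(d, n) == 0:
            return
        g = threshold_at_density(R, d)
        assert abs(g.density - d) <= 1.0 / max_edges(n) + 1e-12


def scan_oracle_dmin(R, grid):
    """Independent oracle: sort all pairs, add top-E edges per grid density,
    check connectivity by BFS component enumeration."""
    from oracles import oracle_components

    n = R.shape[0]
    pairs = sorted(
        ((R[i, j], i, j) for i, j in itertools.combinations(range(n), 2)),
        reverse=True,
    )
    for d in grid:
        e = edge_count_for_density(d, n)
        if e == 0:
            continue
        A = np.zeros((n, n), dtype=int)
        for _, i, j in pairs[:e]:
            A[i, j] = A[j, i] = 1
        comps = oracle_components(A)
        if len(comps) == 1:
            return float(d)
    raise AssertionError("oracle found no connected density")


class TestFindDmin:
    def test_spanning_tree_in_top_three_edges(self):
        # top 3 of 6 weights form a spanning tree on 4 nodes: connectivity
        # needs E >= 3, first reached where round(d*6) = 3
        R = np.zeros((4, 4))
        R[0, 1], R[1, 2], R[2, 3] = 0.9, 0.8, 0.7     # the tree
        R[0, 2], R[0, 3], R[1, 3] = 0.3, 0.2, 0.1
        Rm = R + R.T
        grid = DensityGrid(0.01, 1.0, 0.01)
        expected = scan_oracle_dmin(Rm, grid)
        assert find_dmin(AssociationMatrix(Rm), grid) == pytest.approx(expected)
        assert edge_count_for_density(expected, 4) == 3

    def test_star_spanning_tree(self):
        n = 6
        R = np.zeros((n, n))
        for i in range(1, n):
            R[0, i] = 0.9 - 0.01 * i     # star edges strongest
        others = 0.3
        for i, j in itertools.combinations(range(1, n), 2):
            R[i, j] = others
            others -= 0.01
        Rm = R + R.T
        grid = DensityGrid(0.01, 1.0, 0.01)
        expected = scan_oracle_dmin(Rm, grid)
        assert find_dmin(AssociationMatrix(Rm), grid) == pytest.approx(expected)
        assert edge_count_for_density(expected, n) == n - 1

    def test_infeasible_grid_rejected(self):
        R = symmetric_weights(8, np.random.default_rng(0))
        with pytest.raises(ValueError, match="0.05"):
            find_dmin(R, DensityGrid(0.03, 0.05, 0.01))

    @pytest.mark.parametrize("seed", range(8))
    def test_result_is_minimal_on_grid(self, seed):
        R = symmetric_weights(15, np.random.default_rng(seed))
        grid = DensityGrid(0.02, 1.0, 0.02)
        dmin = find_dmin(R, grid)
        assert not is_fragmented(threshold_at_density(R, dmin))[0]
        below = dmin - grid.step
        if edge_count_for_density(below, 15) > 0:
            assert is_fragmented(threshold_at_density(R, below))[0]


class TestZscores:
    def test_zero_maps_to_zero_and_known_value(self):
        Z = np.zeros((1, 3, 3))
        Z[0, 0, 1] = Z[0, 1, 0] = np.arctanh(0.5)
        (mat,) = zscores_to_r(Z)
        assert mat.R[0, 1] == pytest.approx(0.5)
        assert mat.R[0, 2] == 0.0

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(-0.9, 0.9, size=(4, 4))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        (back,) = zscores_to_r(np.arctanh(r)[None])
        assert np.allclose(back.R, r, atol=1e-12)

    def test_nan_rejected_with_subject(self):
        Z = np.zeros((2, 3, 3))
        Z[1, 0, 1] = np.nan
        with pytest.raises(ValueError, match="subject index 1"):
            zscores_to_r(Z)


class TestFragmentation:
    def test_component_reporting(self):
        connected = graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        assert is_fragmented(connected) == (False, [4])
        split = graph_from_edges(4, [(0, 1), (2, 3)])
        assert is_fragmented(split) == (True, [2, 2])
        edgeless = graph_from_edges(3, [])
        assert is_fragmented(edgeless) == (True, [1, 1, 1])
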