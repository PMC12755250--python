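"""Standardization, correlation, clustering, PC aggregation and LMG."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dagclimb import (
    VariableTable,
    cluster_variables,
    correlation_matrix,
    lmg_importance,
    make_correlated_blocks,
    pca_aggregate,
    standardize,
)
from dagclimb.preprocess import ClusterAssignment, CorrelationMatrix

from conftest import standardized_from_array


class TestStandardize:
    def test_three_point_column_maps_to_unit_z_scores(self):
        table = VariableTable(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        z = standardize(table)
        np.testing.assert_allclose(z.column("x"), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_idempotent(self, gaussian_data):
        again = standardize(gaussian_data)
        np.testing.assert_allclose(
            again.frame.to_numpy(), gaussian_data.frame.to_numpy(), atol=1e-10
        )

    def test_constant_column_errors_naming_variable(self):
        table = VariableTable(pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0] * 3}))
        with pytest.raises(ValueError, match="zero variance.*flat"):
            standardize(table)

    def test_missing_values_rejected_at_construction(self):
        with pytest.raises(ValueError, match="missing"):
            VariableTable(pd.DataFrame({"x": [1.0, np.nan, 3.0]}))

    def test_roles_preserved(self):
        table = VariableTable(
            pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [3.0, 1.0, 2.0]}),
            {"y": "outcome"},
        )
        assert standardize(table).outcome == "y"

    def test_complete_case_filtering_at_ingest(self, tmp_path):
        path = tmp_path / "data.csv"
        path.write_text("a,b\n1,2\n3,\n5,6\n7,8\n")
        table = VariableTable.read_table(path)
        assert table.n == 3  # the incomplete row is dropped


class TestCorrelationMatrix:
    def test_unit_diagonal_and_negation(self):
        data = standardized_from_array(
            np.column_stack([[1.0, 2.0, 3.0, 5.0], [-1.0, -2.0, -3.0, -5.0]]),
            ["X", "Y"],
        )
        corr = correlation_matrix(data)
        assert corr["X", "X"] == pytest.approx(1.0)
        assert corr["X", "Y"] == pytest.approx(-1.0)

    def test_matches_explicit_pearson_oracle(self, toy_table):
        data = standardize(toy_table)
        corr = correlation_matrix(data)
        raw = toy_table.frame
        for a, b in itertools.combinations(raw.columns, 2):
            x, y = raw[a].to_numpy(), raw[b].to_numpy()
            n = len(x)
            sx = np.sqrt(((x - x.mean()) ** 2).sum() / (n - 1))
            sy = np.sqrt(((y - y.mean()) ** 2).sum() / (n - 1))
            oracle = ((x - x.mean()) * (y - y.mean())).sum() / ((n - 1) * sx * sy)
            assert corr[a, b] == pytest.approx(oracle, abs=1e-12)

    def test_validation_rejects_asymmetry(self):
        bad = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            CorrelationMatrix(bad)


def _corr_from(entries, names):
    return CorrelationMatrix(pd.DataFrame(entries, index=names, columns=names))


def _single_pass_merge_oracle(corr, threshold):
    """Brute-force average-linkage merging on 1 - |r| until cutoff."""
    names = corr.names
    clusters = [[n] for n in names]
    dist = 1.0 - np.abs(corr.values.to_numpy())

    def linkage(a, b):
        idx = {n: i for i, n in enumerate(names)}
        return np.mean([[dist[idx[x], idx[y]] for y in b] for x in a])

    while len(clusters) > 1:
        best = min(
            (
                (linkage(clusters[i], clusters[j]), i, j)
                for i in range(len(clusters))
                for j in range(i + 1, len(clusters))
            ),
            key=lambda t: t[0],
        )
        if best[0] > 1.0 - threshold:
            break
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}


class TestClusterVariables:
    def test_high_pair_merges_low_stays_singleton(self):
        corr = _corr_from(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]], ["A", "B", "C"]
        )
        result = cluster_variables(corr, 0.7)
        assert {frozenset(c) for c in result.clusters} == {
            frozenset({"A", "B"}),
            frozenset({"C"}),
        }

    def test_all_high_correlations_form_single_cluster(self):
        corr = _corr_from(np.full((3, 3), 0.95) + np.eye(3) * 0.05, ["A", "B", "C"])
        result = cluster_variables(corr, 0.7)
        assert len(result.clusters) == 1

    def test_two_blocks_recovered_and_match_merge_oracle(self):
        table = make_correlated_blocks((3, 3), 0.8, 0.1, 4000, seed=7)
        corr = correlation_matrix(standardize(table))
        result = cluster_variables(corr, 0.7)
        got = {frozenset(c) for c in result.clusters}
        assert got == _single_pass_merge_oracle(corr, 0.7)
        assert got == {
            frozenset({"B1V1", "B1V2", "B1V3"}),
            frozenset({"B2V1", "B2V2", "B2V3"}),
        }

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.5, 1.5])
    def test_threshold_outside_open_interval_rejected(self, threshold):
        corr = _corr_from(np.eye(2), ["A", "B"])
        with pytest.raises(ValueError):
            cluster_variables(corr, threshold)

    def test_threshold_near_one_gives_all_singletons(self, gaussian_data):
        corr = correlation_matrix(gaussian_data)
        result = cluster_variables(corr, 0.999999)
        assert all(len(c) == 1 for c in result.clusters)

    def test_partition_validation(self):
        with pytest.raises(ValueError, match="two clusters"):
            ClusterAssignment((("A",), ("A", "B")), 0.7)


class TestPcaAggregate:
    def test_singleton_passes_through(self, gaussian_data):
        clusters = ClusterAssignment((("X",),), 0.7)
        result = pca_aggregate(gaussian_data, clusters)
        np.testing.assert_allclose(
            result.factors["X"].to_numpy(), gaussian_data.column("X")
        )
        assert result.variance_explained["X"] == 1.0

    def test_two_variable_closed_form(self, rng):
        # For two z-scored variables the leading eigenvalue is 1 + |r|.
        table = make_correlated_blocks((2,), 0.832, 0.0, 500, seed=3)
        data = standardize(table)
        r = correlation_matrix(data)["B1V1", "B1V2"]
        clusters = ClusterAssignment((("B1V1", "B1V2"),), 0.7)
        result = pca_aggregate(data, clusters)
        assert result.variance_explained["F1"] == pytest.approx(
            (1 + abs(r)) / 2, abs=1e-9
        )

    def test_equicorrelated_block_matches_analytic_eigenvalue(self):
        # rho = 0.6 on 5 variables: leading eigenvalue (1 + 4*0.6) / 5 = 0.68.
        table = make_correlated_blocks((5,), 0.6, 0.0, 50_000, seed=11)
        data = standardize(table)
        clusters = ClusterAssignment((tuple(data.names),), 0.5)
        result = pca_aggregate(data, clusters)
        assert result.variance_explained["F1"] == pytest.approx(0.68, abs=0.01)

    def test_factor_mean_zero_and_sign_convention(self, rng):
        table = make_correlated_blocks((3,), 0.7, 0.0, 300, seed=5)
        data = standardize(table)
        clusters = ClusterAssignment((tuple(data.names),), 0.6)
        result = pca_aggregate(data, clusters)
        factor = result.factors["F1"].to_numpy()
        assert abs(factor.mean()) < 1e-10
        assert sum(result.loadings["F1"].values()) > 0
        # Flipping every variable's sign flips the factor deterministically.
        flipped = standardized_from_array(
            -data.frame.to_numpy(), data.names
        )
        result_f = pca_aggregate(flipped, clusters)
        np.testing.assert_allclose(
            result_f.factors["F1"].to_numpy(), -factor, atol=1e-10
        )

    def test_unknown_variable_rejected(self, gaussian_data):
        clusters = ClusterAssignment((("X", "nope"),), 0.7)
        with pytest.raises(ValueError, match="unknown"):
            pca_aggregate(gaussian_data, clusters)


class TestLmgImportance:
    def test_single_predictor_equals_simple_r2(self, rng):
        x = rng.standard_normal(100)
        y = 0.6 * x + rng.standard_normal(100)
        data = standardized_from_array(np.column_stack([x, y]), ["x", "y"])
        shares = lmg_importance(data, "y", ["x"])
        r2 = sm.OLS(data.column("y"), sm.add_constant(data.column("x"))).fit().rsquared
        assert shares["x"] == pytest.approx(r2, abs=1e-9)

    def test_brute_force_orderings_oracle(self, rng):
        # 20-row, 3 correlated predictors: compare against the explicit
        # average over all 6 orderings, each increment fitted with OLS.
        n, names = 20, ["a", "b", "c"]
        base = rng.standard_normal((n, 3)) @ np.array(
            [[1.0, 0.5, 0.3], [0.0, 1.0, 0.4], [0.0, 0.0, 1.0]]
        )
        y = base @ [0.5, -0.3, 0.2] + rng.standard_normal(n)
        data = standardized_from_array(np.column_stack([base, y]), names + ["y"])

        def r2(subset):
            if not subset:
                return 0.0
            X = sm.add_constant(data.frame[list(subset)].to_numpy())
            return sm.OLS(data.column("y"), X).fit().rsquared

        oracle = {name: 0.0 for name in names}
        orderings = list(itertools.permutations(names))
        for order in orderings:
            for pos, name in enumerate(order):
                oracle[name] += (r2(order[: pos + 1]) - r2(order[:pos])) / len(orderings)

        shares = lmg_importance(data, "y", names)
        for name in names:
            assert shares[name] == pytest.approx(oracle[name], abs=1e-9)
        assert sum(shares.values()) == pytest.approx(r2(tuple(names)), abs=1e-9)

    def test_orthogonal_predictors_get_squared_correlations(self):
        # Exactly orthogonal design: shares reduce to marginal r^2.
        n = 8
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        y = 0.8 * a + 0.3 * b
        data = standardized_from_array(np.column_stack([a, b, y]), ["a", "b", "y"])
        shares = lmg_importance(data, "y", ["a", "b"])
        for name in ("a", "b"):
            r = np.corrcoef(data.column(name), data.column("y"))[0, 1]
            assert shares[name] == pytest.approx(r**2, abs=1e-9)

    def test_too_many_predictors_rejected(self, rng):
        frame = pd.DataFrame(
            rng.standard_normal((30, 14)), columns=[f"v{i}" for i in range(14)]
        )
        data = standardize(VariableTable(frame))
        with pytest.raises(ValueError, match="at most"):
            lmg_importance(data, "v0", [f"v{i}" for i in range(1, 14)])

    def test_outcome_among_predictors_rejected(self, gaussian_data):
        with pytest.raises(ValueError, match="outcome"):
            lmg_importance(gaussian_data, "X", ["X", "Y"])
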