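import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import betaimpute as bi
from betaimpute.core import (
    ImputationConfig,
    UnimputableGroupError,
    build_regression_system,
    find_missingness_groups,
    impute_group,
    impute_matrix,
    inverse_logit,
    logit_transform,
    min_norm_least_squares,
)


class TestLogitPair:
    def test_symmetry_point(self):
        assert logit_transform(0.5) == 0.0
        assert inverse_logit(0.0) == 0.5

    def test_boundary_is_clamped(self):
        eps = 1e-6
        expected = math.log(eps / (1.0 - eps))
        assert logit_transform(0.0, eps) == pytest.approx(expected, rel=1e-12)
        # antisymmetric up to the rounding of 1 - (1 - eps)
        assert logit_transform(1.0, eps) == pytest.approx(-expected, rel=1e-9)

    def test_known_value(self):
        # log(0.73/0.27) = 0.99462257514406205... (30-digit arithmetic)
        assert logit_transform(0.73) == pytest.approx(0.9946225751440621, abs=1e-12)
        assert inverse_logit(0.9946225751440621) == pytest.approx(0.73, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            logit_transform(1.2)
        with pytest.raises(ValueError):
            logit_transform(-0.1)

    def test_asymptotes(self):
        assert inverse_logit(800.0) == pytest.approx(1.0)
        assert inverse_logit(-800.0) == pytest.approx(0.0)
        assert 0.0 < inverse_logit(-800.0) or inverse_logit(-800.0) == 0.0

    @given(st.floats(min_value=1e-6, max_value=1.0 - 1e-6))
    def test_round_trip_identity(self, p):
        q = logit_transform(p, eps=1e-6)
        assert inverse_logit(q) == pytest.approx(p, rel=1e-12, abs=1e-12)

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_monotone(self, a, b):
        if a < b:
            assert logit_transform(a) <= logit_transform(b)


class TestFindMissingnessGroups:
    def test_groups_by_shared_pattern(self):
        values = np.full((3, 4), 0.5)
        values[1, 0] = np.nan  # col0 missing at row 1
        values[1, 1] = np.nan  # col1 missing at row 1 -> same group
        values[1, 2] = np.nan
        values[2, 2] = np.nan  # col2 missing at rows {1,2} -> own group
        X = bi.BetaMatrix(values, ["a", "b", "c"], ["w", "x", "y", "z"])
        groups = find_missingness_groups(X)
        assert len(groups) == 2
        assert groups[0].na_rows == (1,) and groups[0].na_cols == (0, 1)
        assert groups[1].na_rows == (1, 2) and groups[1].na_cols == (2,)

    def test_complete_matrix_has_no_groups(self):
        X = bi.BetaMatrix(np.full((3, 3), 0.4), list("abc"), list("xyz"))
        assert find_missingness_groups(X) == []

    def test_distinct_single_row_patterns_stay_singletons(self):
        n, m = 6, 5
        values = np.full((n, m), 0.5)
        for j in range(m):
            values[j, j] = np.nan
        X = bi.BetaMatrix(values, [f"s{i}" for i in range(n)], [f"c{j}" for j in range(m)])
        groups = find_missingness_groups(X)
        assert len(groups) == 5
        assert [g.na_cols for g in groups] == [(j,) for j in range(m)]
        assert [g.na_rows for g in groups] == [(j,) for j in range(m)]

    @given(st.integers(min_value=0, max_value=2**20 - 1))
    def test_partition_property(self, bits):
        # random 4x5 mask from the integer's bits: groups must partition the
        # set of columns containing at least one NA, with disjoint na_cols
        mask = np.array([[bool(bits >> (i * 5 + j) & 1) for j in range(5)] for i in range(4)])
        mask[:, mask.all(axis=0)] = False  # keep every column partly observed
        values = np.where(mask, np.nan, 0.5)
        X = bi.BetaMatrix(values, [f"s{i}" for i in range(4)], [f"c{j}" for j in range(5)])
        groups = find_missingness_groups(X)
        covered = [j for g in groups for j in g.na_cols]
        assert sorted(covered) == sorted(set(covered))
        assert set(covered) == set(np.flatnonzero(mask.any(axis=0)).tolist())
        for g in groups:
            sub = mask[:, list(g.na_cols)]
            assert np.all(sub[list(g.na_rows), :])
            assert not sub[np.setdiff1d(np.arange(4), g.na_rows), :].any()


class TestBuildRegressionSystem:
    def test_block_dimensions(self):
        values = np.random.default_rng(0).uniform(0.2, 0.8, size=(4, 5))
        values[3, 4] = np.nan
        X = bi.BetaMatrix(values, [f"s{i}" for i in range(4)], [f"c{j}" for j in range(5)])
        (group,) = find_missingness_groups(X)
        sys = build_regression_system(X, group)
        assert sys.A.shape == (3, 4)
        assert sys.B.shape == (3, 1)
        assert sys.C.shape == (1, 4)
        assert not np.isnan(sys.A).any() and not np.isnan(sys.B).any()

    def test_no_complete_predictor_is_unimputable(self):
        values = np.full((3, 2), 0.5)
        values[0, 0] = np.nan
        values[1, 1] = np.nan
        X = bi.BetaMatrix(values, list("abc"), list("xy"))
        for group in find_missingness_groups(X):
            with pytest.raises(UnimputableGroupError, match="m-L = 0"):
                build_regression_system(X, group)

    def test_predictor_set_is_group_independent(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0.1, 0.9, size=(5, 6))
        values[0, 0] = np.nan
        values[2, 1] = np.nan
        X = bi.BetaMatrix(values, [f"s{i}" for i in range(5)], [f"c{j}" for j in range(6)])
        systems = [build_regression_system(X, g) for g in find_missingness_groups(X)]
        assert len(systems) == 2
        assert systems[0].predictor_cols == systems[1].predictor_cols == tuple(range(2, 6))


class TestMinNormLeastSquares:
    def test_identity_system(self):
        Y = np.random.default_rng(2).normal(size=(4, 3))
        x = min_norm_least_squares(np.eye(4), Y)
        assert np.allclose(x, Y, atol=1e-12)

    def test_overdetermined_consistent_recovery(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(3, 2))
        x_true = rng.normal(size=(2, 4))
        x = min_norm_least_squares(M, M @ x_true)
        assert np.allclose(x, x_true, atol=1e-10)

    def test_underdetermined_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(2, 5))
        Y = rng.normal(size=(2, 3))
        oracle = M.T @ np.linalg.solve(M @ M.T, Y)
        x = min_norm_least_squares(M, Y)
        assert np.allclose(x, oracle, atol=1e-10)

    @pytest.mark.parametrize("shape", [(3, 3), (6, 2), (2, 6), (8, 5), (4, 8)])
    def test_matches_full_svd_pseudoinverse(self, shape):
        rng = np.random.default_rng(sum(shape))
        M = rng.normal(size=shape)
        Y = rng.normal(size=(shape[0], 3))
        assert np.allclose(
            min_norm_least_squares(M, Y), np.linalg.pinv(M) @ Y, atol=1e-10
        )

    @pytest.mark.parametrize("shape", [(3, 50), (50, 3)])
    def test_gram_side_path_agrees_with_pinv(self, shape):
        # strongly rectangular systems take the Gram-matrix SVD path
        rng = np.random.default_rng(7)
        M = rng.normal(size=shape)
        Y = rng.normal(size=(shape[0], 2))
        assert np.allclose(
            min_norm_least_squares(M, Y), np.linalg.pinv(M) @ Y, atol=1e-9
        )

    def test_rank_deficient_min_norm(self):
        # duplicate column: pinv solution splits the coefficient evenly
        M = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        Y = np.array([[2.0], [4.0], [6.0]])
        x = min_norm_least_squares(M, Y)
        assert np.allclose(x, [[1.0], [1.0]], atol=1e-10)

    def test_zero_matrix_gives_zero_solution(self):
        x = min_norm_least_squares(np.zeros((3, 4)), np.ones((3, 2)))
        assert np.array_equal(x, np.zeros((4, 2)))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="row mismatch"):
            min_norm_least_squares(np.ones((3, 2)), np.ones((4, 1)))


class TestImputeGroup:
    def test_exact_recovery_on_noiseless_logit_linear_data(self):
        from conftest import exact_logit_linear_matrix

        X0 = exact_logit_linear_matrix(20, 50, rank=2, seed=5)
        values = X0.values.copy()
        truth = values[7, 30]
        values[7, 30] = np.nan
        X = bi.BetaMatrix(values, X0.sample_ids, X0.probe_ids)
        (group,) = find_missingness_groups(X)
        imp = impute_group(X, group)
        assert imp.shape == (1, 1)
        assert imp[0, 0] == pytest.approx(truth, abs=1e-8)

    def test_constant_matrix_reproduces_constant(self):
        values = np.full((6, 5), 0.6)
        values[2, 4] = np.nan
        X = bi.BetaMatrix(values, [f"s{i}" for i in range(6)], [f"c{j}" for j in range(5)])
        (group,) = find_missingness_groups(X)
        imp = impute_group(X, group)
        assert imp[0, 0] == pytest.approx(0.6, abs=1e-8)

    def test_imputed_values_strictly_inside_unit_interval(self, masked_fixture):
        imputed, report = impute_matrix(masked_fixture.observed)
        filled = imputed.values[tuple(zip(*masked_fixture.artificial_mask))]
        assert np.all(filled > 0.0) and np.all(filled < 1.0)

    def test_skip_logit_identity_transform(self):
        # on raw scale a perfectly linear relation is recovered directly
        rng = np.random.default_rng(6)
        base = rng.uniform(0.2, 0.8, size=(10, 3))
        target = 0.25 * base[:, 0] + 0.5 * base[:, 1] + 0.25 * base[:, 2]
        values = np.column_stack([base, target])
        truth = values[4, 3]
        values[4, 3] = np.nan
        X = bi.BetaMatrix(values, [f"s{i}" for i in range(10)], list("wxyz"))
        (group,) = find_missingness_groups(X)
        imp = impute_group(X, group, ImputationConfig(skip_logit=True))
        assert imp[0, 0] == pytest.approx(truth, abs=1e-10)


class TestImputeMatrix:
    def test_no_missing_is_identity(self):
        X = bi.BetaMatrix(np.full((3, 4), 0.3), list("abc"), list("wxyz"))
        out, report = impute_matrix(X)
        assert out.equals(X)
        assert report.n_groups == 0

    def test_observed_entries_bit_identical(self, masked_fixture):
        observed = masked_fixture.observed
        out, _ = impute_matrix(observed)
        keep = ~observed.missing_mask()
        assert np.array_equal(out.values[keep], observed.values[keep])

    def test_column_missing_everywhere_left_missing_and_reported(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0.2, 0.8, size=(4, 5))
        values[:, 2] = np.nan
        X = bi.BetaMatrix(values, [f"s{i}" for i in range(4)], [f"c{j}" for j in range(5)])
        out, report = impute_matrix(X)
        assert np.isnan(out.values[:, 2]).all()
        assert 2 in report.unimputable_cols
        assert report.n_unimputable_groups == 1

    def test_fills_all_entries_on_synthetic_fixture(self, masked_fixture):
        out, report = impute_matrix(masked_fixture.observed)
        assert out.n_missing == 0
        assert report.n_imputed_entries == masked_fixture.n_masked

    def test_row_permutation_equivariance(self, masked_fixture):
        X = masked_fixture.observed
        perm = np.random.default_rng(9).permutation(X.n_samples)
        Xp = X.select_samples(perm)
        out, _ = impute_matrix(X)
        out_p, _ = impute_matrix(Xp)
        assert np.allclose(
            out_p.values, out.values[perm, :], atol=1e-10, equal_nan=True
        )

    def test_complete_column_permutation_invariance(self, masked_fixture):
        X = masked_fixture.observed
        mask_cols = set(np.flatnonzero(X.missing_mask().any(axis=0)).tolist())
        complete_cols = [j for j in range(X.n_probes) if j not in mask_cols]
        rng = np.random.default_rng(10)
        shuffled = list(complete_cols)
        rng.shuffle(shuffled)
        order = list(range(X.n_probes))
        for a, b in zip(complete_cols, shuffled):
            order[a] = b
        Xp = X.select_probes(order)
        out, _ = impute_matrix(X)
        out_p, _ = impute_matrix(Xp)
        for j in mask_cols:
            col_p = Xp.probe_ids.index(X.probe_ids[j])
            assert np.allclose(
                out_p.values[:, col_p], out.values[:, j], atol=1e-10, equal_nan=True
            )
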