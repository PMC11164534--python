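"""SCM baseline: Kronecker design, ridge fit, discrepancy-score comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biconn.containers import CellFeatureMatrix, ConnectivityMatrix
from biconn.scm import (
    EdgeList,
    RuleMatrix,
    build_kronecker_design,
    compare_rule_matrices,
    discrepancy_score,
    fit_scm_ridge,
    flag_divergent_entries,
    predict_scm,
)


def _edges_all_pairs(Z):
    return EdgeList.from_matrices(Z, np.ones_like(Z.values), symmetric=True)


class TestKroneckerDesign:
    def test_basis_vector_symmetric_row(self):
        X = CellFeatureMatrix(np.eye(2), cell_ids=["a", "b"])
        edges = EdgeList(["a"], ["b"], np.array([1.0]), np.array([True]))
        design, _ = build_kronecker_design(X, edges, symmetric=True)
        np.testing.assert_allclose(design[0], [0.0, 0.5, 0.5, 0.0])

    def test_all_ones_row(self):
        X = CellFeatureMatrix(np.ones((1, 2)), cell_ids=["a"])
        edges = EdgeList(["a"], ["a"], np.array([1.0]), np.array([True]))
        design, _ = build_kronecker_design(X, edges)
        np.testing.assert_allclose(design[0], np.ones(4))

    def test_design_reproduces_quadratic_form(self, rng):
        X = CellFeatureMatrix(rng.standard_normal((5, 3)))
        O = rng.standard_normal((3, 3))
        O = 0.5 * (O + O.T)
        Z = ConnectivityMatrix(X.values @ O @ X.values.T,
                               pre_ids=X.cell_ids, post_ids=X.cell_ids)
        edges = _edges_all_pairs(Z)
        design, targets = build_kronecker_design(X, edges)
        # loop-computed xᵢ O xⱼᵀ for every edge
        preds = design @ O.ravel()
        np.testing.assert_allclose(preds, targets, atol=1e-12)

    def test_unknown_cell_id_raises(self, rng):
        X = CellFeatureMatrix(rng.standard_normal((2, 2)), cell_ids=["a", "b"])
        edges = EdgeList(["a"], ["zzz"], np.array([1.0]), np.array([True]))
        with pytest.raises(KeyError, match="zzz"):
            build_kronecker_design(X, edges)


class TestRidgeFit:
    def test_consistent_system_recovers_rule(self, rng):
        X = CellFeatureMatrix(rng.standard_normal((10, 3)))
        O_star = rng.standard_normal((3, 3))
        O_star = 0.5 * (O_star + O_star.T)
        Z = ConnectivityMatrix(X.values @ O_star @ X.values.T,
                               pre_ids=X.cell_ids, post_ids=X.cell_ids)
        design, targets = build_kronecker_design(X, _edges_all_pairs(Z))
        O = fit_scm_ridge(design, targets, lam=1e-10)
        assert np.linalg.norm(O.values - O_star) / np.linalg.norm(O_star) < 1e-6

    def test_huge_lambda_shrinks_to_zero(self, rng):
        X = CellFeatureMatrix(rng.standard_normal((6, 2)))
        Z = ConnectivityMatrix(rng.standard_normal((6, 6)),
                               pre_ids=X.cell_ids, post_ids=X.cell_ids)
        design, targets = build_kronecker_design(X, _edges_all_pairs(Z))
        O = fit_scm_ridge(design, targets, lam=1e12)
        assert np.abs(O.values).max() < 1e-6

    def test_matches_augmented_least_squares(self, rng):
        X = CellFeatureMatrix(rng.standard_normal((7, 3)))
        Z = ConnectivityMatrix(rng.standard_normal((7, 7)),
                               pre_ids=X.cell_ids, post_ids=X.cell_ids)
        design, targets = build_kronecker_design(X, _edges_all_pairs(Z))
        lam = 0.3
        O = fit_scm_ridge(design, targets, lam=lam, symmetric=False)
        # oracle: stack sqrt(lam) I below the design, zeros below targets
        aug_D = np.vstack([design, np.sqrt(lam) * np.eye(9)])
        aug_t = np.concatenate([targets, np.zeros(9)])
        vec, *_ = np.linalg.lstsq(aug_D, aug_t, rcond=None)
        np.testing.assert_allclose(O.values.ravel(), vec, atol=1e-8)

    def test_singular_at_zero_lambda_raises(self):
        # two identical cells: rank-deficient design
        X = CellFeatureMatrix(np.ones((2, 2)))
        Z = ConnectivityMatrix(np.ones((2, 2)), pre_ids=X.cell_ids,
                               post_ids=X.cell_ids)
        design, targets = build_kronecker_design(X, _edges_all_pairs(Z))
        with pytest.raises(np.linalg.LinAlgError, match="lambda > 0"):
            fit_scm_ridge(design, targets, lam=0.0)

    def test_ridge_norm_nonincreasing_in_lambda(self, rng):
        X = CellFeatureMatrix(rng.standard_normal((8, 3)))
        Z = ConnectivityMatrix(rng.standard_normal((8, 8)),
                               pre_ids=X.cell_ids, post_ids=X.cell_ids)
        design, targets = build_kronecker_design(X, _edges_all_pairs(Z))
        norms = [np.linalg.norm(fit_scm_ridge(design, targets, lam).values)
                 for lam in (1e-6, 1e-3, 1, 1e3)]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))


class TestPredictSCM:
    def test_identity_rule_gives_gram_matrix(self, rng):
        X = CellFeatureMatrix(rng.standard_normal((4, 3)))
        O = RuleMatrix(np.eye(3))
        pred = predict_scm(X, O)
        np.testing.assert_allclose(pred.values, X.values @ X.values.T)

    def test_zero_rule_gives_zero(self, rng):
        X = CellFeatureMatrix(rng.standard_normal((4, 3)))
        assert np.all(predict_scm(X, RuleMatrix(np.zeros((3, 3)))).values == 0)

    def test_factored_rule_equals_bilinear_prediction(self, rng):
        from biconn.containers import BilinearFactors
        from biconn.model import predict_connectivity, rule_product

        X = CellFeatureMatrix(rng.standard_normal((5, 3)))
        F = BilinearFactors(rng.standard_normal((3, 2)), rng.standard_normal((3, 2)))
        O = RuleMatrix(rule_product(F))
        np.testing.assert_allclose(predict_scm(X, O).values,
                                   predict_connectivity(X, X, F).values,
                                   atol=1e-12)


class TestDiscrepancyScore:
    @pytest.mark.parametrize("o_hat,o,expected", [
        (1.0, 1.0, 0.0),
        (1.0, -1.0, 1.0),
        (0.3, 0.1, 0.5),
        (0.0, 0.0, 0.0),
    ])
    def test_reference_values(self, o_hat, o, expected):
        assert discrepancy_score(o_hat, o) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(x=st.floats(1e-3, 10).flatmap(lambda v: st.sampled_from([v, -v])),
           y=st.floats(1e-3, 10).flatmap(lambda v: st.sampled_from([v, -v])),
           c=st.floats(0.01, 100))
    def test_symmetric_scale_invariant_bounded(self, x, y, c):
        ds = discrepancy_score(x, y)
        assert 0.0 <= ds <= 1.0
        assert ds == pytest.approx(discrepancy_score(y, x))
        assert ds == pytest.approx(discrepancy_score(c * x, c * y), abs=1e-9)


class TestFlagging:
    def test_floor_filters_small_pairs(self):
        O_hat = RuleMatrix(np.array([[0.05]]))
        O = RuleMatrix(np.array([[0.01]]))
        report = flag_divergent_entries(O_hat, O)
        assert report.ds_values[0, 0] == pytest.approx(2 / 3)
        assert not report.flagged[0, 0]

    def test_equal_entries_not_flagged(self):
        O = RuleMatrix(np.array([[0.5]]))
        assert not flag_divergent_entries(O, O).flagged[0, 0]

    def test_large_discrepant_entry_flagged(self):
        O_hat = RuleMatrix(np.array([[0.5]]))
        O = RuleMatrix(np.array([[0.05]]))
        report = flag_divergent_entries(O_hat, O)
        assert report.ds_values[0, 0] == pytest.approx(0.45 / 0.55)
        assert report.flagged[0, 0]


class TestCompareRuleMatrices:
    def test_identical_matrices_correlate_perfectly(self, rng):
        O = RuleMatrix(rng.standard_normal((3, 3)))
        r, _ = compare_rule_matrices(O, O)
        assert r == pytest.approx(1.0)

    def test_negated_matrix_anticorrelates(self, rng):
        O = RuleMatrix(rng.standard_normal((3, 3)))
        r, _ = compare_rule_matrices(RuleMatrix(-O.values), O)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self, rng):
        A = rng.standard_normal((4, 4))
        B = rng.standard_normal((4, 4))
        r, _ = compare_rule_matrices(RuleMatrix(A), RuleMatrix(B))
        a, b = A.ravel(), B.ravel()
        expected = (((a - a.mean()) * (b - b.mean())).mean()
                    / (a.std() * b.std()))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_matrix_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            compare_rule_matrices(RuleMatrix(np.ones((2, 2))),
                                  RuleMatrix(np.eye(2)))


class TestScmLambdaCV:
    def test_low_noise_prefers_small_lambda(self, rng):
        X = CellFeatureMatrix(rng.standard_normal((10, 3)))
        O_star = rng.standard_normal((3, 3))
        O_star = 0.5 * (O_star + O_star.T)
        Z = ConnectivityMatrix(X.values @ O_star @ X.values.T
                               + 0.01 * rng.standard_normal((10, 10)),
                               pre_ids=X.cell_ids, post_ids=X.cell_ids)
        design, targets = build_kronecker_design(X, _edges_all_pairs(Z))
        from biconn.scm import cv_scm_lambda
        best, mse = cv_scm_lambda(design, targets, [1e-4, 1e4], k=5, seed=0)
        assert best == 1e-4
        assert mse[0] < mse[1]

    def test_fold_selection_deterministic_in_seed(self, rng):
        X = CellFeatureMatrix(rng.standard_normal((8, 2)))
        Z = ConnectivityMatrix(rng.standard_normal((8, 8)),
                               pre_ids=X.cell_ids, post_ids=X.cell_ids)
        design, targets = build_kronecker_design(X, _edges_all_pairs(Z))
        from biconn.scm import cv_scm_lambda
        b1, m1 = cv_scm_lambda(design, targets, [0.1, 1, 10], k=3, seed=5)
        b2, m2 = cv_scm_lambda(design, targets, [0.1, 1, 10], k=3, seed=5)
        assert b1 == b2
        np.testing.assert_array_equal(m1, m2)
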