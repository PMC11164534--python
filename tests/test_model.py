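"""Core bilinear model: losses, gradients, AGD fitting, prediction."""

import numpy as np
import pytest

from biconn.containers import (
    BilinearFactors,
    CellFeatureMatrix,
    ConnectivityMatrix,
    DimensionError,
    FitConfig,
    TypeFeatureMatrix,
    WeightMatrix,
)
from biconn.model import (
    ConvergenceError,
    fit_agd,
    grad_cellwise,
    grad_typewise,
    loss_cellwise,
    loss_typewise,
    predict_connectivity,
    rule_product,
)
from biconn.simulate import SyntheticScenario, generate_bilinear_instance
from biconn.workflows import gradient_fd_error


def _loss_cellwise_bruteforce(X, Y, Z, W, A, B, lamA, lamB):
    """Independent elementwise double sum of the weighted objective."""
    total = 0.0
    for i in range(X.shape[0]):
        for j in range(Y.shape[0]):
            pred = float((X[i] @ A) @ (Y[j] @ B))
            total += W[i, j] * (Z[i, j] - pred) ** 2
    total += 0.5 * lamA * (A ** 2).sum() + 0.5 * lamB * (B ** 2).sum()
    return total


def _loss_typewise_bruteforce(Xh, Yh, Zb, A, B, lamA, lamB):
    total = 0.0
    for i in range(Xh.shape[0]):
        for j in range(Yh.shape[0]):
            pred = float((Xh[i] @ A) @ (Yh[j] @ B))
            total += (Zb[i, j] - pred) ** 2
    GA = A.T @ A
    GB = B.T @ B
    return total + 0.5 * lamA * (GA ** 2).sum() + 0.5 * lamB * (GB ** 2).sum()


class TestLossCellwise:
    def test_exactly_representable_gives_zero(self, rng):
        X = CellFeatureMatrix(rng.standard_normal((5, 3)))
        Y = CellFeatureMatrix(rng.standard_normal((4, 3)))
        F = BilinearFactors(rng.standard_normal((3, 2)), rng.standard_normal((3, 2)))
        Z = ConnectivityMatrix((X.values @ F.A) @ (Y.values @ F.B).T)
        W = WeightMatrix(np.ones((5, 4)))
        assert loss_cellwise(X, Y, Z, W, F) == pytest.approx(0.0, abs=1e-20)

    def test_scalar_case_with_penalties(self):
        X = CellFeatureMatrix([[1.0]])
        Y = CellFeatureMatrix([[1.0]])
        Z = ConnectivityMatrix([[0.0]])
        W = WeightMatrix([[1.0]])
        F = BilinearFactors([[1.0]], [[1.0]])
        # (0 - 1)^2 + (2/2)*1 + (2/2)*1 = 3
        assert loss_cellwise(X, Y, Z, W, F, 2.0, 2.0) == pytest.approx(3.0)

    def test_matches_elementwise_bruteforce(self, small_cellwise):
        X, Y, Z, W, F = small_cellwise
        expected = _loss_cellwise_bruteforce(
            X.values, Y.values, Z.values, W.values, F.A, F.B, 0.7, 1.3)
        assert loss_cellwise(X, Y, Z, W, F, 0.7, 1.3) == pytest.approx(
            expected, abs=1e-10)

    def test_shape_mismatch_names_axes(self, small_cellwise):
        X, Y, Z, W, F = small_cellwise
        bad_Z = ConnectivityMatrix(np.zeros((2, 2)))
        with pytest.raises(DimensionError, match="cells"):
            loss_cellwise(X, Y, bad_Z, W, F)

    def test_zero_weight_entries_have_no_influence(self, small_cellwise):
        X, Y, Z, W, F = small_cellwise
        Wv = W.values.copy()
        Wv[0, 0] = 0.0
        W0 = WeightMatrix(Wv)
        base_loss = loss_cellwise(X, Y, Z, W0, F, 0.5, 0.5)
        base_grads = grad_cellwise(X, Y, Z, W0, F, 0.5, 0.5)
        Zp = Z.values.copy()
        Zp[0, 0] = 1e6
        Z_perturbed = ConnectivityMatrix(Zp)
        assert loss_cellwise(X, Y, Z_perturbed, W0, F, 0.5, 0.5) == base_loss
        for g, g0 in zip(grad_cellwise(X, Y, Z_perturbed, W0, F, 0.5, 0.5),
                         base_grads):
            np.testing.assert_array_equal(g, g0)


class TestGradCellwise:
    def test_zero_factors_give_zero_gradient(self, small_cellwise):
        X, Y, Z, W, _ = small_cellwise
        F0 = BilinearFactors(np.zeros((3, 2)), np.zeros((2, 2)))
        gA, gB = grad_cellwise(X, Y, Z, W, F0, 1.0, 1.0)
        np.testing.assert_array_equal(gA, 0)
        np.testing.assert_array_equal(gB, 0)

    def test_scalar_case_by_hand(self):
        X = CellFeatureMatrix([[1.0]])
        Y = CellFeatureMatrix([[1.0]])
        Z = ConnectivityMatrix([[0.0]])
        W = WeightMatrix([[1.0]])
        F = BilinearFactors([[1.0]], [[1.0]])
        gA, gB = grad_cellwise(X, Y, Z, W, F, 2.0, 2.0)
        # 2*1*(1-0)*1*1 + 2*1 = 4
        assert gA[0, 0] == pytest.approx(4.0)
        assert gB[0, 0] == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_finite_differences(self, seed):
        assert gradient_fd_error(seed, "cellwise") < 1e-5


class TestLossTypewise:
    def test_exactly_bilinear_gives_zero(self, rng):
        Xh = TypeFeatureMatrix(rng.standard_normal((4, 3)))
        Yh = TypeFeatureMatrix(rng.standard_normal((3, 3)))
        F = BilinearFactors(rng.standard_normal((3, 2)), rng.standard_normal((3, 2)))
        Zb = ConnectivityMatrix((Xh.values @ F.A) @ (Yh.values @ F.B).T)
        assert loss_typewise(Xh, Yh, Zb, F) == pytest.approx(0.0, abs=1e-20)

    def test_orthonormal_columns_penalty_is_d(self):
        # data term zero, A with orthonormal columns: penalty (2/2)*||I_d||^2 = d
        d = 3
        A = np.eye(4)[:, :d]
        B = np.zeros((2, d))
        Xh = TypeFeatureMatrix(np.zeros((2, 4)))
        Yh = TypeFeatureMatrix(np.zeros((2, 2)))
        Zb = ConnectivityMatrix(np.zeros((2, 2)))
        F = BilinearFactors(A, B)
        assert loss_typewise(Xh, Yh, Zb, F, lambda_A=2.0) == pytest.approx(d)

    def test_matches_elementwise_bruteforce(self, small_typewise):
        Xh, Yh, Zb, F = small_typewise
        expected = _loss_typewise_bruteforce(
            Xh.values, Yh.values, Zb.values, F.A, F.B, 0.4, 0.9)
        assert loss_typewise(Xh, Yh, Zb, F, 0.4, 0.9) == pytest.approx(
            expected, abs=1e-10)


class TestGradTypewise:
    def test_zero_factors_give_zero_gradient(self, small_typewise):
        Xh, Yh, Zb, _ = small_typewise
        F0 = BilinearFactors(np.zeros((4, 2)), np.zeros((3, 2)))
        gA, gB = grad_typewise(Xh, Yh, Zb, F0, 1.0, 1.0)
        np.testing.assert_array_equal(gA, 0)
        np.testing.assert_array_equal(gB, 0)

    def test_penalty_only_gradient(self, rng):
        # with Zbar equal to the prediction, only the Gram penalty remains
        A = rng.standard_normal((2, 2))
        B = rng.standard_normal((2, 2))
        F = BilinearFactors(A, B)
        Xh = TypeFeatureMatrix(rng.standard_normal((3, 2)))
        Yh = TypeFeatureMatrix(rng.standard_normal((2, 2)))
        Zb = ConnectivityMatrix((Xh.values @ A) @ (Yh.values @ B).T)
        gA, _ = grad_typewise(Xh, Yh, Zb, F, lambda_A=1.5)
        np.testing.assert_allclose(gA, 2 * 1.5 * A @ (A.T @ A), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_finite_differences(self, seed):
        assert gradient_fd_error(seed, "typewise") < 1e-5


class TestFitAGD:
    def test_noiseless_rank_d_instance_recovered(self):
        s = SyntheticScenario(a=5, b=4, cells_per_type=3, p=6, q=6, d_true=2,
                              within_type_sd=0.0, connectivity_noise_sd=0.0,
                              seed=3)
        inst = generate_bilinear_instance(s)
        cfg = FitConfig(d=2, tol=1e-12, max_iter=100_000, seed=0)
        res = fit_agd("cellwise", {k: inst[k] for k in ("X", "Y", "Z", "W")}, cfg)
        Zhat = predict_connectivity(inst["X"], inst["Y"], res.factors)
        rel = np.linalg.norm(Zhat.values - inst["Z"].values) \
            / np.linalg.norm(inst["Z"].values)
        assert rel < 1e-3

    def test_recovered_rule_product_matches_truth(self):
        # factors are identifiable only up to an invertible transform;
        # the product ABᵀ is what must match
        s = SyntheticScenario(a=8, b=6, cells_per_type=4, p=5, q=5, d_true=2,
                              within_type_sd=0.0, connectivity_noise_sd=0.0,
                              seed=7)
        inst = generate_bilinear_instance(s)
        cfg = FitConfig(d=2, tol=1e-14, max_iter=200_000, seed=1)
        res = fit_agd("cellwise", {k: inst[k] for k in ("X", "Y", "Z", "W")}, cfg)
        O_hat = rule_product(res.factors)
        O_true = rule_product(inst["factors_true"])
        assert np.linalg.norm(O_hat - O_true) / np.linalg.norm(O_true) < 1e-2

    def test_loss_nonincreasing_with_small_enough_rate(self, rng):
        X = CellFeatureMatrix(rng.standard_normal((6, 4)))
        Y = CellFeatureMatrix(rng.standard_normal((5, 4)))
        Z = ConnectivityMatrix(rng.standard_normal((6, 5)))
        W = WeightMatrix(np.ones((6, 5)))
        r = 1e-3
        for _ in range(8):  # halving schedule
            cfg = FitConfig(d=2, learning_rate=r, tol=1e-12, max_iter=500,
                            seed=0, adaptive=False)
            try:
                res = fit_agd("cellwise", {"X": X, "Y": Y, "Z": Z, "W": W}, cfg)
            except ConvergenceError:
                r *= 0.5
                continue
            diffs = np.diff(res.loss_trajectory)
            if np.all(diffs <= 1e-12):
                break
            r *= 0.5
        else:
            pytest.fail("no learning rate in the halving schedule descends")

    def test_adaptive_trajectory_is_monotone(self, small_typewise):
        Xh, Yh, Zb, _ = small_typewise
        cfg = FitConfig(d=2, tol=1e-10, max_iter=5000, seed=0)
        res = fit_agd("typewise", {"Xh": Xh, "Yh": Yh, "Zbar": Zb}, cfg)
        assert np.all(np.diff(res.loss_trajectory) <= 0)

    def test_same_seed_gives_identical_result(self, small_typewise):
        Xh, Yh, Zb, _ = small_typewise
        cfg = FitConfig(d=2, tol=1e-8, max_iter=2000, seed=5)
        r1 = fit_agd("typewise", {"Xh": Xh, "Yh": Yh, "Zbar": Zb}, cfg)
        r2 = fit_agd("typewise", {"Xh": Xh, "Yh": Yh, "Zbar": Zb}, cfg)
        np.testing.assert_array_equal(r1.factors.A, r2.factors.A)
        np.testing.assert_array_equal(r1.factors.B, r2.factors.B)
        np.testing.assert_array_equal(r1.loss_trajectory, r2.loss_trajectory)
        assert r1.n_iter == r2.n_iter

    def test_divergence_raises_with_guidance(self, rng):
        X = CellFeatureMatrix(10 * rng.standard_normal((6, 4)))
        Y = CellFeatureMatrix(10 * rng.standard_normal((5, 4)))
        Z = ConnectivityMatrix(rng.standard_normal((6, 5)))
        W = WeightMatrix(np.ones((6, 5)))
        cfg = FitConfig(d=2, learning_rate=10.0, tol=1e-8, max_iter=100,
                        seed=0, adaptive=False)
        with pytest.raises(ConvergenceError, match="smaller learning rate"):
            fit_agd("cellwise", {"X": X, "Y": Y, "Z": Z, "W": W}, cfg)

    def test_converged_means_final_change_below_tol(self, small_typewise):
        Xh, Yh, Zb, _ = small_typewise
        cfg = FitConfig(d=2, tol=1e-6, max_iter=50_000, seed=2)
        res = fit_agd("typewise", {"Xh": Xh, "Yh": Yh, "Zbar": Zb}, cfg)
        assert res.converged
        assert abs(res.loss_trajectory[-1] - res.loss_trajectory[-2]) < cfg.tol


class TestPredictAndRuleProduct:
    def test_all_ones_prediction(self):
        X = CellFeatureMatrix([[1.0], [1.0]])
        F = BilinearFactors([[1.0]], [[1.0]])
        Z = predict_connectivity(X, X, F)
        np.testing.assert_array_equal(Z.values, np.ones((2, 2)))
        assert Z.pre_ids == X.cell_ids

    def test_rank_bounded_by_d(self, rng):
        X = CellFeatureMatrix(rng.standard_normal((8, 6)))
        Y = CellFeatureMatrix(rng.standard_normal((7, 5)))
        F = BilinearFactors(rng.standard_normal((6, 2)), rng.standard_normal((5, 2)))
        Z = predict_connectivity(X, Y, F)
        assert np.linalg.matrix_rank(Z.values) <= 2

    def test_matches_triple_loop(self, rng):
        X = CellFeatureMatrix(rng.standard_normal((4, 3)))
        Y = CellFeatureMatrix(rng.standard_normal((3, 2)))
        F = BilinearFactors(rng.standard_normal((3, 2)), rng.standard_normal((2, 2)))
        Z = predict_connectivity(X, Y, F)
        for i in range(4):
            for j in range(3):
                expected = float((X.values[i] @ F.A) @ (Y.values[j] @ F.B))
                assert Z.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_outer_product_rule(self):
        F = BilinearFactors(np.array([[1.0], [2.0]]), np.array([[3.0], [4.0]]))
        np.testing.assert_allclose(rule_product(F), [[3.0, 4.0], [6.0, 8.0]])

    def test_rule_product_consistent_with_prediction(self, rng):
        # X (ABᵀ) Xᵀ must equal the factored prediction with Y = X
        X = CellFeatureMatrix(rng.standard_normal((5, 4)))
        F = BilinearFactors(rng.standard_normal((4, 2)), rng.standard_normal((4, 2)))
        direct = X.values @ rule_product(F) @ X.values.T
        np.testing.assert_allclose(
            direct, predict_connectivity(X, X, F).values, atol=1e-10)
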