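"""End-to-end study harnesses on synthetic data with known ground truth.

Each function wires the generators, the preprocessing chain, a fit and an
evaluation into one named experiment: gradient self-consistency, noiseless
exact recovery, recovery at the retina problem's shape, cross-validated
latent-dimension selection, and the bilinear/SCM equivalence on a small
consistent instance.  They are used by the examples, the test suite and the
acceptance script alike.
"""

from __future__ import annotations

import numpy as np

from .connectivity import average_by_type
from .containers import (
    BilinearFactors,
    CellFeatureMatrix,
    ConnectivityMatrix,
    FitConfig,
    TypeFeatureMatrix,
    WeightMatrix,
)
from .evaluate import cross_validate, matrix_pearson
from .model import (
    fit_agd,
    grad_cellwise,
    grad_typewise,
    loss_cellwise,
    loss_typewise,
    predict_connectivity,
    rule_product,
)
from .preprocess import normalize_type_matrix, typewise_stats
from .scm import EdgeList, RuleMatrix, build_kronecker_design, fit_scm_ridge, predict_scm
from .simulate import SyntheticScenario, generate_bilinear_instance


# ---------------------------------------------------------------------------
# gradient finite-difference checks
# ---------------------------------------------------------------------------

def _central_fd(loss_of, M: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar loss w.r.t. a matrix."""
    G = np.zeros_like(M)
    for idx in np.ndindex(*M.shape):
        Mp = M.copy()
        Mp[idx] += eps
        Mm = M.copy()
        Mm[idx] -= eps
        G[idx] = (loss_of(Mp) - loss_of(Mm)) / (2 * eps)
    return G


def gradient_fd_error(seed: int, variant: str = "cellwise",
                      max_features: int = 10) -> float:
    """Max relative error between analytic gradients and central finite
    differences on one randomized instance.

    Sizes (cells, types, features) are drawn from the seed, capped at
    ``max_features`` features per side; ridge strengths are drawn positive so
    the penalty terms are exercised too.
    """
    rng = np.random.default_rng(seed)
    p = int(rng.integers(2, max_features + 1))
    q = int(rng.integers(2, max_features + 1))
    d = int(rng.integers(1, 4))
    lamA = float(rng.uniform(0.1, 2.0))
    lamB = float(rng.uniform(0.1, 2.0))
    F = BilinearFactors(rng.standard_normal((p, d)), rng.standard_normal((q, d)))

    if variant == "cellwise":
        n = int(rng.integers(3, 9))
        m = int(rng.integers(3, 9))
        X = CellFeatureMatrix(rng.standard_normal((n, p)))
        Y = CellFeatureMatrix(rng.standard_normal((m, q)))
        Z = ConnectivityMatrix(rng.standard_normal((n, m)))
        W = WeightMatrix(rng.uniform(0, 1, (n, m)))
        A_an, B_an = grad_cellwise(X, Y, Z, W, F, lamA, lamB)
        A_fd = _central_fd(lambda M: loss_cellwise(
            X, Y, Z, W, BilinearFactors(M, F.B), lamA, lamB), F.A)
        B_fd = _central_fd(lambda M: loss_cellwise(
            X, Y, Z, W, BilinearFactors(F.A, M), lamA, lamB), F.B)
    elif variant == "typewise":
        a = int(rng.integers(3, 9))
        b = int(rng.integers(3, 9))
        Xh = TypeFeatureMatrix(rng.standard_normal((a, p)))
        Yh = TypeFeatureMatrix(rng.standard_normal((b, q)))
        Zb = ConnectivityMatrix(rng.standard_normal((a, b)))
        A_an, B_an = grad_typewise(Xh, Yh, Zb, F, lamA, lamB)
        A_fd = _central_fd(lambda M: loss_typewise(
            Xh, Yh, Zb, BilinearFactors(M, F.B), lamA, lamB), F.A)
        B_fd = _central_fd(lambda M: loss_typewise(
            Xh, Yh, Zb, BilinearFactors(F.A, M), lamA, lamB), F.B)
    else:
        raise ValueError(f"unknown variant {variant!r}")

    err_A = np.abs(A_an - A_fd).max() / max(np.abs(A_fd).max(), 1.0)
    err_B = np.abs(B_an - B_fd).max() / max(np.abs(B_fd).max(), 1.0)
    return float(max(err_A, err_B))


# ---------------------------------------------------------------------------
# recovery experiments
# ---------------------------------------------------------------------------

def noiseless_recovery(seed: int = 1) -> dict:
    """Fit the cellwise model on an exactly bilinear, noise-free instance.

    With zero within-type scatter and zero connectivity noise, Z has rank
    d_true exactly, so an unregularized fit should reconstruct it to
    numerical accuracy.  Returns the relative Frobenius error and the
    Pearson correlation against the generating Z.
    """
    s = SyntheticScenario(a=6, b=4, cells_per_type=3, p=8, q=8, d_true=2,
                          within_type_sd=0.0, connectivity_noise_sd=0.0,
                          seed=seed)
    inst = generate_bilinear_instance(s)
    cfg = FitConfig(d=2, tol=1e-12, max_iter=100_000, seed=seed)
    res = fit_agd("cellwise", {k: inst[k] for k in ("X", "Y", "Z", "W")}, cfg)
    Zhat = predict_connectivity(inst["X"], inst["Y"], res.factors)
    rel = float(np.linalg.norm(Zhat.values - inst["Z"].values)
                / np.linalg.norm(inst["Z"].values))
    r = matrix_pearson(Zhat.values, inst["Z"].values)
    return {"relative_error": rel, "pearson_r": r, "n_iter": res.n_iter,
            "converged": res.converged, "n": inst["Z"].values.size}


def type_level_pipeline(inst: dict):
    """Type-level views (X̂, Ŷ, Z̄) of a generated cell-level instance.

    The generated connectivity is already signed, so the type matrix is the
    plain cell-pair average (no standardization step is needed); expression
    goes through the pooled-variance normalization exactly as real data does.
    """
    Zbar = average_by_type(inst["Z"], inst["pre_labels"], inst["post_labels"])
    Xh = normalize_type_matrix(typewise_stats(inst["X"]))
    Yh = normalize_type_matrix(typewise_stats(inst["Y"]))
    return Xh, Yh, Zbar


def retina_shaped_recovery(seed: int = 0, tol: float = 1e-9,
                           max_iter: int = 100_000) -> dict:
    """Type-level fit on the default 25 x 12 scenario (noise sd 0.05).

    Measures how well the typewise model recovers the noiseless type-level
    connectivity from variance-normalized type means — the synthetic analogue
    of reconstructing the retina BC-RGC connectivity map.
    """
    inst = generate_bilinear_instance(SyntheticScenario(seed=seed))
    Xh, Yh, Zbar = type_level_pipeline(inst)
    cfg = FitConfig(d=2, tol=tol, max_iter=max_iter, seed=seed)
    res = fit_agd("typewise", {"Xh": Xh, "Yh": Yh, "Zbar": Zbar}, cfg)
    Zhat = predict_connectivity(Xh, Yh, res.factors)
    r = matrix_pearson(Zhat.values, inst["Z_type_true"].values)
    return {"pearson_r": r, "n_iter": res.n_iter, "converged": res.converged,
            "result": res, "Xh": Xh, "Yh": Yh, "Zbar": Zbar, "inst": inst}


def cv_dimension_selection(seed: int, d_grid=(1, 2, 3, 4),
                           lambda_grid=(0.1,), noise_sd: float = 0.1) -> int:
    """Cross-validated latent-dimension choice on d_true = 2 data.

    Generates a modest type-structured instance with connectivity noise
    ``noise_sd``, runs entry-level five-fold CV on the type-level model over
    the given grid, and returns the selected d.  Within-type expression
    scatter is set commensurate with the between-type separation (sd 0.5),
    the regime real transcriptomic data occupies, which keeps the
    variance-normalized type features at order one.
    """
    s = SyntheticScenario(a=12, b=8, cells_per_type=5, p=10, q=10, d_true=2,
                          within_type_sd=0.5, connectivity_noise_sd=noise_sd,
                          seed=seed)
    inst = generate_bilinear_instance(s)
    Xh, Yh, Zbar = type_level_pipeline(inst)
    res = cross_validate("typewise", {"Xh": Xh, "Yh": Yh, "Zbar": Zbar},
                         lambda_grid, d_grid, k=5, seed=seed,
                         tol=1e-8, max_iter=3_000)
    return res.selected[1]


def scm_equivalence(seed: int = 0, n_neurons: int = 12, p: int = 4) -> dict:
    """Bilinear full-rank fit vs SCM ridge on a consistent instance.

    Builds a symmetric gap-junction-style world Z = X O* Xᵀ with a symmetric
    rule O*, fits the SCM by ridge (tiny λ) and the bilinear model with
    d = p and vanishing ridge, and compares their predictions and rule
    matrices.  With d = p the bilinear factorization can represent any rule,
    so the two fits should coincide.
    """
    rng = np.random.default_rng(seed)
    Xv = rng.standard_normal((n_neurons, p))
    O_star = rng.standard_normal((p, p))
    O_star = 0.5 * (O_star + O_star.T)
    Zv = Xv @ O_star @ Xv.T

    X = CellFeatureMatrix(Xv, cell_ids=[f"n{i}" for i in range(n_neurons)],
                          type_labels=[f"n{i}" for i in range(n_neurons)])
    Z = ConnectivityMatrix(Zv, pre_ids=X.cell_ids, post_ids=X.cell_ids)
    W = WeightMatrix(np.ones_like(Zv))

    edges = EdgeList.from_matrices(Z, np.ones_like(Zv), symmetric=True)
    design, targets = build_kronecker_design(X, edges, symmetric=True)
    O_scm = fit_scm_ridge(design, targets, lam=1e-8,
                          feature_ids=X.feature_ids, symmetric=True)
    pred_scm = predict_scm(X, O_scm)

    cfg = FitConfig(d=p, lambda_A=1e-10, lambda_B=1e-10, tol=1e-14,
                    max_iter=300_000, seed=seed)
    res = fit_agd("cellwise", {"X": X, "Y": X, "Z": Z, "W": W}, cfg)
    pred_bl = predict_connectivity(X, X, res.factors)
    O_hat = rule_product(res.factors)

    rel = float(np.linalg.norm(pred_bl.values - pred_scm.values)
                / np.linalg.norm(pred_scm.values))
    r = matrix_pearson(O_hat, O_scm.values)
    return {"prediction_relative_error": rel, "rule_pearson_r": r,
            "O_hat": RuleMatrix(O_hat, row_feature_ids=X.feature_ids,
                                col_feature_ids=X.feature_ids),
            "O_scm": O_scm, "n": Zv.size}
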