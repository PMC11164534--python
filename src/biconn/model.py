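"""Bilinear connectivity model: losses, gradients, and alternating gradient descent.

Two data regimes are supported.

* **Cellwise** — expression and connectivity are observed on the same cells.
  The loss is the weighted squared residual
  ``sum_pairs w * (z - (xA)(yB)ᵀ)²`` plus ridge penalties
  ``(λ_A/2)||A||² + (λ_B/2)||B||²``.  The weights either balance type sizes
  (w = 1/(nᵢnⱼ)) or encode a binary physical-contact mask; a zero weight
  removes the pair from the fit entirely.

* **Typewise** — expression (single-cell transcriptomics) and connectivity
  (connectomics) come from different sources and are aligned only at the
  type level.  Inputs are variance-normalized type means, and the ridge
  penalty acts on the Gram matrices: ``(λ_A/2)||AᵀA||² + (λ_B/2)||BᵀB||²``,
  which pulls the latent features of each type toward its type mean.

Both regimes are fit by alternating gradient descent (AGD): per iteration
the prediction ``Ẑ = XA(YB)ᵀ`` is computed once, both gradients are taken at
the current point, and A is updated before B.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    BilinearFactors,
    CellFeatureMatrix,
    ConnectivityMatrix,
    DimensionError,
    FitConfig,
    FitResult,
    TypeFeatureMatrix,
    WeightMatrix,
    check_shapes,
    check_shapes_typewise,
)


class ConvergenceError(RuntimeError):
    """Raised when the AGD loss diverges to NaN/inf."""


# ---------------------------------------------------------------------------
# cellwise regime
# ---------------------------------------------------------------------------

def loss_cellwise(X: CellFeatureMatrix, Y: CellFeatureMatrix,
                  Z: ConnectivityMatrix, W: WeightMatrix,
                  F: BilinearFactors,
                  lambda_A: float = 0.0, lambda_B: float = 0.0) -> float:
    """Weighted squared-error loss with ridge penalties on A and B.

    Each squared residual is multiplied once by its weight, so with type-
    balance weights the data term is exactly the per-type-pair average of
    squared cell-pair residuals; the analytic gradients below are its true
    derivatives.
    """
    check_shapes(X, Y, Z, W, F)
    with np.errstate(over="ignore", invalid="ignore"):
        R = Z.values - (X.values @ F.A) @ (Y.values @ F.B).T
        data = float(np.sum(W.values * R * R))
        return data + 0.5 * lambda_A * float(np.sum(F.A ** 2)) \
            + 0.5 * lambda_B * float(np.sum(F.B ** 2))


def grad_cellwise(X: CellFeatureMatrix, Y: CellFeatureMatrix,
                  Z: ConnectivityMatrix, W: WeightMatrix,
                  F: BilinearFactors,
                  lambda_A: float = 0.0, lambda_B: float = 0.0):
    """Analytic gradients of :func:`loss_cellwise` w.r.t. A and B.

    A_grad = 2 Xᵀ (W ⊙ (Ẑ − Z)) Y B + λ_A A
    B_grad = 2 Yᵀ (W ⊙ (Ẑ − Z))ᵀ X A + λ_B B
    """
    check_shapes(X, Y, Z, W, F)
    XA = X.values @ F.A
    YB = Y.values @ F.B
    E = W.values * (XA @ YB.T - Z.values)     # W ⊙ (Ẑ − Z)
    A_grad = 2.0 * X.values.T @ E @ YB + lambda_A * F.A
    B_grad = 2.0 * Y.values.T @ E.T @ XA + lambda_B * F.B
    return A_grad, B_grad


# ---------------------------------------------------------------------------
# typewise regime
# ---------------------------------------------------------------------------

def loss_typewise(Xh: TypeFeatureMatrix, Yh: TypeFeatureMatrix,
                  Zbar: ConnectivityMatrix, F: BilinearFactors,
                  lambda_A: float = 0.0, lambda_B: float = 0.0,
                  weights: np.ndarray | None = None) -> float:
    """Type-level loss ``||Z̄ − X̂A(ŶB)ᵀ||² + (λ_A/2)||AᵀA||² + (λ_B/2)||BᵀB||²``.

    ``weights`` is an optional nonnegative matrix over type pairs used by the
    cross-validation harness to hold out entries; omitted, every pair counts
    equally (weight one).
    """
    check_shapes_typewise(Xh, Yh, Zbar, F)
    with np.errstate(over="ignore", invalid="ignore"):
        R = Zbar.values - (Xh.values @ F.A) @ (Yh.values @ F.B).T
        if weights is None:
            data = float(np.sum(R * R))
        else:
            data = float(np.sum(weights * R * R))
        GA = F.A.T @ F.A
        GB = F.B.T @ F.B
        return data + 0.5 * lambda_A * float(np.sum(GA ** 2)) \
            + 0.5 * lambda_B * float(np.sum(GB ** 2))


def grad_typewise(Xh: TypeFeatureMatrix, Yh: TypeFeatureMatrix,
                  Zbar: ConnectivityMatrix, F: BilinearFactors,
                  lambda_A: float = 0.0, lambda_B: float = 0.0,
                  weights: np.ndarray | None = None):
    """Analytic gradients of :func:`loss_typewise`.

    A_grad = 2 X̂ᵀ (Ẑ − Z̄) ŶB + 2 λ_A A (AᵀA)
    B_grad = 2 Ŷᵀ (Ẑ − Z̄)ᵀ X̂A + 2 λ_B B (BᵀB)

    The B-side data term uses the transposed residual so that shapes conform;
    both terms carry the factor 2 of the true derivative.
    """
    check_shapes_typewise(Xh, Yh, Zbar, F)
    XA = Xh.values @ F.A
    YB = Yh.values @ F.B
    E = XA @ YB.T - Zbar.values
    if weights is not None:
        E = weights * E
    A_grad = 2.0 * Xh.values.T @ E @ YB + 2.0 * lambda_A * F.A @ (F.A.T @ F.A)
    B_grad = 2.0 * Yh.values.T @ E.T @ XA + 2.0 * lambda_B * F.B @ (F.B.T @ F.B)
    return A_grad, B_grad


# ---------------------------------------------------------------------------
# alternating gradient descent
# ---------------------------------------------------------------------------

def _factor_step_polynomial(side_feats, other_proj, Zv, weights, M, g, lam,
                            penalty: str, transpose: bool) -> np.ndarray:
    """Quartic coefficients of the loss along one factor's gradient.

    With the other factor held fixed, the prediction is linear in the moving
    factor, so the data term of L(M - t g) is quadratic in t; the typewise
    Gram penalty contributes degree-4 terms.  ``transpose`` marks the
    post-synaptic side, whose projection enters the prediction transposed.
    Returns [c0, c1, c2, c3, c4].
    """
    P0 = side_feats @ M
    P1 = side_feats @ g
    if transpose:
        R0 = Zv - other_proj @ P0.T
        U = other_proj @ P1.T
    else:
        R0 = Zv - P0 @ other_proj.T
        U = P1 @ other_proj.T
    w = weights if weights is not None else 1.0
    c = np.array([
        np.sum(w * R0 * R0),
        2.0 * np.sum(w * R0 * U),
        np.sum(w * U * U),
        0.0,
        0.0,
    ])
    if penalty == "frobenius":
        c[0] += 0.5 * lam * np.sum(M * M)
        c[1] -= lam * np.sum(M * g)
        c[2] += 0.5 * lam * np.sum(g * g)
    else:  # gram penalty ||MᵀM||² of the typewise loss
        G0 = M.T @ M
        G1 = M.T @ g + g.T @ M
        G2 = g.T @ g
        c[0] += 0.5 * lam * np.sum(G0 * G0)
        c[1] -= lam * np.sum(G0 * G1)
        c[2] += 0.5 * lam * (np.sum(G1 * G1) + 2.0 * np.sum(G0 * G2))
        c[3] -= lam * np.sum(G1 * G2)
        c[4] += 0.5 * lam * np.sum(G2 * G2)
    return c


def _minimize_quartic(c: np.ndarray) -> float:
    """Nonnegative minimizer of a coercive polynomial c0 + c1 t + ... + c4 t⁴."""
    if c[4] == 0.0 and c[3] == 0.0:
        # quadratic fast path (data term + Frobenius penalty)
        if c[2] <= 0.0:
            return 0.0
        return max(-c[1] / (2.0 * c[2]), 0.0)
    deriv = [4 * c[4], 3 * c[3], 2 * c[2], c[1]]
    while deriv and deriv[0] == 0:
        deriv = deriv[1:]
    if not deriv or len(deriv) == 1:
        return 0.0
    roots = np.roots(deriv)
    cand = [float(t.real) for t in roots if abs(t.imag) < 1e-10 and t.real > 0]
    if not cand:
        return 0.0
    vals = [np.polyval(c[::-1], t) for t in cand]
    best = cand[int(np.argmin(vals))]
    return best if np.min(vals) <= c[0] else 0.0


def _agd_loop(loss_fn, grad_fn, p: int, q: int, config: FitConfig,
              step_ctx=None) -> FitResult:
    rng = np.random.default_rng(config.seed)
    A = rng.standard_normal((p, config.d))
    B = rng.standard_normal((q, config.d))
    F = BilinearFactors(A, B)
    r = config.learning_rate

    losses = [loss_fn(F)]
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        A_grad, B_grad = grad_fn(F)
        if config.adaptive:
            # exact line search along each factor's gradient: both gradients
            # are taken at the iteration's start, A moves first, and each
            # step size minimizes the loss in closed form along its direction
            Xv, Yv, Zv, weights, lamA, lamB, penalty = step_ctx
            cA = _factor_step_polynomial(Xv, Yv @ F.B, Zv, weights, F.A,
                                         A_grad, lamA, penalty, False)
            F.A = F.A - _minimize_quartic(cA) * A_grad
            cB = _factor_step_polynomial(Yv, Xv @ F.A, Zv, weights, F.B,
                                         B_grad, lamB, penalty, True)
            F.B = F.B - _minimize_quartic(cB) * B_grad
            L = loss_fn(F)
            if not np.isfinite(L):
                raise ConvergenceError(
                    f"loss became non-finite at iteration {n_iter}"
                )
            losses.append(L)
            if abs(losses[-1] - losses[-2]) < config.tol:
                converged = True
                break
        else:
            F.A = F.A - r * A_grad
            F.B = F.B - r * B_grad
            L = loss_fn(F)
            if not np.isfinite(L):
                raise ConvergenceError(
                    f"loss diverged to {L} at iteration {n_iter}; "
                    "try a smaller learning rate"
                )
            losses.append(L)
            if abs(losses[-1] - losses[-2]) < config.tol:
                converged = True
                break
    return FitResult(
        factors=F,
        loss_trajectory=np.array(losses),
        converged=converged,
        n_iter=n_iter,
        config=config,
    )


def fit_agd(variant: str, data: dict, config: FitConfig) -> FitResult:
    """Fit the bilinear model by alternating gradient descent.

    Parameters
    ----------
    variant : {"cellwise", "typewise"}
        Which data regime to fit.
    data : dict
        Cellwise: keys ``X``, ``Y`` (CellFeatureMatrix), ``Z``
        (ConnectivityMatrix), ``W`` (WeightMatrix).
        Typewise: keys ``Xh``, ``Yh`` (TypeFeatureMatrix), ``Zbar``
        (ConnectivityMatrix); optional ``weights`` (ndarray over type pairs).
    config : FitConfig
        d, learning rate, ridge strengths, tolerance, iteration cap, seed.

    Both factors are initialized from a seeded standard normal, so the result
    is a pure function of (data, config).  Per iteration both gradients are
    taken at the current prediction and A is updated before B; by default
    each update's step size is an exact line search along the gradient (the
    loss restricted to that line is a low-degree polynomial), while
    ``adaptive=False`` uses the fixed learning rate.  The loop stops when the
    absolute loss change drops below ``config.tol`` or ``config.max_iter`` is
    reached; a NaN/inf loss raises :class:`ConvergenceError`.
    """
    lamA, lamB = config.lambda_A, config.lambda_B
    if variant == "cellwise":
        X, Y, Z, W = data["X"], data["Y"], data["Z"], data["W"]
        check_shapes(X, Y, Z, W, BilinearFactors(
            np.zeros((X.n_features, config.d)), np.zeros((Y.n_features, config.d))))

        def loss_fn(F):
            return loss_cellwise(X, Y, Z, W, F, lamA, lamB)

        def grad_fn(F):
            return grad_cellwise(X, Y, Z, W, F, lamA, lamB)

        step_ctx = (X.values, Y.values, Z.values, W.values, lamA, lamB,
                    "frobenius")
        return _agd_loop(loss_fn, grad_fn, X.n_features, Y.n_features, config,
                         step_ctx)

    if variant == "typewise":
        Xh, Yh, Zbar = data["Xh"], data["Yh"], data["Zbar"]
        weights = data.get("weights")
        check_shapes_typewise(Xh, Yh, Zbar, BilinearFactors(
            np.zeros((Xh.n_features, config.d)), np.zeros((Yh.n_features, config.d))))

        def loss_fn(F):
            return loss_typewise(Xh, Yh, Zbar, F, lamA, lamB, weights)

        def grad_fn(F):
            return grad_typewise(Xh, Yh, Zbar, F, lamA, lamB, weights)

        step_ctx = (Xh.values, Yh.values, Zbar.values, weights, lamA, lamB,
                    "gram")
        return _agd_loop(loss_fn, grad_fn, Xh.n_features, Yh.n_features,
                         config, step_ctx)

    raise ValueError(f"unknown variant {variant!r}; use 'cellwise' or 'typewise'")


def predict_connectivity(X, Y, F: BilinearFactors) -> ConnectivityMatrix:
    """Predicted connectivity ``XA(YB)ᵀ`` with axis labels propagated.

    Accepts either cell-level or type-level feature matrices; the output has
    numerical rank at most d.
    """
    if F.A.shape[0] != X.values.shape[1]:
        raise DimensionError(
            f"A has {F.A.shape[0]} feature rows but pre matrix has "
            f"{X.values.shape[1]} features"
        )
    if F.B.shape[0] != Y.values.shape[1]:
        raise DimensionError(
            f"B has {F.B.shape[0]} feature rows but post matrix has "
            f"{Y.values.shape[1]} features"
        )
    vals = (X.values @ F.A) @ (Y.values @ F.B).T
    pre_ids = getattr(X, "cell_ids", None) or getattr(X, "type_ids", None)
    post_ids = getattr(Y, "cell_ids", None) or getattr(Y, "type_ids", None)
    level = "cell" if hasattr(X, "cell_ids") else "type"
    return ConnectivityMatrix(vals, pre_ids=pre_ids, post_ids=post_ids, level=level)


def rule_product(F: BilinearFactors) -> np.ndarray:
    """Low-rank rule matrix ``Ô = ABᵀ`` (p x q).

    Interpretable as the bilinear model's reconstruction of the gene-gene
    interaction rule matrix of the spatial connectome model.
    """
    return F.A @ F.B.T
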