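"""Model evaluation: link-prediction ROC, matrix correlation, five-fold
cross-validation over (lambda, d), run-to-run consistency, and missed-
connection analysis."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score, roc_curve

from .containers import (
    ConnectivityMatrix,
    FitConfig,
    FitResult,
    WeightMatrix,
)
from .model import fit_agd, loss_cellwise, loss_typewise
from .scm import discrepancy_score


@dataclass
class CVResult:
    """Grid-search cross-validation outcome.

    ``selected`` minimizes the mean validation loss; ties break toward
    smaller d, then smaller lambda.
    """

    grid: list                 # list of (lambda, d)
    mean_val_loss: np.ndarray  # per grid point
    fold_losses: np.ndarray    # folds x grid points
    selected: tuple            # (lambda, d)
    fold_seed: int

    def to_dict(self) -> dict:
        return {
            "grid": [list(g) for g in self.grid],
            "mean_val_loss": self.mean_val_loss.tolist(),
            "fold_losses": self.fold_losses.tolist(),
            "selected": list(self.selected),
            "fold_seed": self.fold_seed,
        }


@dataclass
class ConsistencyScore:
    """Pairwise run-similarity matrix in [0, 1]; diagonal 1, symmetric."""

    pairwise_scores: np.ndarray

    @property
    def min(self) -> float:
        iu = np.triu_indices_from(self.pairwise_scores, k=1)
        return float(self.pairwise_scores[iu].min()) if iu[0].size else 1.0

    @property
    def mean(self) -> float:
        iu = np.triu_indices_from(self.pairwise_scores, k=1)
        return float(self.pairwise_scores[iu].mean()) if iu[0].size else 1.0


def _masked_entries(values: np.ndarray, mask: WeightMatrix | None):
    if mask is None:
        return values.ravel()
    return values[mask.values > 0]


def roc_auc(scores: ConnectivityMatrix, truth: np.ndarray,
            mask: WeightMatrix | None = None):
    """ROC-AUC of continuous connectivity scores against binary truth.

    Only entries with positive mask weight enter (all entries if no mask).
    Ties are handled by the rank equivalence
    AUC = P(score₊ > score₋) + ½·P(score₊ = score₋).
    Returns (auc, curve) with the curve as a list of (fpr, tpr) points.
    """
    truth = np.asarray(truth)
    if truth.shape != scores.values.shape:
        raise ValueError(f"truth {truth.shape} vs scores {scores.values.shape}")
    if not np.isin(truth, (0, 1)).all():
        raise ValueError("truth must be binary 0/1")
    s = _masked_entries(scores.values, mask)
    t = _masked_entries(truth, mask).astype(int)
    if len(np.unique(t)) < 2:
        raise ValueError("ROC-AUC undefined: truth has a single class among "
                         "unmasked entries")
    auc = float(roc_auc_score(t, s))
    fpr, tpr, _ = roc_curve(t, s)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def matrix_pearson(Mhat: np.ndarray, M: np.ndarray,
                   mask: WeightMatrix | None = None) -> float:
    """Pearson correlation over corresponding (unmasked) matrix entries."""
    Mhat = np.asarray(Mhat, dtype=float)
    M = np.asarray(M, dtype=float)
    if Mhat.shape != M.shape:
        raise ValueError(f"shape mismatch: {Mhat.shape} vs {M.shape}")
    a = _masked_entries(Mhat, mask)
    b = _masked_entries(M, mask)
    if a.size < 2:
        raise ValueError("need at least 2 unmasked entries")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(pearsonr(a, b).statistic)


def _observed_entries(variant: str, data: dict) -> np.ndarray:
    """Flat indices of entries that participate in the fit."""
    if variant == "cellwise":
        W = data["W"].values
        return np.flatnonzero(W.ravel() > 0)
    Zbar = data["Zbar"].values
    return np.arange(Zbar.size)


def cross_validate(variant: str, data: dict, lambda_grid, d_grid,
                   k: int = 5, seed: int = 0,
                   learning_rate: float | None = None,
                   tol: float = 1e-6, max_iter: int = 1_000_000) -> CVResult:
    """Five-fold (by default) cross-validation over a (lambda, d) grid.

    Observed connectivity entries — cell pairs with positive weight in the
    cellwise regime, all type pairs in the typewise regime — are shuffled by
    the seed and partitioned into ``k`` folds.  For each grid point the model
    is fit with held-out entries weighted zero, and the unregularized
    weighted data term on the held-out entries is the validation loss.
    The selected pair minimizes the mean validation loss, ties broken toward
    smaller d then smaller lambda.
    """
    observed = _observed_entries(variant, data)
    if observed.size < k:
        raise ValueError(
            f"only {observed.size} observed entries for k={k} folds; use smaller k"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(observed)
    folds = np.array_split(perm, k)
    for f in folds:
        if f.size == 0:
            raise ValueError(f"empty cross-validation fold; use smaller k than {k}")

    grid = [(float(lam), int(d)) for lam in lambda_grid for d in d_grid]
    fold_losses = np.empty((k, len(grid)))

    if variant == "cellwise":
        X, Y, Z, W = data["X"], data["Y"], data["Z"], data["W"]
        shape = Z.values.shape
        for fi, fold in enumerate(folds):
            W_train = W.values.copy().ravel()
            W_train[fold] = 0.0
            W_val = np.zeros(Z.values.size)
            W_val[fold] = W.values.ravel()[fold]
            bundle = {"X": X, "Y": Y, "Z": Z,
                      "W": WeightMatrix(W_train.reshape(shape))}
            Wv = WeightMatrix(W_val.reshape(shape))
            for gi, (lam, d) in enumerate(grid):
                cfg = _make_config(lam, d, seed, learning_rate, tol, max_iter)
                res = fit_agd("cellwise", bundle, cfg)
                fold_losses[fi, gi] = loss_cellwise(X, Y, Z, Wv, res.factors)
    elif variant == "typewise":
        Xh, Yh, Zbar = data["Xh"], data["Yh"], data["Zbar"]
        shape = Zbar.values.shape
        base_w = data.get("weights")
        base_w = np.ones(shape) if base_w is None else np.asarray(base_w, float)
        for fi, fold in enumerate(folds):
            w_train = base_w.copy().ravel()
            w_train[fold] = 0.0
            w_val = np.zeros(Zbar.values.size)
            w_val[fold] = base_w.ravel()[fold]
            bundle = {"Xh": Xh, "Yh": Yh, "Zbar": Zbar,
                      "weights": w_train.reshape(shape)}
            for gi, (lam, d) in enumerate(grid):
                cfg = _make_config(lam, d, seed, learning_rate, tol, max_iter)
                res = fit_agd("typewise", bundle, cfg)
                fold_losses[fi, gi] = loss_typewise(
                    Xh, Yh, Zbar, res.factors, weights=w_val.reshape(shape))
    else:
        raise ValueError(f"unknown variant {variant!r}")

    mean_val = fold_losses.mean(axis=0)
    # ties toward smaller d, then smaller lambda
    order = sorted(range(len(grid)),
                   key=lambda i: (mean_val[i], grid[i][1], grid[i][0]))
    selected = grid[order[0]]
    return CVResult(grid=grid, mean_val_loss=mean_val, fold_losses=fold_losses,
                    selected=selected, fold_seed=seed)


def _make_config(lam, d, seed, learning_rate, tol, max_iter) -> FitConfig:
    kwargs = dict(d=d, lambda_A=lam, lambda_B=lam, tol=tol, max_iter=max_iter,
                  seed=seed)
    if learning_rate is not None:
        kwargs["learning_rate"] = learning_rate
    return FitConfig(**kwargs)


def _abs_cos(u: np.ndarray, v: np.ndarray) -> float:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return abs(float(u @ v)) / (nu * nv)


def _pair_consistency(Fa, Fb) -> float:
    """Best average |cosine| over latent-column pairings of two solutions.

    Negating a latent column in both factors, or permuting columns jointly,
    leaves the fitted product unchanged; the score searches all d! pairings
    for d <= 4 (greedy matching beyond) and takes the maximum of the mean
    |cosine| averaged over the A-side and B-side factors.
    """
    d = Fa.d
    if Fb.d != d:
        raise ValueError(f"runs have different latent dimensions: {d} vs {Fb.d}")

    def score(perm):
        vals = []
        for kk, pk in enumerate(perm):
            vals.append(0.5 * (_abs_cos(Fa.A[:, kk], Fb.A[:, pk])
                               + _abs_cos(Fa.B[:, kk], Fb.B[:, pk])))
        return float(np.mean(vals))

    if d <= 4:
        return max(score(p) for p in itertools.permutations(range(d)))
    # greedy matching for larger d
    sim = np.empty((d, d))
    for i in range(d):
        for j in range(d):
            sim[i, j] = 0.5 * (_abs_cos(Fa.A[:, i], Fb.A[:, j])
                               + _abs_cos(Fa.B[:, i], Fb.B[:, j]))
    perm = [-1] * d
    free = set(range(d))
    for i in np.argsort(-sim.max(axis=1)):
        j = max(free, key=lambda j: sim[i, j])
        perm[i] = j
        free.remove(j)
    return score(perm)


def consistency_across_runs(runs) -> ConsistencyScore:
    """Pairwise solution-consistency scores across repeated fits.

    For each run pair the score is the maximum over latent-column pairings of
    the mean absolute cosine similarity of corresponding coefficient vectors,
    averaged across the pre- and post-side factors.  1 means identical up to
    the sign/permutation indeterminacy of the latent space.
    """
    factors = [r.factors if isinstance(r, FitResult) else r for r in runs]
    n = len(factors)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = _pair_consistency(factors[i], factors[j])
    return ConsistencyScore(pairwise_scores=S)


def missed_connections(Zhat: ConnectivityMatrix, Z: ConnectivityMatrix):
    """Count target connections (Z > 0) the reconstruction misses (Ẑ <= 0).

    Returns (n_missed, n_positive, ds_map) where ds_map is the entrywise
    discrepancy score between reconstruction and target.
    """
    if Zhat.values.shape != Z.values.shape:
        raise ValueError(
            f"shape mismatch: {Zhat.values.shape} vs {Z.values.shape}"
        )
    positive = Z.values > 0
    n_positive = int(positive.sum())
    n_missed = int((positive & (Zhat.values <= 0)).sum())
    ds_map = discrepancy_score(Zhat.values, Z.values)
    return n_missed, n_positive, ds_map
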