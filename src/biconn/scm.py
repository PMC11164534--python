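"""Spatial connectome model (SCM) baseline and rule-matrix comparison.

The SCM predicts connectivity between physically contacting neurons as
``X O Xᵀ``, where O is a gene-gene rule matrix fit by ridge regression:
each contacting pair (i, j) contributes a row ``xᵢ ⊗ xⱼ`` of the Kronecker
design matrix and its observed connectivity as the target.  For undirected
(gap-junction) connectivity O is constrained symmetric by averaging the two
orientations of each design row and counting each unordered pair once.

The bilinear model's ``Ô = ABᵀ`` is a low-rank factorization of O; the
discrepancy score DS = |ô − o| / (|ô| + |o|) localizes where the two rules
disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import lsqr
from scipy.stats import pearsonr

from .containers import CellFeatureMatrix, ConnectivityMatrix, DimensionError


@dataclass
class RuleMatrix:
    """Gene-gene interaction coefficients (p x q; p x p and symmetric for
    gap junctions)."""

    values: np.ndarray
    row_feature_ids: list = field(default_factory=list)
    col_feature_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("RuleMatrix.values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RuleMatrix contains non-finite entries")
        p, q = self.values.shape
        if not self.row_feature_ids:
            self.row_feature_ids = [f"f{m}" for m in range(p)]
        if not self.col_feature_ids:
            self.col_feature_ids = [f"f{m}" for m in range(q)]


@dataclass
class EdgeList:
    """Connectivity records (pre_cell, post_cell, observed value, contact flag).

    Only records with ``in_contact`` true enter the SCM regression.  In the
    symmetric (gap-junction) case each unordered pair must appear once.
    """

    pre_cells: list
    post_cells: list
    observed: np.ndarray
    in_contact: np.ndarray

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.in_contact = np.asarray(self.in_contact, dtype=bool)
        n = len(self.pre_cells)
        if not (len(self.post_cells) == self.observed.size == self.in_contact.size == n):
            raise DimensionError("EdgeList fields must have equal length")

    def contact_subset(self):
        keep = np.flatnonzero(self.in_contact)
        return ([self.pre_cells[i] for i in keep],
                [self.post_cells[i] for i in keep],
                self.observed[keep])

    @classmethod
    def from_matrices(cls, Z: ConnectivityMatrix, contact: np.ndarray,
                      symmetric: bool = True) -> "EdgeList":
        """Build the edge list from a connectivity matrix and a contact mask.

        With ``symmetric`` each unordered in-contact pair (i <= j) is emitted
        once; otherwise every ordered pair is kept.
        """
        contact = np.asarray(contact)
        if contact.shape != Z.shape:
            raise DimensionError(f"contact mask {contact.shape} vs Z {Z.shape}")
        pre, post, obs, flags = [], [], [], []
        n, m = Z.shape
        for i in range(n):
            jstart = i if symmetric else 0
            for j in range(jstart, m):
                if contact[i, j] or (symmetric and contact[j, i]):
                    pre.append(Z.pre_ids[i])
                    post.append(Z.post_ids[j])
                    obs.append(Z.values[i, j])
                    flags.append(True)
        return cls(pre, post, np.array(obs), np.array(flags))


@dataclass
class DiscrepancyReport:
    """Entrywise discrepancy scores in [0, 1] plus the flag matrix."""

    ds_values: np.ndarray
    flagged: np.ndarray
    thresholds: tuple

    def n_flagged(self) -> int:
        return int(self.flagged.sum())


def build_kronecker_design(X: CellFeatureMatrix, edges: EdgeList,
                           symmetric: bool = True):
    """Design matrix of Kronecker rows for the rule-matrix regression.

    Row for edge (i, j) is ``xᵢ ⊗ xⱼ`` (row-major feature pairing) so that
    ``design · vec(O)`` reproduces ``xᵢ O xⱼᵀ``.  In the symmetric case the
    row is the average ``(xᵢ⊗xⱼ + xⱼ⊗xᵢ)/2``, which constrains the fitted O
    to act symmetrically.
    """
    index = {cid: k for k, cid in enumerate(X.cell_ids)}
    pre, post, targets = edges.contact_subset()
    p = X.n_features
    design = np.empty((len(pre), p * p))
    for row, (ci, cj) in enumerate(zip(pre, post)):
        if ci not in index:
            raise KeyError(f"edge cell id {ci!r} not present in expression matrix")
        if cj not in index:
            raise KeyError(f"edge cell id {cj!r} not present in expression matrix")
        xi = X.values[index[ci]]
        xj = X.values[index[cj]]
        r = np.kron(xi, xj)
        if symmetric:
            r = 0.5 * (r + np.kron(xj, xi))
        design[row] = r
    return design, np.asarray(targets, dtype=float)


def fit_scm_ridge(design: np.ndarray, targets: np.ndarray, lam: float,
                  feature_ids: list | None = None,
                  symmetric: bool = True) -> RuleMatrix:
    """Solve the ridge normal equations ``(DᵀD + λI) vec(O) = Dᵀt``.

    Direct solve when p² <= 2,500, iterative LSQR on the ridge-augmented
    system otherwise (tolerance 1e-10).  At λ = 0 a singular system raises
    with a pointer toward λ > 0.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n_edges, psq = design.shape
    if n_edges < 1:
        raise ValueError("need at least one edge to fit the SCM")
    p = int(round(np.sqrt(psq)))
    if p * p != psq:
        raise DimensionError(f"design has {psq} columns, not a perfect square")

    if psq <= 2500:
        G = design.T @ design + lam * np.eye(psq)
        rhs = design.T @ targets
        if lam == 0:
            # guard: rank-deficient normal equations have no unique solution
            rank = np.linalg.matrix_rank(G)
            if rank < psq:
                raise np.linalg.LinAlgError(
                    "singular normal equations at lambda=0; use lambda > 0"
                )
        vec = np.linalg.solve(G, rhs)
    else:
        sol = lsqr(design, targets, damp=np.sqrt(lam), atol=1e-10, btol=1e-10,
                   iter_lim=10 * psq)
        vec = sol[0]
    O = vec.reshape(p, p)
    if symmetric:
        O = 0.5 * (O + O.T)
    ids = feature_ids or [f"f{m}" for m in range(p)]
    return RuleMatrix(O, row_feature_ids=list(ids), col_feature_ids=list(ids))


def cv_scm_lambda(design: np.ndarray, targets: np.ndarray, lambda_grid,
                  k: int = 5, seed: int = 0, symmetric: bool = True):
    """Choose the SCM ridge strength by k-fold CV over edges.

    Edges are shuffled by the seed and split into k folds; per λ the rule is
    fit on k−1 folds and scored by mean squared error on the held-out fold —
    the same fold harness the bilinear model uses, for parity in comparison.
    Returns (best_lambda, mean_val_mse per grid value).
    """
    n_edges = design.shape[0]
    if n_edges < k:
        raise ValueError(f"only {n_edges} edges for k={k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_edges)
    folds = np.array_split(perm, k)
    lambda_grid = [float(l) for l in lambda_grid]
    mse = np.zeros((k, len(lambda_grid)))
    for fi, fold in enumerate(folds):
        train = np.setdiff1d(perm, fold)
        for li, lam in enumerate(lambda_grid):
            O = fit_scm_ridge(design[train], targets[train], lam,
                              symmetric=symmetric)
            pred = design[fold] @ O.values.ravel()
            mse[fi, li] = float(np.mean((pred - targets[fold]) ** 2))
    mean_mse = mse.mean(axis=0)
    best = lambda_grid[int(np.argmin(mean_mse))]
    return best, mean_mse


def predict_scm(X: CellFeatureMatrix, O: RuleMatrix) -> ConnectivityMatrix:
    """SCM prediction ``X O Xᵀ`` over all cell pairs."""
    if X.n_features != O.values.shape[0] or X.n_features != O.values.shape[1]:
        raise DimensionError(
            f"O is {O.values.shape} but X has {X.n_features} features"
        )
    vals = X.values @ O.values @ X.values.T
    return ConnectivityMatrix(vals, pre_ids=X.cell_ids, post_ids=X.cell_ids,
                              level="cell")


def discrepancy_score(o_hat, o):
    """DS = |ô − o| / (|ô| + |o|), elementwise; DS(0, 0) defined as 0.

    Symmetric, invariant to a shared positive rescaling, and bounded in
    [0, 1]: 0 means agreement, 1 means opposite signs or one-sided support.
    """
    o_hat = np.asarray(o_hat, dtype=float)
    o = np.asarray(o, dtype=float)
    denom = np.abs(o_hat) + np.abs(o)
    with np.errstate(invalid="ignore", divide="ignore"):
        ds = np.where(denom > 0, np.abs(o_hat - o) / np.where(denom > 0, denom, 1.0), 0.0)
    if ds.ndim == 0:
        return float(ds)
    return ds


def flag_divergent_entries(O_hat: RuleMatrix, O: RuleMatrix,
                           ds_threshold: float = 0.5,
                           magnitude_floor: float = 0.1) -> DiscrepancyReport:
    """Flag entries where the two rule matrices substantially disagree.

    An entry is flagged iff DS >= ``ds_threshold`` and not both values are
    below ``magnitude_floor`` in magnitude (small coefficients are shrunk
    toward zero by regularization, so their disagreement is uninformative).
    """
    if O_hat.values.shape != O.values.shape:
        raise DimensionError(
            f"rule matrices differ in shape: {O_hat.values.shape} vs {O.values.shape}"
        )
    ds = discrepancy_score(O_hat.values, O.values)
    both_small = (np.abs(O_hat.values) < magnitude_floor) & \
                 (np.abs(O.values) < magnitude_floor)
    flagged = (ds >= ds_threshold) & ~both_small
    return DiscrepancyReport(ds_values=ds, flagged=flagged,
                             thresholds=(ds_threshold, magnitude_floor))


def compare_rule_matrices(O_hat: RuleMatrix, O: RuleMatrix,
                          ds_threshold: float = 0.5,
                          magnitude_floor: float = 0.1):
    """Pearson correlation across all entries plus the discrepancy report."""
    if O_hat.values.shape != O.values.shape:
        raise DimensionError(
            f"rule matrices differ in shape: {O_hat.values.shape} vs {O.values.shape}"
        )
    a = O_hat.values.ravel()
    b = O.values.ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: a rule matrix has zero variance")
    r = float(pearsonr(a, b).statistic)
    report = flag_divergent_entries(O_hat, O, ds_threshold, magnitude_floor)
    return r, report
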