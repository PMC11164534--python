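"""Single-cell transcriptomic preprocessing for the type-level bilinear model.

Pipeline: raw counts -> median normalization + log1p -> highly-variable-gene
selection (mean-CV² regression) -> PCA keeping 95% cumulative variance ->
per-type means with pooled within-type variance -> variance-normalized type
matrix.  Each neuronal class (e.g. bipolar cells and ganglion cells) runs
through its own pipeline instance; type names are aligned to connectomic
types with an explicit mapping table, never by fuzzy matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .containers import CellFeatureMatrix, DimensionError, TypeFeatureMatrix


@dataclass
class CountMatrix:
    """Nonnegative integer transcript counts, cells x genes."""

    counts: np.ndarray
    cell_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)
    type_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DimensionError("CountMatrix.counts must be 2-D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integer-valued")
        n, g = self.counts.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"g{m}" for m in range(g)]
        if not self.type_labels:
            self.type_labels = ["type0"] * n


@dataclass
class TypewiseStats:
    """Per-type feature means and the pooled within-type standard deviation.

    The pooled variance of feature m is the sum over types of the within-type
    population variance (divisor nᵢ); singleton types contribute zero.
    """

    type_means: np.ndarray
    pooled_sd: np.ndarray
    type_ids: list
    feature_ids: list


def median_normalize_log(counts: CountMatrix) -> CellFeatureMatrix:
    """Scale each cell to the median library size, then log1p.

    Each cell's counts are multiplied by (median per-cell total / its own
    total) so totals align at the median, removing cell-size variation, and
    log(1 + x) is applied.
    """
    totals = counts.counts.sum(axis=1).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [counts.cell_ids[i] for i in zero]
        raise ValueError(f"cells with zero total counts: {bad}")
    med = float(np.median(totals))
    scaled = counts.counts * (med / totals)[:, None]
    return CellFeatureMatrix(
        np.log1p(scaled),
        cell_ids=list(counts.cell_ids),
        type_labels=list(counts.type_labels),
        feature_ids=list(counts.gene_ids),
    )


def select_hvgs(expr: CellFeatureMatrix, dispersion_z: float = 1.0) -> CellFeatureMatrix:
    """Select highly variable genes from the mean-CV² relationship.

    Fits a line to log(CV²) vs log(mean) across genes and keeps genes whose
    standardized residual exceeds ``dispersion_z`` — i.e. genes more variable
    than their expression level predicts.  Genes with zero mean or zero
    variance can never be selected.
    """
    if expr.n_cells < 2:
        raise ValueError("need at least 2 cells to estimate dispersion")
    V = expr.values
    mean = V.mean(axis=0)
    var = V.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mean > 0, var / np.maximum(mean, 1e-300) ** 2, 0.0)
    usable = (mean > 0) & (cv2 > 0)
    if usable.sum() < 2:
        raise ValueError("too few expressed genes to fit the mean-CV^2 trend")
    lx = np.log(mean[usable])
    ly = np.log(cv2[usable])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    sd = resid.std()
    z = resid / sd if sd > 0 else np.zeros_like(resid)
    selected = np.zeros(expr.n_features, dtype=bool)
    selected[np.flatnonzero(usable)] = z > dispersion_z
    if selected.sum() < 10:
        warnings.warn(
            f"only {int(selected.sum())} highly variable genes retained",
            UserWarning,
        )
    idx = np.flatnonzero(selected)
    return CellFeatureMatrix(
        V[:, idx],
        cell_ids=list(expr.cell_ids),
        type_labels=list(expr.type_labels),
        feature_ids=[expr.feature_ids[i] for i in idx],
    )


def pca_95(expr: CellFeatureMatrix, variance_target: float = 0.95):
    """Project onto the leading PCs covering ``variance_target`` cumulative
    explained variance.

    Returns (scores as a CellFeatureMatrix, loadings genes x PCs with
    orthonormal columns, explained-variance fractions of the retained PCs).
    Columns are centered internally; scores therefore have zero column means.
    """
    if not (0 < variance_target <= 1):
        raise ValueError("variance_target must be in (0, 1]")
    if expr.n_cells < 2:
        raise ValueError("need at least 2 cells for PCA")
    n_max = min(expr.n_cells - 1, expr.n_features)
    pca = PCA(n_components=n_max, svd_solver="full")
    scores_full = pca.fit_transform(expr.values)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, n_max)
    scores = CellFeatureMatrix(
        scores_full[:, :k],
        cell_ids=list(expr.cell_ids),
        type_labels=list(expr.type_labels),
        feature_ids=[f"PC{i + 1}" for i in range(k)],
    )
    loadings = pca.components_[:k].T          # genes x PCs, orthonormal columns
    explained = pca.explained_variance_ratio_[:k]
    return scores, loadings, explained


def typewise_stats(expr: CellFeatureMatrix) -> TypewiseStats:
    """Per-type means and the pooled within-type variance per feature.

    The pooled variance sums, over types, the within-type mean squared
    deviation from the type mean (population divisor nᵢ); pooled_sd is its
    square root.  Order of types follows first appearance in the cell list.
    """
    types = expr.type_order()
    a = len(types)
    means = np.empty((a, expr.n_features))
    pooled_var = np.zeros(expr.n_features)
    labels = np.asarray(expr.type_labels, dtype=object)
    for i, t in enumerate(types):
        rows = expr.values[labels == t]
        means[i] = rows.mean(axis=0)
        pooled_var += ((rows - means[i]) ** 2).mean(axis=0)
    return TypewiseStats(
        type_means=means,
        pooled_sd=np.sqrt(pooled_var),
        type_ids=list(types),
        feature_ids=list(expr.feature_ids),
    )


def normalize_type_matrix(stats: TypewiseStats, sd_floor: float = 1e-8) -> TypeFeatureMatrix:
    """Variance-normalized type matrix: x̂ᵢₘ = x̄ᵢₘ / max(σ̂ₘ, sd_floor).

    Dividing type means by the pooled within-type standard deviation keeps
    latent features of individual cells close to their type mean, which is the
    approximation the type-level model rests on.
    """
    sd = np.maximum(stats.pooled_sd, sd_floor)
    return TypeFeatureMatrix(
        stats.type_means / sd,
        type_ids=list(stats.type_ids),
        feature_ids=list(stats.feature_ids),
        scale_applied=True,
    )


def align_types(matrix: TypeFeatureMatrix, mapping: dict) -> TypeFeatureMatrix:
    """Rename transcriptomic types to connectomic names via an explicit table.

    ``mapping`` is transcriptomic name -> connectomic name; types without an
    entry are dropped (they have no connectomic counterpart).
    """
    keep, names = [], []
    for i, t in enumerate(matrix.type_ids):
        if t in mapping:
            keep.append(i)
            names.append(mapping[t])
    if not keep:
        raise ValueError("no types matched the alignment table")
    return TypeFeatureMatrix(
        matrix.values[keep],
        type_ids=names,
        feature_ids=list(matrix.feature_ids),
        scale_applied=matrix.scale_applied,
    )
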