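"""Seeded synthetic-data generators with known ground truth.

The generators emulate the statistical structure the model assumes:
type-structured expression (type means plus within-type Gaussian noise), a
ground-truth bilinear connectivity rule with additive noise, sparse
physical-contact masks, Poisson count matrices with cell-size variation and
planted highly variable genes, and Gaussian-bump stratification profiles on
a normalized depth grid.  Every generator is a pure function of its seed and
parameters.  Default scenario sizes mirror the retina problem's aspect ratio
(25 presynaptic x 12 postsynaptic types).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import DEFAULT_DEPTH_GRID
from .containers import (
    BilinearFactors,
    CellFeatureMatrix,
    ConnectivityMatrix,
    WeightMatrix,
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic bilinear-connectivity world.

    ``a``/``b`` pre/post type counts; ``cells_per_type`` cells per type
    (int or per-type list); ``p``/``q`` feature counts; ``d_true`` the
    generating latent dimension; ``within_type_sd`` cell scatter around type
    means; ``connectivity_noise_sd`` additive noise on Z;
    ``contact_density`` Bernoulli probability of physical contact.
    """

    a: int = 25
    b: int = 12
    cells_per_type: int = 10
    p: int = 30
    q: int = 30
    d_true: int = 2
    within_type_sd: float = 0.05
    connectivity_noise_sd: float = 0.05
    contact_density: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.a, self.b, self.p, self.q, self.d_true) < 1:
            raise ValueError("all counts must be >= 1")
        if self.d_true > min(self.p, self.q):
            raise ValueError("d_true must be <= min(p, q)")
        if not (0 < self.contact_density <= 1):
            raise ValueError("contact_density must be in (0, 1]")


def _cells(counts, n_types: int):
    if np.isscalar(counts):
        return [int(counts)] * n_types
    counts = [int(c) for c in counts]
    if len(counts) != n_types:
        raise ValueError("cells_per_type list length must equal type count")
    return counts


def generate_bilinear_instance(s: SyntheticScenario, weight_mode: str = "contact"):
    """Generate a full cell-level bilinear-connectivity instance.

    Type-mean features are drawn once per type from a standard normal; cell
    features add Gaussian(0, within_type_sd) scatter.  True factors A*, B*
    are standard normal; Z = XA*(YB*)ᵀ plus Gaussian noise.  W is a Bernoulli
    contact mask at ``contact_density`` (``weight_mode='contact'``) or the
    1/(nᵢnⱼ) type-balance weights (``weight_mode='type_balance'``).

    Returns a dict with X, Y (CellFeatureMatrix), Z (ConnectivityMatrix),
    W (WeightMatrix), factors_true (BilinearFactors), Z_type_true (noiseless
    type-level connectivity from type-mean features) and the type labels.
    """
    rng = np.random.default_rng(s.seed)
    n_pre = _cells(s.cells_per_type, s.a)
    n_post = _cells(s.cells_per_type, s.b)

    mu_x = rng.standard_normal((s.a, s.p))
    mu_y = rng.standard_normal((s.b, s.q))
    X = np.vstack([mu_x[i] + s.within_type_sd * rng.standard_normal((n_pre[i], s.p))
                   for i in range(s.a)])
    Y = np.vstack([mu_y[j] + s.within_type_sd * rng.standard_normal((n_post[j], s.q))
                   for j in range(s.b)])
    pre_labels = [f"preT{i}" for i in range(s.a) for _ in range(n_pre[i])]
    post_labels = [f"postT{j}" for j in range(s.b) for _ in range(n_post[j])]

    A_true = rng.standard_normal((s.p, s.d_true))
    B_true = rng.standard_normal((s.q, s.d_true))
    Z_clean = (X @ A_true) @ (Y @ B_true).T
    Z = Z_clean + s.connectivity_noise_sd * rng.standard_normal(Z_clean.shape)

    if weight_mode == "contact":
        if s.contact_density >= 1.0:
            W = np.ones(Z.shape)
        else:
            W = (rng.random(Z.shape) < s.contact_density).astype(float)
    elif weight_mode == "type_balance":
        ni = np.repeat(n_pre, n_pre).astype(float)
        nj = np.repeat(n_post, n_post).astype(float)
        W = 1.0 / np.outer(ni, nj)
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")

    Z_type_true = (mu_x @ A_true) @ (mu_y @ B_true).T

    Xm = CellFeatureMatrix(X, cell_ids=[f"pre{i}" for i in range(len(X))],
                           type_labels=pre_labels)
    Ym = CellFeatureMatrix(Y, cell_ids=[f"post{i}" for i in range(len(Y))],
                           type_labels=post_labels)
    Zm = ConnectivityMatrix(Z, pre_ids=Xm.cell_ids, post_ids=Ym.cell_ids,
                            level="cell")
    return {
        "X": Xm,
        "Y": Ym,
        "Z": Zm,
        "W": WeightMatrix(W),
        "factors_true": BilinearFactors(A_true, B_true),
        "Z_type_true": ConnectivityMatrix(
            Z_type_true,
            pre_ids=[f"preT{i}" for i in range(s.a)],
            post_ids=[f"postT{j}" for j in range(s.b)],
            level="type"),
        "pre_labels": pre_labels,
        "post_labels": post_labels,
        "type_means_pre": mu_x,
        "type_means_post": mu_y,
    }


def generate_count_instance(n_types: int = 5, cells_per_type: int = 40,
                            n_genes: int = 200, n_hv_genes: int = 20,
                            library_size_range=(500, 2000),
                            effect_size: float = 3.0, base_rate: float = 5.0,
                            seed: int = 0):
    """Poisson count matrix with cell-size variation and planted HVGs.

    Every gene has a shared baseline rate; the ``n_hv_genes`` planted genes
    additionally carry a per-type multiplicative program (log-normal with
    scale ``effect_size``), making their variance exceed what their mean
    predicts.  Per-cell library-size factors are uniform over
    ``library_size_range``.  Returns (CountMatrix-compatible dict fields via
    preprocess.CountMatrix, planted gene-id list).
    """
    from .preprocess import CountMatrix

    if n_hv_genes > n_genes:
        raise ValueError("n_hv_genes must be <= n_genes")
    rng = np.random.default_rng(seed)
    n_cells = n_types * cells_per_type
    gene_ids = [f"g{m}" for m in range(n_genes)]
    planted = gene_ids[:n_hv_genes]

    rates = np.full((n_types, n_genes), base_rate)
    if n_hv_genes:
        programs = np.exp(effect_size * rng.standard_normal((n_types, n_hv_genes)))
        rates[:, :n_hv_genes] = base_rate * programs

    lo, hi = library_size_range
    lib = rng.uniform(lo, hi, size=n_cells)
    type_labels = [f"type{t}" for t in range(n_types) for _ in range(cells_per_type)]
    type_idx = np.repeat(np.arange(n_types), cells_per_type)

    cell_rates = rates[type_idx]                      # cells x genes
    cell_rates = cell_rates / cell_rates.sum(axis=1, keepdims=True)
    counts = rng.poisson(cell_rates * lib[:, None])
    cm = CountMatrix(counts,
                     cell_ids=[f"cell{i}" for i in range(n_cells)],
                     gene_ids=gene_ids, type_labels=type_labels)
    return cm, planted


def generate_stratification_profiles(n_types_pre: int = 5, n_types_post: int = 4,
                                     cells_per_type: int = 3,
                                     depth_grid: np.ndarray | None = None,
                                     bump_width: float = 0.05,
                                     center_jitter: float = 0.01,
                                     width_jitter: float = 0.005,
                                     seed: int = 0):
    """Museum-style JSON records of Gaussian-bump stratification profiles.

    Each type receives a bump center evenly spaced in [0.1, 0.9]; each cell
    jitters the center and width.  Records carry "cell id", "cell type",
    "cell class" and a "stratification" list of {"depth", "density"} points,
    so the parser is exercised end-to-end.  Returns (pre_records,
    post_records).
    """
    if depth_grid is None:
        depth_grid = DEFAULT_DEPTH_GRID
    rng = np.random.default_rng(seed)

    def make(side, n_types, cls):
        centers = np.linspace(0.1, 0.9, n_types)
        records = []
        for t in range(n_types):
            for c in range(cells_per_type):
                mu = float(np.clip(centers[t] + center_jitter * rng.standard_normal(),
                                   0.0, 1.0))
                sig = max(bump_width + width_jitter * rng.standard_normal(), 0.01)
                dens = np.exp(-0.5 * ((depth_grid - mu) / sig) ** 2)
                records.append({
                    "cell id": f"{side}_t{t}_c{c}",
                    "cell type": f"{side}T{t}",
                    "cell class": cls,
                    "stratification": [
                        {"depth": float(dg), "density": float(dv)}
                        for dg, dv in zip(depth_grid, dens)
                    ],
                })
        return records

    return make("pre", n_types_pre, "BC"), make("post", n_types_post, "RGC")
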