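"""Interpretation of the fitted latent space.

Each latent dimension is a connectivity motif: its rank-one reconstruction
shows which pre/post types it wires together, the latent coordinates place
types on the motif's positive or negative half, and back-projecting factor
columns through the PCA loadings and the 1/sigma scaling recovers gene-level
weights.  New transcriptomic types can be projected into the trained space
to rank candidate synaptic partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    BilinearFactors,
    ConnectivityMatrix,
    DimensionError,
    TypeFeatureMatrix,
)
from .model import predict_connectivity


def reconstruct_single_dimension(Xh: TypeFeatureMatrix, Yh: TypeFeatureMatrix,
                                 F: BilinearFactors, k: int) -> ConnectivityMatrix:
    """Rank-one reconstruction from latent dimension ``k`` (1-based).

    Uses only column k of each factor: (X̂aₖ)(Ŷbₖ)ᵀ.  Summing over all k
    recovers the full prediction exactly.
    """
    if not (1 <= k <= F.d):
        raise ValueError(f"latent dimension k={k} out of range 1..{F.d}")
    Fk = BilinearFactors(F.A[:, [k - 1]], F.B[:, [k - 1]])
    return predict_connectivity(Xh, Yh, Fk)


def latent_coordinates(Th: TypeFeatureMatrix, factor: np.ndarray) -> np.ndarray:
    """Project types into the latent space: rows of ``T̂ · factor``.

    The sign of each coordinate assigns the type to the positive or negative
    half of that motif (zero counts as positive), the grouping used when
    color-coding stratification profiles.
    """
    factor = np.asarray(factor, dtype=float)
    if Th.n_features != factor.shape[0]:
        raise DimensionError(
            f"factor has {factor.shape[0]} feature rows but type matrix has "
            f"{Th.n_features} features"
        )
    return Th.values @ factor


def half_groups(coords: np.ndarray, k: int) -> np.ndarray:
    """Boolean positive-half membership along latent dimension k (1-based);
    zero coordinates count as positive."""
    return coords[:, k - 1] >= 0


def gene_weight_backprojection(factor: np.ndarray, pca_loadings: np.ndarray,
                               pooled_sd: np.ndarray, gene_ids,
                               top_n: int = 50,
                               sd_floor: float = 1e-8) -> pd.DataFrame:
    """Back-project latent coefficients to gene-level weights and rank genes.

    The model operates on variance-normalized PC features, so the effective
    gene-space weight for latent dimension k is
    ``loadings · diag(1/max(sigma, floor)) · factor[:, k]``.
    Returns a table with, per dimension, the ``top_n`` genes by largest
    positive weight and the ``top_n`` by largest negative weight, ranked by
    |weight| within each (dimension, sign) block.
    """
    factor = np.asarray(factor, dtype=float)
    pca_loadings = np.asarray(pca_loadings, dtype=float)
    pooled_sd = np.asarray(pooled_sd, dtype=float)
    n_genes, n_pcs = pca_loadings.shape
    if factor.shape[0] != n_pcs:
        raise DimensionError(
            f"factor has {factor.shape[0]} PC rows but loadings have {n_pcs} PCs"
        )
    if pooled_sd.shape[0] != n_pcs:
        raise DimensionError(
            f"pooled_sd has {pooled_sd.shape[0]} entries but loadings have {n_pcs} PCs"
        )
    gene_ids = list(gene_ids)
    if len(gene_ids) != n_genes:
        raise DimensionError(
            f"{len(gene_ids)} gene ids for {n_genes} loading rows"
        )
    inv_sd = 1.0 / np.maximum(pooled_sd, sd_floor)
    gene_weights = pca_loadings @ (inv_sd[:, None] * factor)   # genes x d

    rows = []
    for k in range(factor.shape[1]):
        w = gene_weights[:, k]
        for sign, idx in (("positive", np.flatnonzero(w > 0)),
                          ("negative", np.flatnonzero(w < 0))):
            order = idx[np.argsort(-np.abs(w[idx]))][:top_n]
            for rank, g in enumerate(order, start=1):
                rows.append({"dimension": k + 1, "sign": sign,
                             "gene_id": gene_ids[g],
                             "weight": float(w[g]), "rank": rank})
    return pd.DataFrame(rows, columns=["dimension", "sign", "gene_id",
                                       "weight", "rank"])


@dataclass
class PartnerPrediction:
    """Predicted synaptic partners for one new (untrained) type."""

    new_type_id: str
    latent_coordinates: np.ndarray
    ranked_partners: list   # [(partner_type_id, predicted_connectivity), ...]


def predict_partners(new_types: TypeFeatureMatrix,
                     partner_types: TypeFeatureMatrix,
                     F: BilinearFactors, top_k: int = 3):
    """Rank candidate partners for types never seen in training.

    ``new_types`` must have been processed through the identical
    preprocessing chain (same HVGs, same PCA basis, same pooled sigma) as the
    training types; a feature-space mismatch raises a provenance error.  The
    new types are projected as Ŷ_new·B and partners ranked by the predicted
    connectivity column X̂A(Ŷ_new·B)ᵀ, ties broken by partner label order.
    """
    if new_types.n_features != F.B.shape[0]:
        raise DimensionError(
            f"new types carry {new_types.n_features} features but the trained "
            f"post-side factor expects {F.B.shape[0]}; the new types must be "
            "processed through the training PC basis"
        )
    if partner_types.n_features != F.A.shape[0]:
        raise DimensionError(
            f"partner types carry {partner_types.n_features} features but the "
            f"trained pre-side factor expects {F.A.shape[0]}"
        )
    coords_new = new_types.values @ F.B                     # new x d
    pred = (partner_types.values @ F.A) @ coords_new.T      # partners x new
    out = []
    for j, tid in enumerate(new_types.type_ids):
        col = pred[:, j]
        order = sorted(range(len(col)),
                       key=lambda i: (-col[i], str(partner_types.type_ids[i])))
        top = [(partner_types.type_ids[i], float(col[i]))
               for i in order[:top_k]]
        out.append(PartnerPrediction(
            new_type_id=tid,
            latent_coordinates=coords_new[j].copy(),
            ranked_partners=top,
        ))
    return out
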