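"""Connectivity-matrix construction from connectomic inputs.

Retina route: EM-reconstruction stratification profiles (linear density of
voxel volume vs normalized inner-plexiform-layer depth) are turned into a
cell-level connectivity proxy via cosine similarity, standardized, and
averaged into a type-level matrix.  C. elegans route: a binary physical-
contact mask becomes the loss weight matrix directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import ConnectivityMatrix, DimensionError, WeightMatrix

logger = logging.getLogger(__name__)

#: Common normalized-IPL-depth grid profiles are resampled to.
DEFAULT_DEPTH_GRID = np.linspace(0.0, 1.0, 120)

#: Landmark depths used only for reporting/grouping, not computation:
#: OFF and ON starburst-amacrine laminae, and the outer/inner IPL boundary.
SAC_DEPTHS = (0.28, 0.62)
OUTER_INNER_BOUNDARY = 0.47


@dataclass
class StratificationProfile:
    """A cell's voxel-volume density over normalized IPL depth."""

    cell_id: str
    cell_type: str
    density: np.ndarray
    depth_grid: np.ndarray
    cell_class: str = ""

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        if self.density.shape != self.depth_grid.shape:
            raise DimensionError(
                f"profile {self.cell_id}: density and depth grid lengths differ"
            )
        if np.any(self.density < 0):
            raise ValueError(f"profile {self.cell_id}: negative density")
        if not np.any(self.density > 0):
            raise ValueError(f"profile {self.cell_id}: all-zero density")


def cosine_profile_similarity(u: StratificationProfile,
                              v: StratificationProfile) -> float:
    """Cosine similarity of two stratification profiles.

    Profiles must share a depth grid (resample upstream).  For nonnegative
    densities the value lies in [0, 1]: 1 for co-stratifying cells, 0 for
    disjoint laminae — the proxy used for synaptic connectivity.
    """
    if u.depth_grid.shape != v.depth_grid.shape or \
            not np.allclose(u.depth_grid, v.depth_grid):
        raise DimensionError(
            f"profiles {u.cell_id} and {v.cell_id} are on different depth grids"
        )
    nu = np.linalg.norm(u.density)
    nv = np.linalg.norm(v.density)
    if nu == 0:
        raise ValueError(f"zero-norm stratification profile for cell {u.cell_id}")
    if nv == 0:
        raise ValueError(f"zero-norm stratification profile for cell {v.cell_id}")
    return float(u.density @ v.density / (nu * nv))


def build_cell_connectivity(profiles_pre, profiles_post) -> ConnectivityMatrix:
    """Pairwise cosine-similarity matrix between pre and post cell profiles."""
    if not profiles_pre or not profiles_post:
        raise ValueError("need at least one profile on each side")
    U = np.stack([p.density for p in profiles_pre])
    V = np.stack([p.density for p in profiles_post])
    if U.shape[1] != V.shape[1]:
        raise DimensionError("pre and post profiles are on different depth grids")
    nu = np.linalg.norm(U, axis=1)
    nv = np.linalg.norm(V, axis=1)
    for p, n in zip(list(profiles_pre) + list(profiles_post),
                    np.concatenate([nu, nv])):
        if n == 0:
            raise ValueError(f"zero-norm stratification profile for cell {p.cell_id}")
    vals = (U @ V.T) / np.outer(nu, nv)
    return ConnectivityMatrix(
        vals,
        pre_ids=[p.cell_id for p in profiles_pre],
        post_ids=[p.cell_id for p in profiles_post],
        level="cell",
    )


def standardize_connectivity(Z: ConnectivityMatrix) -> ConnectivityMatrix:
    """Center and scale to entrywise mean 0 / population SD 1.

    Standardization lets the connectivity metric take both signs, which the
    bilinear inner product requires.
    """
    if Z.values.size < 2:
        raise ValueError("need at least 2 entries to standardize")
    sd = Z.values.std()
    if sd == 0:
        raise ValueError("connectivity matrix has zero variance; cannot standardize")
    vals = (Z.values - Z.values.mean()) / sd
    return ConnectivityMatrix(vals, pre_ids=list(Z.pre_ids),
                              post_ids=list(Z.post_ids), level=Z.level)


def average_by_type(Z: ConnectivityMatrix, pre_labels, post_labels) -> ConnectivityMatrix:
    """Type-level matrix of cell-pair means, z̄ᵢⱼ = mean over cells of type
    pair (i, j)."""
    pre_labels = list(pre_labels)
    post_labels = list(post_labels)
    if len(pre_labels) != Z.shape[0] or len(post_labels) != Z.shape[1]:
        raise ValueError("every cell on both axes must carry a type label")
    if any(l is None or l == "" for l in pre_labels + post_labels):
        raise ValueError("unlabeled cell encountered")

    def order(labels):
        seen: dict = {}
        for l in labels:
            seen.setdefault(l, None)
        return list(seen)

    pre_types = order(pre_labels)
    post_types = order(post_labels)
    pre_arr = np.asarray(pre_labels, dtype=object)
    post_arr = np.asarray(post_labels, dtype=object)
    out = np.empty((len(pre_types), len(post_types)))
    for i, ti in enumerate(pre_types):
        rows = Z.values[pre_arr == ti]
        for j, tj in enumerate(post_types):
            out[i, j] = rows[:, post_arr == tj].mean()
    return ConnectivityMatrix(out, pre_ids=pre_types, post_ids=post_types,
                              level="type")


@dataclass
class ContactMask:
    """Binary physical-contact indicator over cell pairs."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise DimensionError("ContactMask must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("ContactMask entries must be 0 or 1")


def assemble_weight_matrix(mode: str, mask: ContactMask | None = None,
                           pre_labels=None, post_labels=None) -> WeightMatrix:
    """Build the loss weight matrix W.

    ``contact`` mode returns the 0/1 physical-contact mask (pairs without
    contact are excluded from the fit).  ``type_balance`` mode returns
    w = 1/(nᵢnⱼ) per cell pair, so each type pair contributes equally
    regardless of how many cells it contains.
    """
    if mode == "contact":
        if mask is None:
            raise ValueError("contact mode requires a ContactMask")
        return WeightMatrix(mask.values.astype(float))
    if mode == "type_balance":
        if pre_labels is None or post_labels is None:
            raise ValueError("type_balance mode requires pre and post labels")
        pre_labels = list(pre_labels)
        post_labels = list(post_labels)
        pre_counts = {t: pre_labels.count(t) for t in set(pre_labels)}
        post_counts = {t: post_labels.count(t) for t in set(post_labels)}
        ni = np.array([pre_counts[t] for t in pre_labels], dtype=float)
        nj = np.array([post_counts[t] for t in post_labels], dtype=float)
        return WeightMatrix(1.0 / np.outer(ni, nj))
    raise ValueError(f"unknown mode {mode!r}; use 'contact' or 'type_balance'")


_REQUIRED_KEYS = ("cell id", "cell type", "cell class", "stratification")


def parse_stratification_records(records,
                                 depth_grid: np.ndarray | None = None):
    """Parse museum-style JSON records into StratificationProfiles.

    Each record is a mapping with "cell id", "cell type", "cell class" and a
    "stratification" list of {"depth", "density"} points.  Profiles are
    linearly resampled onto the common ``depth_grid`` (default 120 points on
    [0, 1]); records with missing or empty stratification are skipped with a
    warning.  Returns (profiles, n_skipped).
    """
    if depth_grid is None:
        depth_grid = DEFAULT_DEPTH_GRID
    profiles = []
    n_skipped = 0
    for idx, rec in enumerate(records):
        if not isinstance(rec, dict):
            raise ValueError(f"record {idx}: not a JSON object")
        strat = rec.get("stratification")
        if not strat:
            n_skipped += 1
            logger.warning("record %d (%s): missing/empty stratification, skipped",
                           idx, rec.get("cell id", "?"))
            continue
        for key in ("cell id", "cell type"):
            if key not in rec:
                raise ValueError(f"record {idx}: missing attribute {key!r}")
        try:
            depths = np.array([float(pt["depth"]) for pt in strat])
            dens = np.array([float(pt["density"]) for pt in strat])
        except (TypeError, KeyError) as exc:
            raise ValueError(f"record {idx}: malformed stratification: {exc}") from exc
        order = np.argsort(depths)
        resampled = np.interp(depth_grid, depths[order], dens[order],
                              left=0.0, right=0.0)
        if not np.any(resampled > 0):
            n_skipped += 1
            logger.warning("record %d (%s): profile vanishes on target grid, skipped",
                           idx, rec.get("cell id", "?"))
            continue
        profiles.append(StratificationProfile(
            cell_id=str(rec["cell id"]),
            cell_type=str(rec["cell type"]),
            cell_class=str(rec.get("cell class", "")),
            density=resampled,
            depth_grid=depth_grid.copy(),
        ))
    return profiles, n_skipped
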