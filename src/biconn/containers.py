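"""Labeled matrix containers shared across the package.

These are thin dataclasses around numpy arrays plus axis labels.  They keep
cell/type/feature identity attached to the numbers so that downstream steps
(type averaging, alignment with a connectivity matrix, partner ranking) can
be checked instead of trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


class DimensionError(ValueError):
    """Raised when matrix shapes do not conform; message names the axes."""


def _as_labels(labels: Sequence, n: int, what: str) -> list:
    labels = list(labels)
    if len(labels) != n:
        raise DimensionError(
            f"{what}: got {len(labels)} labels for {n} rows/columns"
        )
    return labels


@dataclass
class CellFeatureMatrix:
    """Cells x features expression matrix with per-cell type labels.

    ``values`` holds unitless expression features (log-normalized counts, or
    PC scores after reduction); every cell carries exactly one type label.
    """

    values: np.ndarray
    cell_ids: list = field(default_factory=list)
    type_labels: list = field(default_factory=list)
    feature_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("CellFeatureMatrix.values must be 2-D")
        n, p = self.values.shape
        if p < 1:
            raise DimensionError("CellFeatureMatrix needs at least one feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CellFeatureMatrix contains non-finite values")
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(n)]
        if not self.type_labels:
            self.type_labels = ["type0"] * n
        if not self.feature_ids:
            self.feature_ids = [f"f{m}" for m in range(p)]
        self.cell_ids = _as_labels(self.cell_ids, n, "cell_ids")
        self.type_labels = _as_labels(self.type_labels, n, "type_labels")
        self.feature_ids = _as_labels(self.feature_ids, p, "feature_ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def type_order(self) -> list:
        """Unique type labels in first-appearance order."""
        seen: dict = {}
        for t in self.type_labels:
            seen.setdefault(t, None)
        return list(seen)


@dataclass
class TypeFeatureMatrix:
    """Types x features matrix (type means, optionally 1/sigma-normalized)."""

    values: np.ndarray
    type_ids: list = field(default_factory=list)
    feature_ids: list = field(default_factory=list)
    scale_applied: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("TypeFeatureMatrix.values must be 2-D")
        a, p = self.values.shape
        if not self.type_ids:
            self.type_ids = [f"type{i}" for i in range(a)]
        if not self.feature_ids:
            self.feature_ids = [f"f{m}" for m in range(p)]
        self.type_ids = _as_labels(self.type_ids, a, "type_ids")
        self.feature_ids = _as_labels(self.feature_ids, p, "feature_ids")

    @property
    def n_types(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Real-valued pre x post connectivity, at cell or type level."""

    values: np.ndarray
    pre_ids: list = field(default_factory=list)
    post_ids: list = field(default_factory=list)
    level: str = "cell"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("ConnectivityMatrix.values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ConnectivityMatrix contains non-finite entries")
        n, m = self.values.shape
        if not self.pre_ids:
            self.pre_ids = [f"pre{i}" for i in range(n)]
        if not self.post_ids:
            self.post_ids = [f"post{j}" for j in range(m)]
        self.pre_ids = _as_labels(self.pre_ids, n, "pre_ids")
        self.post_ids = _as_labels(self.post_ids, m, "post_ids")
        if len(set(self.pre_ids)) != n or len(set(self.post_ids)) != m:
            raise ValueError("ConnectivityMatrix axis labels must be unique")
        if self.level not in ("cell", "type"):
            raise ValueError("level must be 'cell' or 'type'")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class WeightMatrix:
    """Nonnegative loss weights over cell pairs; zeros exclude pairs."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("WeightMatrix.values must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("WeightMatrix entries must be >= 0")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class BilinearFactors:
    """Pair of feature-to-latent transforms A (p x d) and B (q x d)."""

    A: np.ndarray
    B: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.ndim != 2 or self.B.ndim != 2:
            raise DimensionError("factors must be 2-D matrices")
        if self.A.shape[1] != self.B.shape[1]:
            raise DimensionError(
                f"A has {self.A.shape[1]} latent columns but B has "
                f"{self.B.shape[1]}; they must share d"
            )
        if self.A.shape[1] < 1:
            raise DimensionError("latent dimension d must be >= 1")

    @property
    def d(self) -> int:
        return self.A.shape[1]


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters for the alternating-gradient-descent fit.

    ``lambda_A``/``lambda_B`` default to a single consolidated ridge strength
    ``lam``; pass them explicitly for unequal regularization.  With
    ``adaptive`` (the default) each factor's step size is chosen by an exact
    line search along its gradient; with ``adaptive=False`` the fixed
    ``learning_rate`` is used instead.
    """

    d: int = 2
    learning_rate: float = 1e-3
    lambda_A: float = 0.0
    lambda_B: float = 0.0
    tol: float = 1e-6
    max_iter: int = 1_000_000
    seed: int = 0
    adaptive: bool = True

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.lambda_A < 0 or self.lambda_B < 0:
            raise ValueError("regularization strengths must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @classmethod
    def with_lambda(cls, lam: float, **kwargs) -> "FitConfig":
        """Single consolidated ridge knob lambda_A = lambda_B = lam."""
        return cls(lambda_A=lam, lambda_B=lam, **kwargs)


@dataclass
class FitResult:
    """Outcome of fit_agd: factors, loss trajectory and convergence state."""

    factors: BilinearFactors
    loss_trajectory: np.ndarray
    converged: bool
    n_iter: int
    config: FitConfig

    def __post_init__(self):
        self.loss_trajectory = np.asarray(self.loss_trajectory, dtype=float)
        if self.loss_trajectory.size == 0:
            raise ValueError("loss_trajectory must be nonempty")


def check_shapes(X: CellFeatureMatrix, Y: CellFeatureMatrix,
                 Z: ConnectivityMatrix, W: WeightMatrix | None,
                 F: BilinearFactors) -> None:
    """Validate that a cellwise (X, Y, Z, W, factors) bundle conforms."""
    if Z.shape != (X.n_cells, Y.n_cells):
        raise DimensionError(
            f"Z is {Z.shape} but X has {X.n_cells} cells (pre axis) and "
            f"Y has {Y.n_cells} cells (post axis)"
        )
    if W is not None and W.shape != Z.shape:
        raise DimensionError(f"W is {W.shape} but Z is {Z.shape}")
    if F.A.shape[0] != X.n_features:
        raise DimensionError(
            f"A has {F.A.shape[0]} feature rows but X has {X.n_features} features"
        )
    if F.B.shape[0] != Y.n_features:
        raise DimensionError(
            f"B has {F.B.shape[0]} feature rows but Y has {Y.n_features} features"
        )


def check_shapes_typewise(Xh: TypeFeatureMatrix, Yh: TypeFeatureMatrix,
                          Zbar: ConnectivityMatrix, F: BilinearFactors) -> None:
    """Validate a typewise (Xh, Yh, Zbar, factors) bundle."""
    if Zbar.shape != (Xh.n_types, Yh.n_types):
        raise DimensionError(
            f"Zbar is {Zbar.shape} but Xh has {Xh.n_types} types (pre axis) "
            f"and Yh has {Yh.n_types} types (post axis)"
        )
    if F.A.shape[0] != Xh.n_features:
        raise DimensionError(
            f"A has {F.A.shape[0]} feature rows but Xh has {Xh.n_features} features"
        )
    if F.B.shape[0] != Yh.n_features:
        raise DimensionError(
            f"B has {F.B.shape[0]} feature rows but Yh has {Yh.n_features} features"
        )


def copy_factors(F: BilinearFactors) -> BilinearFactors:
    return BilinearFactors(F.A.copy(), F.B.copy())


__all__ = [
    "DimensionError",
    "CellFeatureMatrix",
    "TypeFeatureMatrix",
    "ConnectivityMatrix",
    "WeightMatrix",
    "BilinearFactors",
    "FitConfig",
    "FitResult",
    "check_shapes",
    "check_shapes_typewise",
    "copy_factors",
    "replace",
]
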