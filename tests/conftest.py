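import numpy as np
import pytest

from biconn.containers import (
    BilinearFactors,
    CellFeatureMatrix,
    ConnectivityMatrix,
    TypeFeatureMatrix,
    WeightMatrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cellwise(rng):
    """Random 4-cell x 3-cell instance with p=3, q=2 features and d=2."""
    X = CellFeatureMatrix(rng.standard_normal((4, 3)))
    Y = CellFeatureMatrix(rng.standard_normal((3, 2)))
    Z = ConnectivityMatrix(rng.standard_normal((4, 3)))
    W = WeightMatrix(rng.uniform(0, 1, (4, 3)))
    F = BilinearFactors(rng.standard_normal((3, 2)), rng.standard_normal((2, 2)))
    return X, Y, Z, W, F


@pytest.fixture
def small_typewise(rng):
    """Random 3-type x 2-type instance with p=4, q=3 features and d=2."""
    Xh = TypeFeatureMatrix(rng.standard_normal((3, 4)))
    Yh = TypeFeatureMatrix(rng.standard_normal((2, 3)))
    Zb = ConnectivityMatrix(rng.standard_normal((3, 2)))
    F = BilinearFactors(rng.standard_normal((4, 2)), rng.standard_normal((3, 2)))
    return Xh, Yh, Zb, F
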