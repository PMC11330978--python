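import numpy as np
import pytest

from stcomm.data_model import (CellTypeAnnotation, ExpressionMatrix,
                               Resolution, SpatialDataset)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_counts(rng):
    """5 genes x 4 cells integer count matrix."""
    vals = rng.integers(0, 20, size=(5, 4)).astype(float)
    return ExpressionMatrix(vals, [f"g{i}" for i in range(5)],
                            [f"c{i}" for i in range(4)])


@pytest.fixture
def grid_spots():
    """4 spots on a 2x2 grid at 100 um pitch."""
    vals = np.arange(12, dtype=float).reshape(3, 4)
    expr = ExpressionMatrix(vals, ["g0", "g1", "g2"],
                            ["s0", "s1", "s2", "s3"])
    coords = np.array([[0, 0], [100, 0], [0, 100], [100, 100]], dtype=float)
    return SpatialDataset(expr, coords, Resolution.spot)


@pytest.fixture
def two_type_annotation():
    return CellTypeAnnotation({"c0": "A", "c1": "A", "c2": "B", "c3": "B"},
                              type_order=["A", "B"])
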