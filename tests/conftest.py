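import numpy as np
import pytest

from mgw import SpatialDataset, SyntheticSpec, fit_field, make_pair
from mgw.datamodel import FieldConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """Small architecture for fast unit tests."""
    return FieldConfig(hidden_width=32, hidden_layers=2, epochs=200, seed=0)


@pytest.fixture
def small_pair():
    """64-point paired slices, shared features only."""
    spec = SyntheticSpec(n_points=64, grid="uniform_random",
                         n_independent_features=0, seed=5)
    return make_pair(spec)


@pytest.fixture(scope="session")
def trained_field():
    """A field trained once on a smooth 2-D dataset, reused across tests."""
    rng = np.random.default_rng(42)
    coords = rng.uniform(0.0, 1.0, (256, 2))
    X = np.column_stack([
        np.sin(3.0 * coords[:, 0]) + 0.5 * coords[:, 1],
        np.cos(2.0 * coords[:, 1]),
        coords[:, 0] * coords[:, 1],
    ])
    ds = SpatialDataset(coords, X)
    cfg = FieldConfig(hidden_width=64, hidden_layers=2, epochs=400, seed=3)
    return fit_field(ds, cfg), ds
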