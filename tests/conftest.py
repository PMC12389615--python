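import numpy as np
import pytest

from nppkit.raster import Grid, GridTransform
from nppkit.synth import ScenarioConfig


@pytest.fixture
def transform_500m() -> GridTransform:
    return GridTransform(1_000_000.0, 5_000_000.0, 500.0, 500.0)


@pytest.fixture
def small_grid(transform_500m) -> Grid:
    values = np.arange(100, dtype=np.float32).reshape(10, 10)
    return Grid(values, transform_500m)


@pytest.fixture
def tiny_cfg() -> ScenarioConfig:
    """Small, fast scenario for structural tests."""
    return ScenarioConfig(shape=(24, 24), year_start=2001, year_end=2006, seed=42)


def make_grid(values, transform=None, mask=None, crs="EPSG:3395") -> Grid:
    values = np.asarray(values)
    if transform is None:
        transform = GridTransform(0.0, float(values.shape[0]) * 500.0, 500.0, 500.0)
    return Grid(values, transform, mask, crs)
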