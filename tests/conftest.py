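import numpy as np
import pandas as pd
import pytest

from deltaclue.grid import CategoricalRaster, ContinuousRaster, GridSpec
from deltaclue.stack import DriverStack
from deltaclue.synth import make_world


@pytest.fixture
def spec2():
    return GridSpec(ncols=2, nrows=2, cellsize=1000.0)


@pytest.fixture
def spec10():
    return GridSpec(ncols=10, nrows=10, cellsize=1000.0)


@pytest.fixture(scope="session")
def world():
    """A 50x50 synthetic study region shared by read-only tests."""
    return make_world(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def raster_from(spec, rows, categorical=True, name="x"):
    arr = np.asarray(rows)
    if categorical:
        return CategoricalRaster(spec, arr.astype(np.int64))
    return ContinuousRaster(spec, arr.astype(float), name=name)


@pytest.fixture
def toy_maps(spec2):
    """2x2 prediction/reference pair with one disagreement (A=0, B=1)."""
    pred = raster_from(spec2, [[0, 0], [1, 1]])
    ref = raster_from(spec2, [[0, 1], [1, 1]])
    return pred, ref


def stack_from(spec, arrays: dict) -> DriverStack:
    s = DriverStack(spec)
    for name, arr in arrays.items():
        s.add(ContinuousRaster(spec, np.asarray(arr, dtype=float), name=name))
    return s
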