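import numpy as np
import pytest

from watercolumn.benchmark import run_intercomparison
from watercolumn.forward_models import (
    BOTTOM_LABELS,
    deep_water_reflectance,
    make_bottom,
)
from watercolumn.optics_core import Geometry, WATER_TYPES, build_iops


@pytest.fixture(scope="session")
def grid():
    """5-nm working grid for unit tests (fast; shape-preserving)."""
    return np.arange(400.0, 701.0, 5.0)


@pytest.fixture(scope="session")
def geom():
    return Geometry()


@pytest.fixture(scope="session")
def bottoms(grid):
    return {lbl: make_bottom(lbl, grid) for lbl in BOTTOM_LABELS}


@pytest.fixture(scope="session")
def iops_by_water(grid, geom):
    return {name: build_iops(w, geom, grid) for name, w in WATER_TYPES.items()}


@pytest.fixture(scope="session")
def deep_by_water(iops_by_water):
    return {name: deep_water_reflectance(iops) for name, iops in iops_by_water.items()}


@pytest.fixture(scope="session")
def intercomparison_report():
    """The canonical end-to-end run (1-nm grid, 25 noise seeds), computed once."""
    return run_intercomparison(seed=1, n_seeds=25, grid=np.arange(400.0, 701.0))
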