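import numpy as np
import pytest
from hypothesis import settings

from penrate.geometry import ArrayGeometry, SkinModel, SolverConfig
from penrate.solver import discretize
from penrate.stats import sweep_pair

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

COARSE = SolverConfig(voxel_size=100.0)


@pytest.fixture(scope="session")
def grid_3x3():
    """Coarse-resolution grid of the default 3x3 array (shared: read-only)."""
    return discretize(ArrayGeometry.square(3), SkinModel(), COARSE)


@pytest.fixture(scope="session")
def grid_2x3():
    """Two-sheet grid: mirror-symmetric about the tested pair's midplane."""
    return discretize(
        ArrayGeometry(n_sheets=2, tips_per_sheet=3), SkinModel(), COARSE
    )


@pytest.fixture(scope="session")
def sweep_ab(grid_3x3):
    """Exhaustive 64-combination sweep of the adjacent pair A-B."""
    return sweep_pair(grid_3x3, 0, 1)


@pytest.fixture(scope="session")
def sweep_ac(grid_3x3):
    """Exhaustive 64-combination sweep of the distant pair A-C."""
    return sweep_pair(grid_3x3, 0, 2)
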