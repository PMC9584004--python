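import numpy as np
import pytest

from charcoalscape import DemGrid, slope
from charcoalscape.morphology import disc_element, grayscale_closing
from charcoalscape.synthetic import TerrainScenario, generate_dtm


@pytest.fixture(scope="session")
def small_scene():
    """A compact hillslope scenario shared across detection tests: 8
    platforms and 18 confusers on a 300 m square at 0.5 m cells."""
    scenario = TerrainScenario(
        extent_m=(300.0, 300.0), n_platforms=8, n_confusers=18, seed=42
    )
    dem, truths = generate_dtm(scenario)
    slope_grid = slope(dem)
    closed = grayscale_closing(slope_grid, disc_element(7))
    return {
        "scenario": scenario,
        "dem": dem,
        "truths": truths,
        "slope": slope_grid,
        "closed": closed,
    }


@pytest.fixture
def ramp_grid():
    """Plane z = 0.5 x at 1 m cells (slope arctan 0.5 everywhere)."""
    vals = np.fromfunction(lambda i, j: 0.5 * j, (24, 24))
    return DemGrid(vals, cell_size_m=1.0)
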