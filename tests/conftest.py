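import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from portair import (
    GridSpec,
    assemble_inventory,
    generate_factor_fixtures,
    generate_grid,
    generate_source_layout,
    generate_sr_matrix,
    generate_tracts,
)
from portair.inventory import (
    LayerSpec,
    build_direct_inventory,
    build_embodied_inventory,
)


@pytest.fixture(scope="session")
def tracts():
    return generate_tracts(n_tracts=60, seed=7)


@pytest.fixture(scope="session")
def grid(tracts):
    return generate_grid(tracts, coarse_size=10_000.0, refine=2)


@pytest.fixture(scope="session")
def srm(grid):
    return generate_sr_matrix(grid, seed=7)


@pytest.fixture(scope="session")
def layout():
    return generate_source_layout(seed=7)


@pytest.fixture(scope="session")
def factors():
    return generate_factor_fixtures(seed=7)


@pytest.fixture(scope="session")
def inventory(layout, grid, factors):
    direct = build_direct_inventory(layout, grid, factors["trucks"].loc["diesel_current"])
    embodied = build_embodied_inventory(
        LayerSpec(resurfacing_fraction=0.05), layout, factors, grid
    )
    return assemble_inventory(direct, embodied)


@pytest.fixture
def two_cell_grid():
    """Two unit-km cells side by side: [0,1000]x[0,1000] and [1000,2000]x[0,1000]."""
    cells = pd.DataFrame(
        {
            "cell_id": ["A", "B"],
            "geometry": [box(0, 0, 1000, 1000), box(1000, 0, 2000, 1000)],
            "res_class": ["fine", "fine"],
        }
    )
    return GridSpec(cells)
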