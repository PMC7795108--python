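import numpy as np
import pytest

import medaccess as m


@pytest.fixture(scope="session")
def fixture_region():
    return m.fixture_minimal()


@pytest.fixture(scope="session")
def fixture_time_costs(fixture_region):
    return m.cost_matrix(fixture_region.cells, fixture_region.facilities,
                         fixture_region.network, metric=m.TIME_METRIC)


@pytest.fixture(scope="session")
def fixture_space_costs(fixture_region):
    return m.cost_matrix(fixture_region.cells, fixture_region.facilities,
                         fixture_region.network, metric=m.SPACE_METRIC)


@pytest.fixture(scope="session")
def small_config():
    return m.RegionConfig(
        extent_km=50.0,
        cell_km=5.0,
        n_cities=2,
        capital_index=0,
        facility_counts={"primary": 10, "secondary": 4, "tertiary": 2},
        population_total=100_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_region(small_config):
    return m.generate_region(small_config)


def random_cost_instance(rng, n_cells=30, n_fac=5, d0=120.0):
    """Random 2SFCA instance where every facility has in-catchment demand."""
    costs = rng.uniform(2.0, d0 * 0.9, size=(n_cells, n_fac))
    # push some pairs out of range but keep row 0 (populated) inside
    far = rng.random((n_cells, n_fac)) < 0.2
    far[0, :] = False
    costs = np.where(far, d0 * 1.5, costs)
    cells = [
        m.DemandCell(id=i, x=0.0, y=0.0, population=float(rng.integers(1, 500)))
        for i in range(n_cells)
    ]
    levels = ["primary", "secondary", "tertiary"]
    facilities = [
        m.Facility(id=j, x=0.0, y=0.0, level=levels[j % 3],
                   staff=float(rng.uniform(5, 300)))
        for j in range(n_fac)
    ]
    matrix = m.TravelCostMatrix(
        [c.id for c in cells], [f.id for f in facilities], costs,
        m.TIME_METRIC, rail_used=False,
    )
    return matrix, cells, facilities
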