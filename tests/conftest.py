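import numpy as np
import pytest
from shapely.geometry import Polygon

import reefdrift as rd

M_PER_DEG = rd.EARTH_RADIUS_M * np.pi / 180.0


def box_polygon(lon_c, lat_c, width_km, height_km):
    """Axis-aligned lon/lat rectangle of the given metric size."""
    dlon = width_km * 1e3 / 2.0 / (M_PER_DEG * np.cos(np.deg2rad(lat_c)))
    dlat = height_km * 1e3 / 2.0 / M_PER_DEG
    return Polygon([
        (lon_c - dlon, lat_c - dlat), (lon_c + dlon, lat_c - dlat),
        (lon_c + dlon, lat_c + dlat), (lon_c - dlon, lat_c + dlat),
    ])


@pytest.fixture(scope="session")
def coast():
    return rd.default_coast()


@pytest.fixture(scope="session")
def daily_times():
    return np.datetime64("2000-02-01") + np.arange(12) * np.timedelta64(1, "D")


@pytest.fixture
def open_ocean_grid(daily_times):
    """Small all-ocean grid centred on the equator."""
    return rd.GridSpec(0.0, 4.0, 1 / 24, -0.5, 0.5, 1 / 24, daily_times)


def uniform_field(grid, u, v=0.0):
    spec = rd.ScenarioSpec((rd.Component(rd.UniformDrift(u, v)),), coast=None,
                           lon_ref=grid.lon_center, lat_ref=grid.lat_center)
    return rd.velocity_field(spec, grid)


@pytest.fixture(scope="session")
def study_grid():
    return rd.default_grid()


@pytest.fixture(scope="session")
def study_reefs(coast, study_grid):
    return rd.generate_reefs(coast, n_per_complex=4, rng_seed=7, grid=study_grid)
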