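import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import paleocorridor as pc

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=25)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def landscape():
    """Default synthetic landscape: params, DEM, barrier scenario, sites."""
    params = pc.LandscapeParams()
    dem, scenario, sites = pc.generate_landscape(params)
    return params, dem, scenario, sites


@pytest.fixture(scope="session")
def slope_grid(landscape):
    _, dem, _, _ = landscape
    return pc.compute_slope(dem)


def _route(dem, slope, scenario, sites, start, end, apply_band):
    scen = replace(scenario, apply_band=apply_band)
    blocked = pc.build_scenario_mask(dem, scen)
    cost = pc.build_cost_surface(slope, blocked, scenario_name=scen.name)
    s, e = sites.get(start), sites.get(end)
    return pc.least_cost_path(cost, (float(s["lon"]), float(s["lat"])),
                              (float(e["lon"]), float(e["lat"])),
                              start_name=start, end_name=end)


@pytest.fixture(scope="session")
def northern_route(landscape, slope_grid):
    """Continental-scale route from the NW start, suitability band off."""
    _, dem, scenario, sites = landscape
    return _route(dem, slope_grid, scenario, sites,
                  "NW-Piedmont-Cave", "East-End-Cave", apply_band=False)


@pytest.fixture(scope="session")
def southern_route(landscape, slope_grid):
    """Corridor route from the SW start, traced within the suitability band."""
    _, dem, scenario, sites = landscape
    return _route(dem, slope_grid, scenario, sites,
                  "SW-Foothill-Cave", "East-End-Cave", apply_band=True)


@pytest.fixture()
def flat_grid():
    """5x5 flat DEM near the equator with well-conditioned geometry."""
    return pc.GeoGrid(values=np.full((5, 5), 100.0), x_origin=10.0, y_origin=1.0,
                      cell_size=0.1)


def make_cost(values, x_origin=0.0, y_origin=0.0, cell_size=0.1, name="test"):
    """CostSurface straight from a value array (bypasses slope derivation)."""
    grid = pc.GeoGrid(values=np.asarray(values, dtype=float), x_origin=x_origin,
                      y_origin=y_origin, cell_size=cell_size)
    return pc.CostSurface(grid=grid, scenario_name=name)
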