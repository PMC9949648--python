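import numpy as np
import pytest

import paleocorridor as pc
from paleocorridor.geodesy import EARTH_RADIUS_KM, haversine_km

from conftest import make_cost
from oracles import bellman_ford_cost

# cell size whose east-west spacing at the equator is exactly 1 km
KM_CELL_DEG = float(np.degrees(1.0 / EARTH_RADIUS_KM))


def km_lattice_cost(values, y_origin=None):
    """CostSurface on an equator-centred lattice with ~1 km cell spacing."""
    values = np.asarray(values, dtype=float)
    n_rows = values.shape[0]
    y0 = y_origin if y_origin is not None else n_rows * KM_CELL_DEG / 2.0
    return make_cost(values, x_origin=0.0, y_origin=y0, cell_size=KM_CELL_DEG)


# ---------------------------------------------------------------------------
# cost surface construction
# ---------------------------------------------------------------------------

def test_flat_terrain_costs_one(flat_grid):
    slope = pc.compute_slope(flat_grid, "unit-cell")
    blocked = flat_grid.with_values(np.zeros(flat_grid.shape), nodata=-1.0)
    cost = pc.build_cost_surface(slope, blocked, k_slope=0.7)
    interior = cost.values[1:-1, 1:-1]
    np.testing.assert_allclose(interior, 1.0)
    assert np.isinf(cost.values[0, 0])  # border slope is nodata


def test_linear_slope_cost():
    """slope 30 deg with k=1 -> cost 31."""
    grid = pc.GeoGrid(values=np.full((3, 3), 30.0), x_origin=0, y_origin=1,
                      cell_size=0.1)
    blocked = grid.with_values(np.zeros((3, 3)), nodata=-1.0)
    cost = pc.build_cost_surface(grid, blocked, k_slope=1.0)
    assert cost.values[1, 1] == pytest.approx(31.0)


def test_blocked_cells_are_infinite_regardless_of_slope():
    grid = pc.GeoGrid(values=np.zeros((4, 4)), x_origin=0, y_origin=2, cell_size=0.5)
    desert = pc.polygon_mask(grid, [[(0.9, 0.4), (1.6, 0.4), (1.6, 1.1), (0.9, 1.1),
                                     (0.9, 0.4)]])
    cost = pc.build_cost_surface(grid, desert, k_slope=0.1)
    assert np.isinf(cost.values).sum() == pc.mask_array(desert).sum() > 0
    assert (cost.values[~pc.mask_array(desert)] >= 1.0).all()


def test_negative_k_slope_rejected(flat_grid):
    slope = pc.compute_slope(flat_grid, "unit-cell")
    blocked = flat_grid.with_values(np.zeros(flat_grid.shape), nodata=-1.0)
    with pytest.raises(pc.ParameterError):
        pc.build_cost_surface(slope, blocked, k_slope=-0.1)


def test_desert_cost_multiplier_softens_barrier():
    grid = pc.GeoGrid(values=np.zeros((3, 3)), x_origin=0, y_origin=1.5, cell_size=0.5)
    blocked = grid.with_values(np.zeros((3, 3)), nodata=-1.0)
    region = grid.with_values(np.zeros((3, 3)), nodata=-1.0)
    region.values[1, 1] = 1.0
    cost = pc.build_cost_surface(grid, blocked, k_slope=0.1,
                                 multiplier_mask=region, multiplier=5.0)
    assert cost.values[1, 1] == pytest.approx(5.0)
    assert cost.values[0, 0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------

def test_uniform_strip_accumulates_unit_costs():
    cost = km_lattice_cost(np.ones((1, 5)))
    grid = cost.grid
    path = pc.least_cost_path(cost, grid.cell_center(0, 0), grid.cell_center(0, 4))
    assert len(path) == 5
    assert path.total_cost == pytest.approx(4.0, rel=1e-6)


def test_diagonal_route_on_uniform_square():
    cost = km_lattice_cost(np.ones((3, 3)))
    grid = cost.grid
    path = pc.least_cost_path(cost, grid.cell_center(0, 0), grid.cell_center(2, 2))
    assert len(path) == 3
    assert path.total_cost == pytest.approx(2.0 * np.sqrt(2.0), rel=1e-6)


@pytest.mark.parametrize("seed", range(10))
def test_dijkstra_matches_bellman_ford(seed):
    rng = np.random.default_rng(seed)
    cost = make_cost(rng.uniform(1, 10, (7, 7)), x_origin=30.0, y_origin=45.0,
                     cell_size=0.2)
    grid = cost.grid
    path = pc.least_cost_path(cost, grid.cell_center(0, 0), grid.cell_center(6, 6))
    oracle = bellman_ford_cost(cost.values, grid.lats(), grid.lons(), (0, 0), (6, 6))
    assert path.total_cost == pytest.approx(oracle, rel=1e-9)


def test_route_cost_is_symmetric():
    rng = np.random.default_rng(42)
    cost = make_cost(rng.uniform(1, 10, (9, 9)), y_origin=10.0, cell_size=0.3)
    grid = cost.grid
    fwd = pc.least_cost_path(cost, grid.cell_center(0, 0), grid.cell_center(8, 8))
    rev = pc.least_cost_path(cost, grid.cell_center(8, 8), grid.cell_center(0, 0))
    assert fwd.total_cost == pytest.approx(rev.total_cost, rel=1e-12)
    assert fwd.length_km == pytest.approx(rev.length_km, rel=1e-12)


def test_adding_barriers_never_cheapens_route():
    rng = np.random.default_rng(5)
    vals = rng.uniform(1, 5, (10, 10))
    cost = make_cost(vals.copy(), y_origin=5.0, cell_size=0.2)
    grid = cost.grid
    base = pc.least_cost_path(cost, grid.cell_center(0, 0), grid.cell_center(9, 9))
    prev = base.total_cost
    for n_block in (3, 8, 15):
        blocked_vals = vals.copy()
        rows = rng.integers(1, 9, n_block)
        cols = rng.integers(1, 9, n_block)
        blocked_vals[rows, cols] = np.inf
        harder = make_cost(blocked_vals, y_origin=5.0, cell_size=0.2)
        path = pc.least_cost_path(harder, grid.cell_center(0, 0), grid.cell_center(9, 9))
        assert path.total_cost >= base.total_cost - 1e-12
        prev = path.total_cost


def test_complete_cut_raises_unreachable():
    vals = np.ones((5, 5))
    vals[:, 2] = np.inf
    cost = make_cost(vals, y_origin=2.5, cell_size=0.2)
    grid = cost.grid
    with pytest.raises(pc.UnreachableError):
        pc.least_cost_path(cost, grid.cell_center(2, 0), grid.cell_center(2, 4))


def test_endpoint_on_blocked_cell_is_placement_error():
    vals = np.ones((4, 4))
    vals[0, 0] = np.inf
    cost = make_cost(vals, y_origin=2.0, cell_size=0.5)
    grid = cost.grid
    with pytest.raises(pc.PlacementError, match=r"\(0, 0\)"):
        pc.least_cost_path(cost, grid.cell_center(0, 0), grid.cell_center(3, 3))
    with pytest.raises(pc.PlacementError, match="off-grid"):
        pc.least_cost_path(cost, (100.0, 0.0), grid.cell_center(3, 3))


def test_routes_are_deterministic():
    rng = np.random.default_rng(9)
    vals = rng.uniform(1, 3, (8, 8))
    runs = []
    for _ in range(2):
        cost = make_cost(vals.copy(), y_origin=4.0, cell_size=0.25)
        grid = cost.grid
        runs.append(pc.least_cost_path(cost, grid.cell_center(0, 0),
                                       grid.cell_center(7, 7)))
    assert runs[0].cells == runs[1].cells
    assert runs[0].total_cost == runs[1].total_cost


def test_uniform_cost_route_is_near_geodesic():
    """8-connected lattice elongation stays within ~8% of the great circle."""
    cost = make_cost(np.ones((30, 30)), x_origin=20.0, y_origin=48.0, cell_size=0.1)
    grid = cost.grid
    start, end = grid.cell_center(27, 2), grid.cell_center(3, 28)
    path = pc.least_cost_path(cost, start, end)
    straight = float(haversine_km(start[0], start[1], end[0], end[1]))
    assert straight <= path.length_km <= 1.085 * straight


# ---------------------------------------------------------------------------
# path length and serialisation
# ---------------------------------------------------------------------------

def test_single_cell_path_has_zero_length():
    cost = km_lattice_cost(np.ones((3, 3)))
    grid = cost.grid
    path = pc.least_cost_path(cost, grid.cell_center(1, 1), grid.cell_center(1, 1))
    assert len(path) == 1
    assert path.length_km == 0.0
    assert path.total_cost == 0.0


def test_one_degree_equatorial_segment_length():
    path = pc.DispersalPath(cells=[], coords=[(0.0, 0.0), (1.0, 0.0)],
                            total_cost=0.0, length_km=0.0)
    assert pc.path_length_km(path) == pytest.approx(111.195, abs=5e-4)


def test_length_invariant_under_reversal():
    rng = np.random.default_rng(2)
    coords = [(float(x), float(y)) for x, y in rng.uniform(0, 5, (12, 2))]
    fwd = pc.DispersalPath(cells=[], coords=coords, total_cost=0, length_km=0)
    rev = pc.DispersalPath(cells=[], coords=coords[::-1], total_cost=0, length_km=0)
    assert pc.path_length_km(fwd) == pytest.approx(pc.path_length_km(rev), rel=1e-12)


def test_total_cost_bounded_below_by_length(southern_route):
    assert southern_route.total_cost >= southern_route.length_km


def test_path_geojson_roundtrip(tmp_path):
    cost = km_lattice_cost(np.ones((4, 6)))
    grid = cost.grid
    path = pc.least_cost_path(cost, grid.cell_center(0, 0), grid.cell_center(3, 5),
                              start_name="A", end_name="B")
    file = tmp_path / "route.geojson"
    pc.write_path_geojson(path, file)
    back = pc.read_path_geojson(file)
    assert back.start_name == "A" and back.end_name == "B"
    assert back.total_cost == pytest.approx(path.total_cost, rel=1e-9)
    np.testing.assert_allclose(np.asarray(back.coords), np.asarray(path.coords),
                               atol=1e-9)
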