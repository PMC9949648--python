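"""Seeded synthetic landscapes with a Caucasus-Caspian-Altai-like structure.

The generator builds, on a 200 x 400 cell grid at 0.1 deg (lon 40-80 E,
lat 30-50 N by default):

* a **northern mountain range** (east-west Gaussian ridge, tapered in
  longitude) with a piedmont start site on its northern flank;
* a **southern mountain range** spanning the full grid width, whose northern
  piedmont hosts the corridor sites;
* a **closed sea basin** between the two ranges, excavated to below the
  deepest regression stand so every paleo-stand (-140 to +50 m) is
  realisable by flood fill, ringed by a low coastal plain;
* a **coastal corridor strip** between the southern shore and the range's
  1800 m contour, pinched at one point to a flat coastal *bench at exactly
  50 m* beneath a steep spur - the strip survives regressions but drowns
  when the sea rises to the +50 m stand;
* a **lowland embayment** east of the sea (floor ~30 m) through which a
  northern, continental-scale route can descend towards the east while the
  50-1800 m suitability band, when applied, keeps corridor routes out of it;
* a **desert** east of the embayment, treated as an absolute barrier.

Climate fields follow a linear lapse with elevation plus a uniform epochal
cooling and optional band-limited noise, co-registered with the DEM.

Everything is driven by one integer seed; identical parameters reproduce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .barriers import BarrierScenario, build_scenario_mask, flood_fill_sea, mask_array, polygon_mask
from .climate_velocity import ClimateEpochPair
from .exceptions import GenerationError, ParameterError
from .grid_io import GeoGrid, SiteTable


@dataclass
class RidgeParams:
    """East-west Gaussian-profile mountain ridge."""

    crest_lat: float
    height_m: float
    sigma_lat: float
    lon_range: tuple[float, float] | None = None  # None -> full grid width
    taper_deg: float = 1.5


@dataclass
class SeaBasinParams:
    """Closed super-elliptical sea basin with a smooth coastal ring."""

    center: tuple[float, float] = (55.0, 42.2)  # (lon, lat)
    semi_lon: float = 7.0
    semi_lat: float = 1.9
    floor_m: float = -200.0
    shore_width: float = 0.65  # super-ellipse metric units of the blend zone


@dataclass
class LandscapeParams:
    """Everything needed to build one synthetic study landscape."""

    shape: tuple[int, int] = (200, 400)
    cell_size: float = 0.1
    x_origin: float = 40.0
    y_origin: float = 50.0
    seed: int = 7
    base_elev_m: float = 100.0
    northern_range: RidgeParams | None = field(
        default_factory=lambda: RidgeParams(46.85, 2200.0, 0.5, (43.0, 57.0)))
    southern_range: RidgeParams | None = field(
        default_factory=lambda: RidgeParams(37.85, 3000.0, 0.6, None))
    sea_basin: SeaBasinParams | None = field(default_factory=SeaBasinParams)
    # lowland pass east of the sea: (lon_min, lon_max, lat_min, lat_max, floor_m)
    embayment: tuple[float, float, float, float, float] | None = (61.5, 64.0, 40.2, 44.5, 30.0)
    # corridor pinch: (lon_min, lon_max); bench top latitude; spur floor latitude
    pinch_lon: tuple[float, float] | None = (57.0, 59.0)
    bench_lat_top: float = 40.15
    bench_elev_m: float = 50.0
    spur_lat_bottom: float = 38.3
    spur_elev_m: float = 2200.0
    corridor_width_cells: int = 3
    # desert rectangle: (lon_min, lat_min, lon_max, lat_max); its west edge
    # overlaps the embayment so the desert meets the sea's flood fringe at
    # high stands and no dry ledge survives along the embayment rim
    desert_region: tuple[float, float, float, float] | None = (63.5, 40.2, 80.1, 50.1)
    # geographic corridor band used for strip membership reporting
    strip_lat_range: tuple[float, float] = (38.3, 40.45)
    noise_amplitude_m: float = 15.0
    noise_scale_cells: float = 3.0
    sea_level: float = -27.0

    def __post_init__(self):
        if self.corridor_width_cells < 3:
            raise ParameterError("corridor_width_cells must be >= 3 to stay routable")
        if self.sea_basin is not None and not self.sea_basin.floor_m < -140.0:
            raise ParameterError("sea floor must lie below -140 m so all stands flood")


DEFAULT_SITES = [
    # name, lon, lat, culture, role
    ("NW-Piedmont-Cave", 45.0, 47.8, "Micoquian", "start"),
    ("SW-Foothill-Cave", 45.5, 39.3, "Mousterian", "start"),
    ("East-End-Cave", 78.5, 39.5, "other", "end"),
    ("Mid-Corridor-Shelter", 65.0, 39.8, "Mousterian", "waypoint"),
    ("Coastal-Bench-Camp", 58.0, 40.0, "Mousterian", "candidate"),
    ("Piedmont-Terrace", 60.0, 39.6, "Mousterian", "candidate"),
    ("High-Valley", 55.0, 38.6, "other", "candidate"),
    ("Desert-Edge", 70.0, 39.9, "other", "candidate"),
    ("Far-Plateau", 52.0, 36.5, "other", "candidate"),
]


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _band_limited_noise(shape, scale_cells: float, rng) -> np.ndarray:
    """Unit-variance smooth noise (gaussian-filtered white noise)."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=scale_cells, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _ridge_field(lon, lat, ridge: RidgeParams) -> np.ndarray:
    profile = ridge.height_m * np.exp(-0.5 * ((lat - ridge.crest_lat) / ridge.sigma_lat) ** 2)
    if ridge.lon_range is not None:
        lo, hi = ridge.lon_range
        t_in = _smoothstep((lon - lo) / ridge.taper_deg)
        t_out = _smoothstep((hi - lon) / ridge.taper_deg)
        profile = profile * np.minimum(t_in, t_out)
    return profile


def generate_landscape(
    params: LandscapeParams | None = None,
    sites=DEFAULT_SITES,
) -> tuple[GeoGrid, BarrierScenario, SiteTable]:
    """Build (dem, default scenario, site table) from seeded parameters."""
    p = params or LandscapeParams()
    n_rows, n_cols = p.shape
    grid = GeoGrid(values=np.zeros(p.shape), x_origin=p.x_origin,
                   y_origin=p.y_origin, cell_size=p.cell_size)
    lon, lat = np.meshgrid(grid.lons(), grid.lats())

    dem = np.full(p.shape, p.base_elev_m, dtype=np.float64)
    if p.northern_range is not None:
        dem += _ridge_field(lon, lat, p.northern_range)
    if p.southern_range is not None:
        dem += _ridge_field(lon, lat, p.southern_range)
    if p.noise_amplitude_m > 0:
        rng = np.random.default_rng(p.seed)
        dem += p.noise_amplitude_m * _band_limited_noise(p.shape, p.noise_scale_cells, rng)

    sea_seed = None
    if p.sea_basin is not None:
        sb = p.sea_basin
        f = (np.abs((lon - sb.center[0]) / sb.semi_lon) ** 4
             + np.abs((lat - sb.center[1]) / sb.semi_lat) ** 4)
        w = _smoothstep((0.95 + sb.shore_width - f) / sb.shore_width)
        dem = dem * (1.0 - w) + sb.floor_m * w
        sea_seed = sb.center

    if p.embayment is not None:
        lo, hi, la, lb, floor = p.embayment
        taper = 2.0 * p.cell_size
        wb = np.minimum.reduce([
            _smoothstep((lon - lo) / taper), _smoothstep((hi - lon) / taper),
            _smoothstep((lat - la) / taper), _smoothstep((lb - lat) / taper),
        ])
        dem = np.minimum(dem, dem * (1.0 - wb) + floor * wb)

    if p.pinch_lon is not None:
        # half-open intervals with a small tolerance: cell centres can land
        # exactly on the bench boundaries up to float rounding
        eps = 1e-7
        lo, hi = p.pinch_lon
        in_lon = (lon >= lo) & (lon <= hi)
        bench_bottom = p.bench_lat_top - p.corridor_width_cells * p.cell_size
        bench = in_lon & (lat > bench_bottom + eps) & (lat <= p.bench_lat_top + eps)
        spur = in_lon & (lat > p.spur_lat_bottom) & (lat <= bench_bottom + eps)
        dem[bench] = p.bench_elev_m
        dem[spur] = np.maximum(dem[spur], p.spur_elev_m)

    dem_grid = grid.with_values(dem)

    polygons = []
    if p.desert_region is not None:
        x0, y0, x1, y1 = p.desert_region
        polygons.append([(x0, y0), (x1, y0), (x1, y1), (x0, y1), (x0, y0)])

    scenario = BarrierScenario(
        name=f"synthetic-seed{p.seed}",
        sea_level=p.sea_level,
        sea_seed=sea_seed,
        barrier_polygons=polygons,
        apply_band=False,
    )

    table = SiteTable(pd.DataFrame(sites, columns=["name", "lon", "lat", "culture", "role"]))
    _validate_sites(dem_grid, scenario, table, p)
    return dem_grid, scenario, table


def _validate_sites(dem: GeoGrid, scenario: BarrierScenario, sites: SiteTable,
                    p: LandscapeParams) -> None:
    blocked = mask_array(build_scenario_mask(dem, scenario))
    lo_lat, hi_lat = p.strip_lat_range
    for site in sites:
        r, c = dem.index_of(float(site["lon"]), float(site["lat"]))
        if blocked[r, c]:
            raise GenerationError(
                f"site '{site['name']}' falls on a blocked cell under the default scenario")
        elev = dem.values[r, c]
        if lo_lat < float(site["lat"]) < hi_lat and not (50.0 <= elev <= 1800.0):
            raise GenerationError(
                f"corridor site '{site['name']}' at {elev:.0f} m is outside the "
                "50-1800 m suitability band")


def corridor_strip(dem: GeoGrid, params: LandscapeParams,
                   sea_level: float | None = None) -> np.ndarray:
    """Boolean in-strip mask: the coastal band between the sea and the 1800 m contour.

    A cell is in the strip when it lies in the corridor latitude band, its
    elevation sits in the suitability interval, and it is neither flooded at
    the given stand nor desert.
    """
    p = params
    level = p.sea_level if sea_level is None else sea_level
    lat = dem.lats()[:, None]
    in_band = (lat > p.strip_lat_range[0]) & (lat < p.strip_lat_range[1])
    in_band = np.broadcast_to(in_band, dem.shape).copy()
    elev_ok = (dem.values >= 50.0) & (dem.values <= 1800.0)
    strip = in_band & elev_ok & ~dem.nodata_mask
    if p.sea_basin is not None:
        strip &= ~mask_array(flood_fill_sea(dem, level, p.sea_basin.center))
    if p.desert_region is not None:
        x0, y0, x1, y1 = p.desert_region
        ring = [(x0, y0), (x1, y0), (x1, y1), (x0, y1), (x0, y0)]
        strip &= ~mask_array(polygon_mask(dem, [ring]))
    return strip


def generate_climate(
    dem: GeoGrid,
    sea_level_T: float = 15.0,
    lapse_per_km: float = 6.5,
    epochal_cooling: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    delta_years: float = 110_000.0,
) -> ClimateEpochPair:
    """Lapse-rate temperature fields for two epochs, co-registered with the DEM.

    ``t_old = sea_level_T - lapse_per_km * elev_km (+ noise)`` and
    ``t_new = t_old - epochal_cooling (+ independent noise)``.
    """
    rng = np.random.default_rng(seed)
    base = sea_level_T - lapse_per_km * dem.values / 1000.0
    if noise_sd > 0:
        n1 = noise_sd * _band_limited_noise(dem.shape, 2.0, rng)
        n2 = noise_sd * _band_limited_noise(dem.shape, 2.0, rng)
    else:
        n1 = n2 = 0.0
    t_old = base + n1
    t_new = base - epochal_cooling + n2
    nd = dem.nodata_mask
    t_old = np.where(nd, dem.nodata, t_old)
    t_new = np.where(nd, dem.nodata, t_new)
    return ClimateEpochPair(
        t_old=dem.with_values(t_old),
        t_new=dem.with_values(t_new),
        delta_years=delta_years,
    )
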