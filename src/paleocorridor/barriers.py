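"""Barrier masks: paleo-sea flood fill, elevation suitability band, deserts.

A *mask* is a :class:`~paleocorridor.grid_io.GeoGrid` of {0 = open,
1 = blocked} on the DEM's geometry.  A :class:`BarrierScenario` bundles one
paleo-stage hypothesis: a Caspian-style sea stand (flood-filled from a seed,
because the basin is closed — inundation is connectivity-limited, not a
global threshold), a 50-1800 m settlement-suitability band, and desert
polygons treated as absolute barriers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
import yaml
from scipy import ndimage
from shapely.geometry import Polygon

from .exceptions import GeometryError, ParameterError
from .grid_io import GeoGrid, require_same_geometry

#: Caspian stands reported for the late Pleistocene (m asl)
SEA_LEVEL_PRESETS = {
    "present": -27.0,
    "late_khazarian": -10.0,
    "atelian_high": -120.0,
    "atelian_low": -140.0,
    "early_khvalynian": 50.0,
}


@dataclass
class BarrierScenario:
    """One named paleo-stage hypothesis for routing."""

    name: str
    sea_level: float = SEA_LEVEL_PRESETS["present"]
    sea_seed: tuple[float, float] | None = None  # (lon, lat) inside the basin
    min_suitable_elev: float = 50.0
    max_suitable_elev: float = 1800.0
    barrier_polygons: list[list[tuple[float, float]]] = field(default_factory=list)
    apply_band: bool = False
    desert_cost_multiplier: float | None = None  # None -> hard barrier

    def __post_init__(self):
        if not self.min_suitable_elev < self.max_suitable_elev:
            raise ParameterError(
                f"suitability band inverted: [{self.min_suitable_elev}, "
                f"{self.max_suitable_elev}]"
            )

    def with_sea_level(self, sea_level: float, name: str | None = None) -> "BarrierScenario":
        from dataclasses import replace

        return replace(self, sea_level=sea_level, name=name or f"{self.name}@{sea_level:g}m")

    @classmethod
    def from_yaml(cls, path) -> "BarrierScenario":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        polys = doc.get("barrier_polygons", [])
        if isinstance(polys, str):
            from .grid_io import read_polygons_geojson

            polys = read_polygons_geojson(polys)
        return cls(
            name=doc["name"],
            sea_level=float(doc.get("sea_level_m", SEA_LEVEL_PRESETS["present"])),
            sea_seed=tuple(doc["sea_seed"]) if doc.get("sea_seed") else None,
            min_suitable_elev=float(doc.get("min_suitable_elev_m", 50.0)),
            max_suitable_elev=float(doc.get("max_suitable_elev_m", 1800.0)),
            barrier_polygons=[[tuple(p) for p in ring] for ring in polys],
            apply_band=bool(doc.get("apply_band", False)),
            desert_cost_multiplier=doc.get("desert_cost_multiplier"),
        )

    def to_yaml(self, path, polygons_path: str | None = None) -> None:
        doc = {
            "name": self.name,
            "sea_level_m": self.sea_level,
            "sea_seed": list(self.sea_seed) if self.sea_seed else None,
            "min_suitable_elev_m": self.min_suitable_elev,
            "max_suitable_elev_m": self.max_suitable_elev,
            "apply_band": self.apply_band,
        }
        if self.desert_cost_multiplier is not None:
            doc["desert_cost_multiplier"] = self.desert_cost_multiplier
        if polygons_path is not None:
            from .grid_io import write_polygons_geojson

            write_polygons_geojson(self.barrier_polygons, polygons_path)
            doc["barrier_polygons"] = str(polygons_path)
        else:
            doc["barrier_polygons"] = [[list(p) for p in ring] for ring in self.barrier_polygons]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def _mask_like(grid: GeoGrid, blocked: np.ndarray) -> GeoGrid:
    return grid.with_values(blocked.astype(np.float64), nodata=-1.0)


def mask_array(mask: GeoGrid) -> np.ndarray:
    return mask.values >= 0.5


def flood_fill_sea(dem: GeoGrid, sea_level: float, sea_seed: tuple[float, float]) -> GeoGrid:
    """Cells at/below ``sea_level`` 4-connected to the seed.

    Depressions below sea level that are not connected to the seed stay dry:
    in a closed basin, water reaches only what the basin reaches.  A seed
    standing above sea level yields an empty (all-open) mask with a warning.
    """
    r, c = dem.index_of(*sea_seed)
    if dem.values[r, c] == dem.nodata:
        raise ParameterError("sea seed falls on a nodata cell")
    if dem.values[r, c] > sea_level:
        warnings.warn(
            f"sea seed elevation {dem.values[r, c]:.1f} m is above sea level "
            f"{sea_level:g} m: dry-seed scenario, sea mask is empty",
            stacklevel=2,
        )
        return _mask_like(dem, np.zeros(dem.shape, dtype=bool))
    wet = (dem.values <= sea_level) & ~dem.nodata_mask
    four_conn = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, _ = ndimage.label(wet, structure=four_conn)
    return _mask_like(dem, labels == labels[r, c])


def elevation_band_mask(dem: GeoGrid, min_elev: float, max_elev: float) -> GeoGrid:
    """Block cells outside the closed suitability interval [min_elev, max_elev]."""
    if not min_elev < max_elev:
        raise ParameterError(f"inverted elevation band [{min_elev}, {max_elev}]")
    blocked = (dem.values < min_elev) | (dem.values > max_elev)
    blocked &= ~dem.nodata_mask
    return _mask_like(dem, blocked)


def polygon_mask(reference: GeoGrid, polygons) -> GeoGrid:
    """Block cells whose centre lies inside any polygon (even-odd rule)."""
    blocked = np.zeros(reference.shape, dtype=bool)
    if polygons:
        lons = reference.lons()
        lats = reference.lats()
        gx, gy = np.meshgrid(lons, lats)
        for ring in polygons:
            poly = ring if isinstance(ring, Polygon) else Polygon(ring)
            if not poly.is_valid:
                raise GeometryError("self-intersecting or otherwise invalid polygon")
            blocked |= shapely.contains_xy(poly, gx, gy)
    return _mask_like(reference, blocked)


def combine_masks(masks: list[GeoGrid]) -> GeoGrid:
    """Logical OR of masks sharing one geometry."""
    if not masks:
        raise ParameterError("combine_masks needs at least one mask")
    require_same_geometry(*masks)
    blocked = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        blocked |= mask_array(m)
    return _mask_like(masks[0], blocked)


def build_scenario_mask(dem: GeoGrid, scenario: BarrierScenario) -> GeoGrid:
    """Combined blocked mask for a scenario: sea + deserts (+ band if applied).

    Deserts with a finite ``desert_cost_multiplier`` are *not* blocked here;
    they are penalised at cost-surface time instead.
    """
    masks = []
    if scenario.sea_seed is not None:
        masks.append(flood_fill_sea(dem, scenario.sea_level, scenario.sea_seed))
    if scenario.barrier_polygons and scenario.desert_cost_multiplier is None:
        masks.append(polygon_mask(dem, scenario.barrier_polygons))
    if scenario.apply_band:
        masks.append(
            elevation_band_mask(dem, scenario.min_suitable_elev, scenario.max_suitable_elev)
        )
    if not masks:
        masks.append(_mask_like(dem, np.zeros(dem.shape, dtype=bool)))
    return combine_masks(masks)
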