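"""Climate-change velocity and stability (refugium) masks.

Velocity is the classic ratio of a temporal rate of change to the local
spatial gradient: the speed at which an organism would have to move to keep
its climate constant.  Here it is computed for temperature between two
epochs (e.g. Last Interglacial to Last Glaciation) in km per century::

    v = (|T_new - T_old| / delta_years) / |grad T|

Flat-field division is the classic failure mode of velocity maps: where the
spatial gradient falls below ``g_floor`` the velocity is deterministically
assigned the ceiling ``v_cap`` (and all values are clipped to ``v_cap``), so
a spatially uniform field never produces infinities.  Cells with low
velocity — climates that barely had to move — nominate refugia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .grid_io import GeoGrid, require_same_geometry
from .terrain import horn_gradient

DEFAULT_V_CAP = 10_000.0  # km / century
DEFAULT_G_FLOOR = 1e-6  # degC / km


@dataclass
class ClimateEpochPair:
    """Two co-registered temperature grids separated by ``delta_years``."""

    t_old: GeoGrid
    t_new: GeoGrid
    delta_years: float

    def __post_init__(self):
        require_same_geometry(self.t_old, self.t_new)
        if not self.delta_years > 0:
            raise ParameterError(f"delta_years must be positive, got {self.delta_years}")


def temporal_rate(pair: ClimateEpochPair) -> GeoGrid:
    """|T_new - T_old| / delta_years per cell, in degC per year."""
    bad = pair.t_old.nodata_mask | pair.t_new.nodata_mask
    rate = np.abs(pair.t_new.values - pair.t_old.values) / pair.delta_years
    rate[bad] = pair.t_old.nodata
    return pair.t_old.with_values(rate)


def spatial_gradient(t: GeoGrid) -> GeoGrid:
    """Magnitude of the horizontal temperature gradient in degC per km.

    Same Horn stencil as the terrain slope, with metric ground distances;
    borders and incomplete stencils are nodata.
    """
    p, q, valid = horn_gradient(t, ground_distance="metric")
    mag_per_km = np.hypot(p, q) * 1000.0
    out = np.full(t.shape, t.nodata)
    out[valid] = mag_per_km[valid]
    return t.with_values(out)


def climate_velocity(
    pair: ClimateEpochPair,
    gradient_source: str = "old",
    v_cap: float = DEFAULT_V_CAP,
    g_floor: float = DEFAULT_G_FLOOR,
) -> GeoGrid:
    """Temperature-change velocity in km per century, capped at ``v_cap``.

    ``gradient_source`` picks which epoch's spatial gradient to divide by:
    ``old`` (default — the landscape the shift started from), ``new``, or
    ``mean`` of the two.
    """
    if not v_cap > 0:
        raise ParameterError(f"v_cap must be positive, got {v_cap}")
    if gradient_source not in ("old", "new", "mean"):
        raise ParameterError(f"unknown gradient_source '{gradient_source}'")

    rate = temporal_rate(pair)  # degC / yr
    if gradient_source == "old":
        grad = spatial_gradient(pair.t_old)
    elif gradient_source == "new":
        grad = spatial_gradient(pair.t_new)
    else:
        g_old = spatial_gradient(pair.t_old)
        g_new = spatial_gradient(pair.t_new)
        bad = g_old.nodata_mask | g_new.nodata_mask
        vals = 0.5 * (g_old.values + g_new.values)
        vals[bad] = g_old.nodata
        grad = g_old.with_values(vals)

    nodata = rate.nodata_mask | grad.nodata_mask
    out = np.full(pair.t_old.shape, pair.t_old.nodata)
    ok = ~nodata
    g = grad.values[ok]
    r = rate.values[ok]
    v = np.empty_like(r)
    degenerate = g < g_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        v[~degenerate] = (r[~degenerate] / g[~degenerate]) * 100.0  # km/yr -> km/century
    v[degenerate] = v_cap
    np.clip(v, 0.0, v_cap, out=v)
    out[ok] = v
    return pair.t_old.with_values(out)


def stability_mask(velocity: GeoGrid, quantile: float) -> GeoGrid:
    """Mark the most-stable fraction of cells as open (refugium candidates).

    Open = velocity at or below the empirical ``quantile`` of finite
    velocities (inverted-CDF quantile, inclusive threshold, so ties are
    stable); blocked = everything faster.  Mask semantics: "blocked" here
    means "not a refugium".
    """
    if not 0 < quantile < 1:
        raise ParameterError(f"quantile must be in (0, 1), got {quantile}")
    finite = velocity.finite_values()
    if finite.size == 0:
        raise ParameterError("all-nodata velocity grid")
    threshold = np.quantile(finite, quantile, method="inverted_cdf")
    blocked = (velocity.values > threshold) | velocity.nodata_mask
    return velocity.with_values(blocked.astype(np.float64), nodata=-1.0)


def region_summary(grid: GeoGrid, region: GeoGrid | None = None) -> dict[str, float]:
    """Min/mean/max of finite values, optionally inside a region mask.

    This is the whole of the epoch-mapping step: read, co-register, summarise.
    """
    vals = grid.values
    ok = ~grid.nodata_mask
    if region is not None:
        require_same_geometry(grid, region)
        ok &= region.values >= 0.5
    sel = vals[ok]
    if sel.size == 0:
        raise ParameterError("region contains no finite cells")
    return {"min": float(sel.min()), "mean": float(sel.mean()), "max": float(sel.max()),
            "n_cells": int(sel.size)}
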