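"""Slope from elevation via Horn's third-order finite difference.

The 8-neighbour weighted stencil (Horn 1981) estimates the two horizontal
gradient components of a surface; slope is ``atan(|grad|)`` in degrees.  With
``ground_distance="metric"`` the cell size is converted to metres using
111 320 m per degree of latitude and a per-row ``cos(lat)`` shrink for the
east-west spacing — on a raster spanning tens of degrees a single scalar
would systematically bias eastern/western slopes.  ``"unit-cell"`` treats the
cell as 1 m, which is the convention the analytic examples use.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ParameterError
from .geodesy import METERS_PER_DEGREE
from .grid_io import GeoGrid


def horn_gradient(grid: GeoGrid, ground_distance: str = "metric"):
    """Per-cell gradient components (east, north) in value units per metre.

    Returns ``(p, q, valid)`` where ``valid`` marks interior cells whose full
    3x3 stencil is free of nodata.  Border cells are always invalid.
    """
    if grid.n_rows < 3 or grid.n_cols < 3:
        raise ParameterError("gradient stencil needs at least a 3x3 grid")
    if ground_distance not in ("metric", "unit-cell"):
        raise ParameterError(f"unknown ground_distance '{ground_distance}'")

    z = grid.values
    nd = grid.nodata_mask

    def w(dr, dc):
        return z[1 + dr : z.shape[0] - 1 + dr, 1 + dc : z.shape[1] - 1 + dc]

    def wnd(dr, dc):
        return nd[1 + dr : nd.shape[0] - 1 + dr, 1 + dc : nd.shape[1] - 1 + dc]

    # window labels:  a b c / d e f / g h i   (row grows south, col grows east)
    a, b, c = w(-1, -1), w(-1, 0), w(-1, 1)
    d, f = w(0, -1), w(0, 1)
    g, h, i = w(1, -1), w(1, 0), w(1, 1)

    if ground_distance == "metric":
        dy_m = grid.cell_size * METERS_PER_DEGREE
        lat = grid.lats()[1:-1]
        dx_m = dy_m * np.cos(np.radians(lat))[:, None]
    else:
        dy_m = 1.0
        dx_m = 1.0

    p = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dx_m)  # eastward
    q = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * dy_m)  # northward

    stencil_bad = np.zeros_like(p, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            stencil_bad |= wnd(dr, dc)

    valid = np.zeros(grid.shape, dtype=bool)
    valid[1:-1, 1:-1] = ~stencil_bad
    pf = np.zeros(grid.shape)
    qf = np.zeros(grid.shape)
    pf[1:-1, 1:-1] = p
    qf[1:-1, 1:-1] = q
    return pf, qf, valid


def compute_slope(dem: GeoGrid, ground_distance: str = "metric") -> GeoGrid:
    """Slope in degrees from horizontal; borders and nodata stencils -> nodata."""
    p, q, valid = horn_gradient(dem, ground_distance=ground_distance)
    slope = np.degrees(np.arctan(np.hypot(p, q)))
    out = np.full(dem.shape, dem.nodata)
    out[valid] = slope[valid]
    return dem.with_values(out)
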