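"""Settlement-potential corridors: a great-circle buffer around a route.

A corridor is the set of points within ``buffer_km`` (default 30 km) of a
dispersal path, with distance measured as the minimum great-circle distance
to the path's *segments* (cross-track distance clipped to segment extent).
Vertex-only distance would over-exclude points lying near the middle of long
segments on coarse rasters.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cost_lcp import DispersalPath
from .exceptions import ParameterError
from .geodesy import polyline_distance_km
from .grid_io import SiteTable


@dataclass
class Corridor:
    """Buffered route membership predicate."""

    path: DispersalPath
    buffer_km: float = 30.0

    def distance_km(self, lon: float, lat: float) -> float:
        """Minimum great-circle distance from a point to the route."""
        return polyline_distance_km(lon, lat, self.path.coords)

    def contains(self, lon: float, lat: float) -> bool:
        return self.distance_km(lon, lat) <= self.buffer_km


def buffer_corridor(path: DispersalPath, buffer_km: float = 30.0) -> Corridor:
    if len(path.coords) < 1:
        raise ParameterError("cannot buffer an empty path")
    if not buffer_km > 0:
        raise ParameterError(f"buffer_km must be positive, got {buffer_km}")
    return Corridor(path=path, buffer_km=buffer_km)


def sites_in_corridor(sites: SiteTable, corridor: Corridor) -> SiteTable:
    """Sites within the buffer, annotated with their distance to the route.

    Ordered by distance ascending, ties broken by name, so output is stable.
    """
    rows = []
    for site in sites:
        d = corridor.distance_km(float(site["lon"]), float(site["lat"]))
        if d <= corridor.buffer_km:
            rec = site.to_dict()
            rec["distance_km"] = d
            rows.append(rec)
    if not rows:
        return SiteTable(pd.DataFrame(columns=["name", "lon", "lat", "culture", "role",
                                               "distance_km"]))
    df = pd.DataFrame(rows).sort_values(["distance_km", "name"], kind="mergesort")
    return SiteTable(df.reset_index(drop=True))
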