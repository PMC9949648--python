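"""Great-circle geodesy on the mean-radius sphere.

All distances are in kilometres on a sphere of radius ``EARTH_RADIUS_KM``
(IUGG mean Earth radius). Longitudes/latitudes are decimal degrees.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088

#: metres of ground per degree of latitude used for metric slope stencils
METERS_PER_DEGREE = 111_320.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance between two points (array-friendly)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _bearing_rad(lon1, lat1, lon2, lat2):
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    y = np.sin(lon2 - lon1) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(lon2 - lon1)
    return np.arctan2(y, x)


def point_segment_distance_km(lon, lat, lon1, lat1, lon2, lat2) -> float:
    """Minimum great-circle distance from a point to a great-circle segment.

    Uses the cross-track distance where the along-track projection falls
    within the segment, otherwise the nearer endpoint distance.  Degenerate
    (zero-length) segments reduce to a point distance.
    """
    d12 = haversine_km(lon1, lat1, lon2, lat2)
    d1p = float(haversine_km(lon1, lat1, lon, lat))
    if d12 < 1e-12:
        return d1p
    d2p = float(haversine_km(lon2, lat2, lon, lat))
    delta13 = d1p / EARTH_RADIUS_KM
    theta13 = _bearing_rad(lon1, lat1, lon, lat)
    theta12 = _bearing_rad(lon1, lat1, lon2, lat2)
    xtd = np.arcsin(np.clip(np.sin(delta13) * np.sin(theta13 - theta12), -1.0, 1.0))
    # along-track arc from the first endpoint to the foot of the perpendicular
    cos_xtd = np.cos(xtd)
    if abs(cos_xtd) < 1e-15:
        return min(d1p, d2p)
    atd = np.arccos(np.clip(np.cos(delta13) / cos_xtd, -1.0, 1.0))
    # projection behind the start or beyond the end: clamp to endpoints
    if np.cos(theta13 - theta12) < 0.0:
        return d1p
    if atd * EARTH_RADIUS_KM > d12:
        return d2p
    return float(abs(xtd) * EARTH_RADIUS_KM)


def polyline_distance_km(lon: float, lat: float, coords) -> float:
    """Minimum distance from a point to a lon/lat polyline (segment-aware)."""
    coords = list(coords)
    if len(coords) == 0:
        raise ValueError("empty polyline")
    if len(coords) == 1:
        return float(haversine_km(coords[0][0], coords[0][1], lon, lat))
    best = np.inf
    for (x1, y1), (x2, y2) in zip(coords[:-1], coords[1:]):
        d = point_segment_distance_km(lon, lat, x1, y1, x2, y2)
        if d < best:
            best = d
    return float(best)
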