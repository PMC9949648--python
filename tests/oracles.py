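"""Independent reference implementations used only to check the package.

These deliberately use different algorithms and formulations from the
package: synchronous vectorised Bellman-Ford relaxation instead of Dijkstra,
a queue-based flood fill instead of labelled components, 3-D unit-vector
geometry instead of the haversine/cross-track formulas, and explicit-weight
bilinear interpolation.
"""

from __future__ import annotations

from collections import deque

import numpy as np

R_KM = 6371.0088


def sphere_distance_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance via the Vincenty arctan2 form (sphere)."""
    l1, p1, l2, p2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dl = l2 - l1
    num = np.hypot(np.cos(p2) * np.sin(dl),
                   np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl))
    den = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    return float(R_KM * np.arctan2(num, den))


def bellman_ford_cost(cost: np.ndarray, lats: np.ndarray, lons: np.ndarray,
                      start: tuple[int, int], end: tuple[int, int]) -> float:
    """Least accumulated cost by synchronous relaxation to a fixed point.

    Edge weight between 8-neighbours i, j is d(i, j) * (c_i + c_j) / 2 with d
    the great-circle distance between cell centres.
    """
    n_rows, n_cols = cost.shape
    d_ew = np.array([sphere_distance_km(lons[0], la, lons[1], la) for la in lats])
    d_ns = sphere_distance_km(lons[0], lats[0], lons[0], lats[1])
    d_diag = np.array([sphere_distance_km(lons[0], lats[r], lons[1], lats[r + 1])
                       for r in range(n_rows - 1)]) if n_rows > 1 else np.zeros(0)

    dist = np.full(cost.shape, np.inf)
    dist[start] = 0.0
    finite = np.isfinite(cost)
    for _ in range(n_rows * n_cols):
        prev = dist.copy()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                # relax edges entering cell (r, c) from (r - dr, c - dc)
                src = dist[max(0, -dr): n_rows - max(0, dr),
                           max(0, -dc): n_cols - max(0, dc)]
                c_src = cost[max(0, -dr): n_rows - max(0, dr),
                             max(0, -dc): n_cols - max(0, dc)]
                dst_slice = (slice(max(0, dr), n_rows - max(0, -dr)),
                             slice(max(0, dc), n_cols - max(0, -dc)))
                c_dst = cost[dst_slice]
                if dr == 0:
                    w = d_ew[:, None][dst_slice[0], :]
                elif dc == 0:
                    w = d_ns
                else:
                    rows = np.arange(max(0, dr), n_rows - max(0, -dr))
                    # a diagonal step spans rows (r-1, r) moving south, (r, r+1) north
                    w = d_diag[rows - 1 if dr == 1 else rows][:, None]
                cand = src + w * 0.5 * (c_src + c_dst)
                cand = np.where(np.isfinite(c_src) & np.isfinite(c_dst), cand, np.inf)
                np.minimum(dist[dst_slice], cand, out=dist[dst_slice])
        dist[~finite] = np.inf
        if np.array_equal(prev, dist, equal_nan=True):
            break
    return float(dist[end])


def flood_fill_bfs(dem: np.ndarray, nodata: float, sea_level: float,
                   seed: tuple[int, int]) -> np.ndarray:
    """4-connected component of wet cells containing the seed, by BFS."""
    n_rows, n_cols = dem.shape
    wet = (dem <= sea_level) & (dem != nodata)
    out = np.zeros(dem.shape, dtype=bool)
    if not wet[seed]:
        return out
    queue = deque([seed])
    out[seed] = True
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < n_rows and 0 <= nc < n_cols and wet[nr, nc] and not out[nr, nc]:
                out[nr, nc] = True
                queue.append((nr, nc))
    return out


def _unit(lon, lat):
    lo, la = np.radians(lon), np.radians(lat)
    return np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])


def _angle(u, v) -> float:
    return float(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v)))


def point_to_segment_km(lon, lat, lon1, lat1, lon2, lat2) -> float:
    """Point-to-great-circle-segment distance via 3-D vector geometry."""
    a, b, p = _unit(lon1, lat1), _unit(lon2, lat2), _unit(lon, lat)
    n = np.cross(a, b)
    norm = np.linalg.norm(n)
    if norm < 1e-15:  # degenerate segment
        return _angle(a, p) * R_KM
    n = n / norm
    # foot of the perpendicular on the great circle through a, b
    foot = p - np.dot(p, n) * n
    fn = np.linalg.norm(foot)
    if fn < 1e-15:
        return 0.25 * 2 * np.pi * R_KM  # pole of the circle: quarter turn
    foot = foot / fn
    seg = _angle(a, b)
    if abs(_angle(a, foot) + _angle(foot, b) - seg) < 1e-9:
        return abs(_angle(p, foot)) * R_KM
    return min(_angle(p, a), _angle(p, b)) * R_KM


def point_to_polyline_km(lon, lat, coords) -> float:
    best = np.inf
    for (x1, y1), (x2, y2) in zip(coords[:-1], coords[1:]):
        best = min(best, point_to_segment_km(lon, lat, x1, y1, x2, y2))
    return best
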