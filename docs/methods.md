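# Methods

`paleocorridor` models hominin dispersal corridors on raster landscapes and
nominates climate-stability refugia. This note records the model, its
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Movement-cost model and routing

The cost surface is built from terrain slope alone. Slope is computed with
Horn's third-order finite difference over the 8-neighbour window, reported in
degrees from horizontal. With `ground_distance="metric"` the cell size is
converted to metres using 111 320 m per degree of latitude and a per-row
`cos(lat)` shrink for east–west spacing; on study areas spanning tens of
degrees a single scalar spacing would systematically bias eastern and
western slopes. Border cells (and any cell whose 3×3 stencil touches nodata)
are nodata — no one-sided stencils, so routing can never exploit an
artificially flat border.

Per-cell traversal cost is

```
cost = 1 + k_slope · slope_deg        (dimensionless multiplier ≥ 1)
```

with `k_slope = 0.1` by default, i.e. cost doubles at 10° slope. Only the
monotone slope→cost relation is scientifically constrained; a linear form is
the minimal assumption, and `k_slope` is an explicit parameter so the
sensitivity of a route to the slope penalty can be probed directly. Tobler's
hiking function would slot in behind the same contract but is not enabled:
for corridor identification only the ordering of candidate routes matters,
and the linear form keeps the single parameter interpretable.

Routing is Dijkstra's algorithm on the 8-connected cell lattice. The edge
weight between neighbouring cells *i*, *j* is

```
w(i, j) = d(i, j) · (cost_i + cost_j) / 2
```

where `d` is the great-circle distance between the cell centres in km
(sphere of radius 6371.0088 km), so accumulated cost is in cost-weighted
kilometres and is bounded below by the geodesic path length. The trapezoidal
mean over the two endpoint costs matches the transition-matrix convention of
the common landscape-connectivity tool family. Among exactly equal-cost
alternatives the lexicographically smallest (row, col) predecessor wins,
making path outputs byte-reproducible. Route endpoints snap to their
containing cell centre; an endpoint on a blocked cell is a hard error rather
than being silently moved — nearest-open-cell snapping can jump a barrier
and invert the question being asked.

On a uniform cost surface an 8-connected lattice path exceeds the great
circle by at most ~8 % (the classic octile elongation); the test suite
asserts this bound, and verifies optimality against an independent
synchronous Bellman–Ford relaxation on ~100 seeded random grids.

## Barriers

Three barrier mechanisms compose by logical OR into a blocked mask:

* **Closed-basin sea.** The basin is flooded by 4-connected flood fill from
  a seed point at or below the chosen stand, *not* by global thresholding:
  in a closed basin, depressions not connected to the sea stay dry.
  4-connectivity prevents water from leaking diagonally through one-cell
  land bridges that 8-connected routing could not cross anyway. Shipped
  stand presets (m asl): present −27, Late Khazarian −10, Atelian −120 and
  −140 (the reconstruction is a range, so both endpoints ship as named
  presets rather than guessing one), Early Khvalynian +50. A seed above the
  stand yields an empty mask plus a warning (a dry-seed scenario is usually
  a configuration mistake).
* **Deserts** are polygons blocking every cell whose centre falls inside.
  By default they are absolute barriers: the modelled redirection of routes
  onto mountain piedmonts is only guaranteed by a hard barrier. A finite
  `desert_cost_multiplier` is available for sensitivity analysis, in which
  case the polygon inflates cost instead of blocking.
* **Suitability band.** Cells outside the closed elevation interval
  [50 m, 1800 m] are blocked *when the band is applied*. The band encodes
  two observations: later transgressions up to +50 m would have reworked or
  drowned any sub-50 m settlement trace, and settlement density falls off
  above ~1800 m. Band membership is a closed interval — boundary cells are
  open. `apply_band` defaults to **off** for continental-scale routing
  (northern plains routes legitimately cross land below 50 m) and is turned
  **on** when tracing within the coastal corridor itself.

## Corridors

A corridor is the set of points within `buffer_km` (default 30 km) of a
route, with distance measured as minimum great-circle distance to the
route's *segments* (cross-track distance clipped to segment extent), not to
its vertices only — vertex-only distance over-excludes near the middle of
long segments on coarse rasters. Distances are ground (great-circle)
distances, not planimetric map distances. Site reports include each site's
distance so users can re-threshold without recomputation.

## Climate-change velocity and refugia

Velocity between two epochs separated by `delta_years` is

```
v = (|T_new − T_old| / delta_years) / |∇T|     (km per century)
```

with the spatial gradient from the same Horn stencil as the slope, in
°C/km. The gradient is taken from the earlier epoch by default
(`gradient_source="old"` — the landscape the shift started from); `new` and
`mean` are exposed. Flat-field division is the classic failure mode of
velocity maps: cells with gradient below `g_floor` (10⁻⁶ °C/km) are
deterministically assigned the ceiling `v_cap` (10⁴ km/century) and all
values are clipped to `v_cap`, so a spatially uniform field produces a
well-defined constant rather than infinities.

Refugium candidates are the cells at or below a chosen empirical quantile
(default 0.25) of finite velocities. The threshold is the inverted-CDF
quantile and membership is inclusive (≤), so ties are stable and the stable
cell count equals `ceil(q · n)` for distinct values.

Epoch "mapping" beyond velocity reduces to reading the epoch grids,
co-registering them onto the DEM and reporting min/mean/max summaries over a
region mask; cartographic rendering is out of scope.

## Synthetic landscape

The generator emulates the physiography the analysis assumes — a closed sea
between two east–west mountain ranges, a narrow coastal corridor pinched
between the southern range and the sea, a desert to the east — on a
200 × 400 grid at 0.1° (lon 40–80°E, lat 30–50°N), sized so two distinct
routes exist yet the whole pipeline runs in seconds. Components:

* base plain at 100 m; Gaussian-profile ridges (northern 2200 m, tapered in
  longitude; southern 3000 m, full width, 1800 m contour near 38.4°N);
* super-elliptical sea basin excavated to −200 m (below the deepest −140 m
  stand) with a smooth coastal ring whose elevations pass continuously
  through every stand, so inundation is strictly monotone in sea level;
* a corridor **pinch**: a coastal bench at exactly 50 m elevation (three
  cells wide, the minimum routable corridor width) under a steep >1800 m
  spur. At regression stands the bench is the only in-band passage — the
  corridor squeeze — and at the +50 m stand it floods, severing the
  southern route outright;
* a lowland embayment (~30 m floor) east of the sea through which the
  continental northern route descends; the suitability band keeps corridor
  routes out of it;
* a desert rectangle whose west edge overlaps the embayment, so at high
  stands no dry ledge survives along the embayment rim;
* band-limited noise (Gaussian-filtered white noise, amplitude 15 m,
  correlation scale 3 cells) rather than per-cell white noise, so slope
  fields are realistic and flood fill is stable.

Sites are placed as analogues of the study design: a northwest piedmont
start on the northern range, a southwest start on the southern piedmont, an
eastern end, a mid-corridor waypoint, and candidate sites at varied
distances from the southern route. Generation validates that every site is
on open land under the default scenario (corridor sites additionally inside
the 50–1800 m band) and fails loudly otherwise.

Synthetic climate follows a linear lapse (`T = T_sea − 6.5 °C/km · elev`)
plus uniform epochal cooling (default 5 °C over 110 000 years, the Last
Interglacial → Last Glacial Maximum separation) and optional smooth noise
(0.5 °C where enabled). Under a lapse-dominated climate, velocity is lowest
where terrain is steepest — isotherms are compressed, so a cooling epoch is
tracked by a short uphill move. The suite asserts this mountain-refugium
pattern as a negative Spearman rank correlation between slope and velocity.

What the generator does **not** emulate: real orography, ocean-moderated
coastal climates, precipitation, aspect effects, vegetation, taphonomy.
Passing tests therefore demonstrate the *mechanics* of the pipeline — mask
composition, routing optimality, monotone inundation, velocity arithmetic —
on a landscape with the right topology, not a reconstruction of any real
region.

## Numerical choices and degenerate inputs

* Geodesy: haversine on the IUGG mean-radius sphere (6371.0088 km); 1° of
  longitude at the equator is 111.195 km.
* ESRI ASCII grids are written with 6 significant digits by default (the
  documented round-trip exactness boundary); `precision=17` gives lossless
  float64 text. GeoTIFF stores float64 and round-trips bit-exactly.
* Grids are geographic, square-celled, north-up only; anisotropic ground
  distance is handled at edge-weight time rather than by reprojection,
  which keeps the model faithful to the lon/lat rasters the workflow uses.
  Working resolution is always an explicit parameter, never inferred.
* Bilinear alignment propagates nodata if any of the four support cells is
  nodata; samples outside the source cell-centre hull are nodata.
* Paths of fewer than two vertices have zero length; a zero-length corridor
  segment degrades to a point distance.
* Equal-cost route ties are broken by smallest (row, col) predecessor;
  quantile ties in the stability mask are inclusive.

## Problem sizes

Default test and acceptance runs use the 200 × 400 synthetic grid (80 000
cells, routes of ~330–360 cells), 100 random routing grids up to 20 × 20 for
oracle comparison, and 50 random 12 × 14 basins for flood-fill checks. These
sizes exercise every code path while keeping a full run in seconds; all of
them scale up by changing `LandscapeParams`.

## Known limitations

* Costs are isotropic: ascending and descending a slope cost the same, and
  direction-dependent effort (wind, river crossing) is out of scope.
* Dijkstra is exact but single-pair; no current-flow/circuit-theory
  connectivity surface is produced.
* Velocity is univariate (temperature only); multivariate or
  forward/backward velocity variants are not implemented.
* The sphere approximation ignores ellipticity (~0.3 % distance error),
  well below the raster discretisation error at 0.1° cells.
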