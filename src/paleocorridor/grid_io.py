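"""Georeferenced raster model and I/O.

The package's universal carrier is :class:`GeoGrid`: a north-up 2-D array of
values on square geographic (lon/lat, WGS-84) cells.  Cell (0, 0) is the
north-west corner; row index grows southward, column index eastward.
``x_origin``/``y_origin`` are the coordinates of the *outer* corner of cell
(0, 0), so the centre of cell (r, c) sits at::

    lon = x_origin + (c + 0.5) * cell_size
    lat = y_origin - (r + 0.5) * cell_size

Two on-disk dialects are supported: the ESRI ASCII grid (``.asc``) and a
minimal single-band GeoTIFF (plate-carree tags only).  Site tables travel as
CSV with columns ``name,lon,lat,culture,role``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, GridFormatError, ParameterError

DEFAULT_NODATA = -9999.0

_CULTURES = {"Micoquian", "Mousterian", "other"}
_ROLES = {"start", "end", "waypoint", "candidate"}


@dataclass
class GeoGrid:
    """A georeferenced raster of values on square geographic cells."""

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    nodata: float = DEFAULT_NODATA
    crs_tag: str = "geographic-WGS84"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise GridFormatError("grid values must be a 2-D array")
        if not (self.cell_size > 0):
            raise GridFormatError(f"cellsize must be positive, got {self.cell_size}")

    # -- geometry -----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def lats(self) -> np.ndarray:
        """Latitudes of row centres, north to south."""
        return self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def lons(self) -> np.ndarray:
        """Longitudes of column centres, west to east."""
        return self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x_origin + (col + 0.5) * self.cell_size,
            self.y_origin - (row + 0.5) * self.cell_size,
        )

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a lon/lat point."""
        col = int(np.floor((lon - self.x_origin) / self.cell_size))
        row = int(np.floor((self.y_origin - lat) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise AlignmentError(f"point ({lon}, {lat}) falls outside the grid")
        return row, col

    def same_geometry(self, other: "GeoGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    # -- values -------------------------------------------------------------
    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata

    def finite_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "GeoGrid":
        """A new grid sharing this geometry but carrying different values."""
        grid = replace(self, values=np.asarray(values, dtype=np.float64))
        if nodata is not None:
            grid.nodata = nodata
        return grid


def require_same_geometry(*grids: GeoGrid) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_geometry(g):
            raise AlignmentError("grids do not share shape/origin/cell size")


# ---------------------------------------------------------------------------
# ESRI ASCII grid dialect
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_ascii(path) -> GeoGrid:
    with open(path) as fh:
        header: dict[str, float] = {}
        line_no = 0
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise GridFormatError("unexpected end of file in header")
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                key = parts[0].lower()
                if not _is_number(parts[1]):
                    raise GridFormatError(f"malformed header field '{key}'")
                header[key] = float(parts[1])
                line_no += 1
            else:
                fh.seek(pos)
                break
        for key in _HEADER_KEYS:
            if key not in header:
                raise GridFormatError(f"missing header field '{key}'")
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        if ncols <= 0 or nrows <= 0:
            raise GridFormatError("ncols/nrows must be positive")
        if header["cellsize"] <= 0:
            raise GridFormatError(f"cellsize must be positive, got {header['cellsize']:g}")
        nodata = header.get("nodata_value", DEFAULT_NODATA)
        data = np.loadtxt(fh, dtype=np.float64, ndmin=2)
        if data.shape != (nrows, ncols):
            raise GridFormatError(
                f"data block is {data.shape}, header says ({nrows}, {ncols})"
            )
    cell = header["cellsize"]
    return GeoGrid(
        values=data,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        nodata=nodata,
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _write_ascii(grid: GeoGrid, path, precision: int = 6) -> None:
    fmt = f"%.{precision}g"
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {grid.y_origin - grid.n_rows * grid.cell_size!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {fmt % grid.nodata}\n")
        np.savetxt(fh, grid.values, fmt=fmt)


# ---------------------------------------------------------------------------
# GeoTIFF dialect (minimal geographic single-band flavour)
# ---------------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey directory declaring a geographic WGS-84 raster
_GEO_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


def _read_geotiff(path) -> GeoGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = np.asarray(page.asarray(), dtype=np.float64)
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise GridFormatError("GeoTIFF lacks georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        if abs(sx - sy) > 1e-12:
            raise GridFormatError(f"non-square cells unsupported ({sx} x {sy})")
        tie = tags[_TAG_TIEPOINT].value
        # tiepoint maps raster (i, j) -> model (x, y); we only support (0, 0)
        if abs(tie[0]) > 1e-12 or abs(tie[1]) > 1e-12:
            raise GridFormatError("only corner-anchored tiepoints supported")
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    if data.ndim != 2:
        raise GridFormatError("multi-band GeoTIFF unsupported")
    return GeoGrid(values=data, x_origin=float(tie[3]), y_origin=float(tie[4]),
                   cell_size=float(sx), nodata=nodata)


def _write_geotiff(grid: GeoGrid, path) -> None:
    import tifffile

    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x_origin, grid.y_origin, 0.0)),
        (_TAG_GEO_KEYS, "H", len(_GEO_KEYS), _GEO_KEYS),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)),
    ]
    tifffile.imwrite(path, grid.values, extratags=extratags)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_grid(path, dialect: str = "ascii_grid") -> GeoGrid:
    """Read a raster in the named dialect (``ascii_grid`` or ``geotiff``)."""
    if dialect == "ascii_grid":
        return _read_ascii(path)
    if dialect == "geotiff":
        return _read_geotiff(path)
    raise ParameterError(f"unknown dialect '{dialect}'")


def write_grid(grid: GeoGrid, path, dialect: str = "ascii_grid", precision: int = 6) -> None:
    """Write a raster; ``precision`` (significant digits) applies to ASCII only.

    Six significant digits is the default round-trip exactness boundary of the
    ASCII dialect; pass ``precision=17`` for lossless float64 text.
    """
    if dialect == "ascii_grid":
        _write_ascii(grid, path, precision=precision)
    elif dialect == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise ParameterError(f"unknown dialect '{dialect}'")


def align_to(reference: GeoGrid, other: GeoGrid, method: str = "nearest") -> GeoGrid:
    """Resample ``other`` onto ``reference``'s geometry.

    ``nearest`` picks the containing cell of ``other``; ``bilinear``
    interpolates between the four surrounding cell centres.  Nodata (and
    off-extent samples) propagate as ``reference``-flavoured nodata.
    """
    if method not in ("nearest", "bilinear"):
        raise ParameterError(f"unknown resampling method '{method}'")
    # extent overlap check (outer edges)
    ref_w, ref_e = reference.x_origin, reference.x_origin + reference.n_cols * reference.cell_size
    ref_s, ref_n = reference.y_origin - reference.n_rows * reference.cell_size, reference.y_origin
    oth_w, oth_e = other.x_origin, other.x_origin + other.n_cols * other.cell_size
    oth_s, oth_n = other.y_origin - other.n_rows * other.cell_size, other.y_origin
    if ref_w >= oth_e or oth_w >= ref_e or ref_s >= oth_n or oth_s >= ref_n:
        raise AlignmentError("grid extents do not overlap")

    lons = reference.lons()
    lats = reference.lats()
    # fractional index of each reference centre in `other`'s index space
    fc = (lons[None, :] - other.x_origin) / other.cell_size - 0.5
    fr = (other.y_origin - lats[:, None]) / other.cell_size - 0.5
    fc = np.broadcast_to(fc, reference.shape)
    fr = np.broadcast_to(fr, reference.shape)

    src = other.values
    src_nodata = other.nodata_mask
    out = np.full(reference.shape, reference.nodata, dtype=np.float64)

    if method == "nearest":
        rc = np.rint(fr).astype(np.int64)
        cc = np.rint(fc).astype(np.int64)
        inside = (rc >= 0) & (rc < other.n_rows) & (cc >= 0) & (cc < other.n_cols)
        rs, cs = rc[inside], cc[inside]
        vals = src[rs, cs]
        good = ~src_nodata[rs, cs]
        tmp = np.full(rs.shape, reference.nodata)
        tmp[good] = vals[good]
        out[inside] = tmp
    else:  # bilinear
        r0 = np.floor(fr).astype(np.int64)
        c0 = np.floor(fc).astype(np.int64)
        # a sample landing exactly on the last centre still has weight-1 support
        r0 = np.minimum(r0, other.n_rows - 2)
        c0 = np.minimum(c0, other.n_cols - 2)
        tr = fr - r0
        tc = fc - c0
        inside = (fr >= 0) & (fr <= other.n_rows - 1) & (fc >= 0) & (fc <= other.n_cols - 1)
        r0i, c0i = r0[inside], c0[inside]
        tri, tci = tr[inside], tc[inside]
        q00 = src[r0i, c0i]
        q01 = src[r0i, c0i + 1]
        q10 = src[r0i + 1, c0i]
        q11 = src[r0i + 1, c0i + 1]
        bad = (
            src_nodata[r0i, c0i] | src_nodata[r0i, c0i + 1]
            | src_nodata[r0i + 1, c0i] | src_nodata[r0i + 1, c0i + 1]
        )
        interp = (
            q00 * (1 - tri) * (1 - tci)
            + q01 * (1 - tri) * tci
            + q10 * tri * (1 - tci)
            + q11 * tri * tci
        )
        interp[bad] = reference.nodata
        out[inside] = interp

    return GeoGrid(values=out, x_origin=reference.x_origin, y_origin=reference.y_origin,
                   cell_size=reference.cell_size, nodata=reference.nodata)


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

@dataclass
class SiteTable:
    """Named lon/lat sites with a culture label and a routing role."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["name", "lon", "lat", "culture", "role"]))

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        missing = {"name", "lon", "lat", "culture", "role"} - set(df.columns)
        if missing:
            raise GridFormatError(f"site table missing columns {sorted(missing)}")
        if df["name"].duplicated().any():
            dupes = df.loc[df["name"].duplicated(), "name"].tolist()
            raise GridFormatError(f"duplicate site names {dupes}")
        if len(df) and not (
            df["lon"].between(-180, 180).all() and df["lat"].between(-90, 90).all()
        ):
            raise GridFormatError("site coordinates outside lon [-180,180] / lat [-90,90]")
        bad_culture = set(df["culture"]) - _CULTURES
        if bad_culture:
            raise GridFormatError(f"unknown culture labels {sorted(bad_culture)}")
        bad_role = set(df["role"]) - _ROLES
        if bad_role:
            raise GridFormatError(f"unknown roles {sorted(bad_role)}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return (row for _, row in self.df.iterrows())

    def get(self, name: str) -> pd.Series:
        hit = self.df[self.df["name"] == name]
        if hit.empty:
            raise KeyError(f"no site named '{name}'")
        return hit.iloc[0]

    def names(self) -> list[str]:
        return self.df["name"].tolist()


def read_sites(path) -> SiteTable:
    return SiteTable(pd.read_csv(path))


def write_sites(sites: SiteTable, path) -> None:
    sites.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GeoJSON helpers (paths and polygons)
# ---------------------------------------------------------------------------

def read_polygons_geojson(path) -> list[list[tuple[float, float]]]:
    """Exterior rings of all (Multi)Polygon features, as lon/lat lists."""
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    rings = []
    for feat in feats:
        geom = feat.get("geometry", feat)
        if geom["type"] == "Polygon":
            rings.append([tuple(pt) for pt in geom["coordinates"][0]])
        elif geom["type"] == "MultiPolygon":
            for poly in geom["coordinates"]:
                rings.append([tuple(pt) for pt in poly[0]])
    return rings


def write_polygons_geojson(polygons, path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {},
            "geometry": {"type": "Polygon", "coordinates": [[list(pt) for pt in ring]]},
        }
        for ring in polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)
        fh.write("\n")
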