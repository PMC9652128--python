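"""Georeferenced raster and vector primitives.

All pipeline stages share one raster convention:

* ``values`` is a row-major 2-D float array; row 0 is the northernmost row.
* ``(x_origin, y_origin)`` is the *outer* corner of the top-left cell, so the
  center of cell ``(r, c)`` is ``(x_origin + (c + 0.5) * cell_size,
  y_origin - (r + 0.5) * cell_size)``.
* Cells are square. A cell's extent is half-open: ``[left, right)`` in x and
  ``(bottom, top]`` in y, so points on an interior boundary map to the larger
  column / larger row index.
* Internally, nodata is ``NaN`` and unreachable-but-valid is ``+inf``; both
  are written to disk as the nodata sentinel and read back as ``NaN``.

Grids may be projected (map units = meters, planar distances) or geographic
(map units = decimal degrees, haversine great-circle distances on a sphere of
radius 6,371,009 m).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from shapely.geometry import Point, mapping, shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_M = 6_371_009.0

CrsKind = Literal["projected_m", "geographic_deg"]

#: sentinel returned by :func:`point_to_cell` for points outside the grid
OUTSIDE = (-1, -1)


class GridFormatError(ValueError):
    """Raised for unreadable rasters or unsupported geometry (non-square cells)."""


@dataclass
class RasterGrid:
    """A single-band georeferenced raster with square cells.

    Parameters
    ----------
    values
        2-D float array, shape ``(nrows, ncols)``. NaN marks nodata.
    x_origin, y_origin
        Map coordinates of the outer corner of the top-left cell.
    cell_size
        Cell edge length in map units (> 0).
    nodata
        Sentinel written to disk for NaN/inf cells.
    crs_kind
        ``"projected_m"`` (planar meters) or ``"geographic_deg"`` (lon/lat).
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    nodata: float = -9999.0
    crs_kind: CrsKind = "projected_m"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GridFormatError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise GridFormatError("cell_size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        """New grid sharing this grid's georeferencing with different values."""
        if values.shape != self.values.shape:
            raise ValueError("replacement values must match the grid shape")
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            cell_size=self.cell_size,
            nodata=self.nodata,
            crs_kind=self.crs_kind,
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x_origin + (col + 0.5) * self.cell_size,
            self.y_origin - (row + 0.5) * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs of all columns, ys of all rows) as 1-D arrays."""
        xs = self.x_origin + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(self.nrows) + 0.5) * self.cell_size
        return xs, ys


@dataclass
class FacilitySet:
    """Health-facility point locations in the grid CRS."""

    points: np.ndarray  # (n, 2) array of (x, y)
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not self.ids:
            self.ids = [f"fac_{i}" for i in range(len(self.points))]
        if len(self.ids) != len(self.points):
            raise ValueError("ids and points length mismatch")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class AdminPolygons:
    """Administrative-unit polygons used to constrain cluster displacement."""

    polygons: list[BaseGeometry]
    ids: list[str]

    def __post_init__(self) -> None:
        if len(self.polygons) != len(self.ids):
            raise ValueError("ids and polygons length mismatch")
        for pid, poly in zip(self.ids, self.polygons):
            if not poly.is_valid:
                raise ValueError(f"polygon {pid!r} is invalid (self-intersecting?)")

    def containing(self, x: float, y: float) -> int | None:
        """Index of the first polygon (file order) containing the point, else None."""
        p = Point(x, y)
        for i, poly in enumerate(self.polygons):
            # boundary points count as inside so cluster centroids on shared
            # tile edges are assignable
            if poly.covers(p):
                return i
        return None


@dataclass
class AccessibilitySurface:
    """A RasterGrid tagged with the accessibility method that produced it.

    Methods: ``ED`` (meters to closest facility), ``CD_M``/``CD_W`` (travel
    minutes, motorized/walking), ``KD`` (dimensionless kernel density; higher
    is better, opposite sign convention to the others).
    """

    grid: RasterGrid
    method: Literal["ED", "CD_M", "CD_W", "KD"]
    units: Literal["meters", "minutes", "dimensionless"]


# ---------------------------------------------------------------------------
# point <-> cell conversions
# ---------------------------------------------------------------------------

def point_to_cell(grid: RasterGrid, x: float, y: float) -> tuple[int, int]:
    """Cell (row, col) whose extent contains (x, y), or OUTSIDE.

    Cell extents are half-open, [left, right) x (bottom, top], so boundary
    points go to the larger column / larger row index.
    """
    col = math.floor((x - grid.x_origin) / grid.cell_size)
    row = math.floor((grid.y_origin - y) / grid.cell_size)
    if 0 <= row < grid.nrows and 0 <= col < grid.ncols:
        return (row, col)
    return OUTSIDE


def points_to_cells(grid: RasterGrid, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized point_to_cell: (rows, cols, inside-mask) for an (n, 2) array."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    cols = np.floor((pts[:, 0] - grid.x_origin) / grid.cell_size).astype(int)
    rows = np.floor((grid.y_origin - pts[:, 1]) / grid.cell_size).astype(int)
    inside = (rows >= 0) & (rows < grid.nrows) & (cols >= 0) & (cols < grid.ncols)
    return rows, cols, inside


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in meters between lon/lat points (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def point_distance(grid: RasterGrid, x1: float, y1: float, x2: float, y2: float) -> float:
    """Distance in meters between two map points under the grid's CRS kind."""
    if grid.crs_kind == "projected_m":
        return float(math.hypot(x2 - x1, y2 - y1))
    return float(haversine_m(x1, y1, x2, y2))


def cell_center_distance(grid: RasterGrid, cell_a: tuple[int, int], cell_b: tuple[int, int]) -> float:
    """Distance in meters between two cell centers (planar or haversine)."""
    xa, ya = grid.cell_center(*cell_a)
    xb, yb = grid.cell_center(*cell_b)
    return point_distance(grid, xa, ya, xb, yb)


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def _encode_nodata(grid: RasterGrid) -> np.ndarray:
    out = grid.values.copy()
    out[~np.isfinite(out)] = grid.nodata
    return out


def _decode_nodata(values: np.ndarray, nodata: float | None) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if nodata is not None:
        values = np.where(np.isclose(values, nodata, rtol=1e-9, atol=0.0), np.nan, values)
    return values


def write_raster(grid: RasterGrid, path: str | Path, format: str = "geotiff") -> None:
    """Write a grid to disk as GeoTIFF or ESRI-ASCII; inf/NaN become nodata."""
    path = Path(path)
    if format == "esri_ascii":
        _write_esri_ascii(grid, path)
    elif format == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise GridFormatError(f"unknown raster format {format!r}")


def read_raster(path: str | Path, format: str | None = None,
                crs_kind: CrsKind | None = None) -> RasterGrid:
    """Read a GeoTIFF or ESRI-ASCII raster; nodata cells become NaN.

    ``format`` is inferred from the suffix when omitted. ``crs_kind``
    overrides the CRS kind for formats that cannot store one (ESRI ASCII).
    """
    path = Path(path)
    if format is None:
        format = "esri_ascii" if path.suffix.lower() in {".asc", ".txt"} else "geotiff"
    if format == "esri_ascii":
        grid = _read_esri_ascii(path)
    elif format == "geotiff":
        grid = _read_geotiff(path)
    else:
        raise GridFormatError(f"unknown raster format {format!r}")
    if crs_kind is not None:
        grid.crs_kind = crs_kind
    return grid


def _write_esri_ascii(grid: RasterGrid, path: Path) -> None:
    vals = _encode_nodata(grid)
    yll = grid.y_origin - grid.nrows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def _read_esri_ascii(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    try:
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if not data_lines and key in {"ncols", "nrows", "xllcorner", "yllcorner",
                                              "cellsize", "dx", "dy", "nodata_value"}:
                    header[key] = float(parts[1])
                else:
                    data_lines.append(line)
    except OSError as exc:
        raise GridFormatError(f"cannot read {path}: {exc}") from exc
    if "dx" in header or "dy" in header:
        if header.get("dx") != header.get("dy"):
            raise GridFormatError("rectangular cells are not supported")
        header["cellsize"] = header["dx"]
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise GridFormatError(f"ESRI ASCII header missing {req}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    values = np.loadtxt(data_lines, dtype=float, ndmin=2)
    if values.size != nrows * ncols:
        raise GridFormatError("ESRI ASCII data size does not match header")
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    return RasterGrid(
        values=_decode_nodata(values, nodata),
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * header["cellsize"],
        cell_size=header["cellsize"],
        nodata=nodata,
    )


# GeoTIFF tag ids
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113
_GEOKEY_MODEL_TYPE = 1024  # 1 = projected, 2 = geographic


def _write_geotiff(grid: RasterGrid, path: Path) -> None:
    import tifffile

    vals = _encode_nodata(grid)
    model_type = 2 if grid.crs_kind == "geographic_deg" else 1
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x_origin, grid.y_origin, 0.0)),
        (_TAG_GEO_KEYS, "H", 8, (1, 1, 0, 1, _GEOKEY_MODEL_TYPE, 0, 1, model_type)),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def _read_geotiff(path: Path) -> RasterGrid:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray().astype(float)
            tags = {t.code: t.value for t in page.tags.values()}
    except Exception as exc:  # tifffile raises several types for bad files
        raise GridFormatError(f"cannot read GeoTIFF {path}: {exc}") from exc
    if values.ndim != 2:
        raise GridFormatError("multi-band rasters are not supported")
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise GridFormatError(f"{path} lacks GeoTIFF georeferencing tags")
    sx, sy = tags[_TAG_PIXEL_SCALE][0], tags[_TAG_PIXEL_SCALE][1]
    if not math.isclose(sx, sy, rel_tol=1e-12):
        raise GridFormatError("rectangular cells are not supported")
    tie = tags[_TAG_TIEPOINT]
    # tiepoint maps raster (i, j) -> model (x, y); we require the corner anchor
    x_origin = tie[3] - tie[0] * sx
    y_origin = tie[4] + tie[1] * sy
    crs_kind: CrsKind = "projected_m"
    if _TAG_GEO_KEYS in tags:
        keys = tags[_TAG_GEO_KEYS]
        for k in range(4, len(keys), 4):
            if keys[k] == _GEOKEY_MODEL_TYPE and keys[k + 3] == 2:
                crs_kind = "geographic_deg"
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        nodata = float(tags[_TAG_GDAL_NODATA])
    return RasterGrid(
        values=_decode_nodata(values, nodata),
        x_origin=x_origin,
        y_origin=y_origin,
        cell_size=sx,
        nodata=nodata if nodata is not None else -9999.0,
        crs_kind=crs_kind,
    )


# ---------------------------------------------------------------------------
# vector I/O
# ---------------------------------------------------------------------------

def write_facilities_csv(facilities: FacilitySet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "x", "y"])
        for fid, (x, y) in zip(facilities.ids, facilities.points):
            writer.writerow([fid, repr(float(x)), repr(float(y))])


def read_facilities_csv(path: str | Path) -> FacilitySet:
    ids: list[str] = []
    pts: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            ids.append(rec["id"])
            pts.append((float(rec["x"]), float(rec["y"])))
    return FacilitySet(points=np.array(pts, dtype=float).reshape(-1, 2), ids=ids)


def write_facilities_geojson(facilities: FacilitySet, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"id": fid},
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
        }
        for fid, (x, y) in zip(facilities.ids, facilities.points)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_facilities_geojson(path: str | Path) -> FacilitySet:
    with open(path) as fh:
        doc = json.load(fh)
    ids, pts = [], []
    for i, feat in enumerate(doc["features"]):
        geom = feat["geometry"]
        if geom["type"] != "Point":
            raise GridFormatError("facility GeoJSON must contain Point features")
        ids.append(str(feat.get("properties", {}).get("id", f"fac_{i}")))
        pts.append(tuple(geom["coordinates"][:2]))
    return FacilitySet(points=np.array(pts, dtype=float).reshape(-1, 2), ids=ids)


def write_admin_geojson(admin: AdminPolygons, path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {"id": pid}, "geometry": mapping(poly)}
        for pid, poly in zip(admin.ids, admin.polygons)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_admin_geojson(path: str | Path) -> AdminPolygons:
    with open(path) as fh:
        doc = json.load(fh)
    ids, polys = [], []
    for i, feat in enumerate(doc["features"]):
        ids.append(str(feat.get("properties", {}).get("id", f"admin_{i}")))
        polys.append(shape(feat["geometry"]))
    return AdminPolygons(polygons=polys, ids=ids)
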