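"""The four modelled-accessibility surfaces.

Four methods, each producing one value per raster cell:

* **ED** — planar or great-circle distance (m) to the closest facility, using
  exact facility coordinates.
* **CD-M / CD-W** — accumulated least travel time (min) from the nearest
  facility over a friction raster (min/m), motorized or walking, via
  multi-source Dijkstra on the raster graph. The edge cost between adjacent
  cells a, b is ``dist(center_a, center_b) * (f_a + f_b) / 2``.
* **KD** — sum over facilities of an unnormalized Gaussian kernel
  ``exp(-d^2 / (2 sigma^2))`` truncated at a distance threshold (15 km by
  default); dimensionless, and the only method where larger = better access.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grid import (
    AccessibilitySurface,
    FacilitySet,
    RasterGrid,
    haversine_m,
    points_to_cells,
)

__all__ = [
    "FrictionSurface",
    "KernelConfig",
    "euclidean_surface",
    "cost_distance_surface",
    "kernel_density_surface",
    "resample_to",
    "extract_at_points",
]


@dataclass
class FrictionSurface:
    """Traversal time per unit distance (minutes per meter) on a grid.

    Impassable cells are +inf (or NaN for nodata); all other values must be
    strictly positive.
    """

    grid: RasterGrid
    mode: Literal["motorized", "walking"]

    def __post_init__(self) -> None:
        vals = self.grid.values
        finite = np.isfinite(vals)
        if np.any(vals[finite] <= 0):
            raise ValueError("friction values must be strictly positive")


@dataclass
class KernelConfig:
    """Gaussian kernel parameters: hard truncation radius and scale, meters."""

    threshold: float = 15_000.0
    sigma: float | None = None  # defaults to threshold / 3

    def __post_init__(self) -> None:
        if self.sigma is None:
            self.sigma = self.threshold / 3.0
        if self.threshold <= 0 or self.sigma <= 0:
            raise ValueError("threshold and sigma must be positive")


def _distances_to_point(template: RasterGrid, fx: float, fy: float) -> np.ndarray:
    """Distance (m) from every cell center to one facility point."""
    xs, ys = template.cell_centers()
    if template.crs_kind == "projected_m":
        dx = xs[None, :] - fx
        dy = ys[:, None] - fy
        return np.hypot(dx, dy)
    lon = np.broadcast_to(xs[None, :], (template.nrows, template.ncols))
    lat = np.broadcast_to(ys[:, None], (template.nrows, template.ncols))
    return haversine_m(lon, lat, fx, fy)


def euclidean_surface(template: RasterGrid, facilities: FacilitySet) -> AccessibilitySurface:
    """Distance in meters from each cell center to the closest facility.

    Facilities are used at their exact coordinates (not snapped to cells).
    """
    if len(facilities) == 0:
        raise ValueError("facility set is empty")
    best = np.full((template.nrows, template.ncols), np.inf)
    for fx, fy in facilities.points:
        np.minimum(best, _distances_to_point(template, fx, fy), out=best)
    return AccessibilitySurface(grid=template.copy_with(best), method="ED", units="meters")


# neighbor offsets: 8-connectivity (rook + bishop), 16 adds knight moves
_OFFSETS_8 = [(0, 1), (1, 0), (1, 1), (1, -1)]
_OFFSETS_16 = _OFFSETS_8 + [(1, 2), (2, 1), (2, -1), (1, -2)]


def _row_step_distances(grid: RasterGrid, dr: int, dc: int) -> np.ndarray:
    """Center-to-center distance (m) for offset (dr, dc), per source row.

    On projected grids this is constant; on geographic grids it varies with
    latitude. Returned as an array over source rows 0..nrows-1-dr.
    """
    n = grid.nrows - dr
    if grid.crs_kind == "projected_m":
        d = grid.cell_size * float(np.hypot(dr, dc))
        return np.full(n, d)
    xs, ys = grid.cell_centers()
    lon0 = np.full(n, xs[0])
    lon1 = np.full(n, xs[0] + dc * grid.cell_size)
    return np.asarray(haversine_m(lon0, ys[:n], lon1, ys[dr : dr + n]))


def _snap_facilities(grid: RasterGrid, facilities: FacilitySet) -> np.ndarray:
    rows, cols, inside = points_to_cells(grid, facilities.points)
    n_out = int(np.sum(~inside))
    if n_out:
        warnings.warn(f"{n_out} facilities outside the grid were dropped", stacklevel=3)
    if not np.any(inside):
        raise ValueError("all facilities fall outside the grid")
    return np.unique(rows[inside] * grid.ncols + cols[inside])


def cost_distance_surface(
    friction: FrictionSurface,
    facilities: FacilitySet,
    connectivity: int = 8,
) -> AccessibilitySurface:
    """Accumulated least travel time (min) from the nearest facility.

    Multi-source Dijkstra over the raster graph: facility cells start at 0,
    each edge costs inter-center distance times the mean of the two cells'
    friction. Cells cut off by impassable friction come back as +inf.
    """
    if connectivity == 8:
        offsets = _OFFSETS_8
    elif connectivity == 16:
        offsets = _OFFSETS_16
    else:
        raise ValueError("connectivity must be 8 or 16")
    grid = friction.grid
    f = grid.values
    nrows, ncols = grid.nrows, grid.ncols
    sources = _snap_facilities(grid, facilities)

    passable = np.isfinite(f)
    rows_i, cols_i, rows_j, cols_j, weights = [], [], [], [], []
    for dr, dc in offsets:
        r0 = np.arange(max(0, -dr), min(nrows, nrows - dr))
        c0 = np.arange(max(0, -dc), min(ncols, ncols - dc))
        if r0.size == 0 or c0.size == 0:
            continue
        rr, cc = np.meshgrid(r0, c0, indexing="ij")
        rr2, cc2 = rr + dr, cc + dc
        ok = passable[rr, cc] & passable[rr2, cc2]
        step = _row_step_distances(grid, dr, abs(dc))
        # all offsets have dr >= 0, so the northern row of each pair is rr
        w = step[rr[ok]] * 0.5 * (f[rr, cc][ok] + f[rr2, cc2][ok])
        rows_i.append(rr[ok])
        cols_i.append(cc[ok])
        rows_j.append(rr2[ok])
        cols_j.append(cc2[ok])
        weights.append(w)

    n = nrows * ncols
    if weights:
        i = np.concatenate(rows_i) * ncols + np.concatenate(cols_i)
        j = np.concatenate(rows_j) * ncols + np.concatenate(cols_j)
        w = np.concatenate(weights)
        graph = coo_matrix((w, (i, j)), shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    dist = dijkstra(graph.tocsr(), directed=False, indices=sources, min_only=True)
    values = dist.reshape(nrows, ncols)
    values[~passable] = np.inf
    values[np.isnan(f)] = np.nan
    method = "CD_M" if friction.mode == "motorized" else "CD_W"
    return AccessibilitySurface(grid=grid.copy_with(values), method=method, units="minutes")


def kernel_density_surface(
    template: RasterGrid,
    facilities: FacilitySet,
    cfg: KernelConfig | None = None,
) -> AccessibilitySurface:
    """Truncated-Gaussian facility density; 0 exactly beyond the threshold."""
    if len(facilities) == 0:
        raise ValueError("facility set is empty")
    if cfg is None:
        cfg = KernelConfig()
    total = np.zeros((template.nrows, template.ncols))
    inv = 1.0 / (2.0 * cfg.sigma**2)
    for fx, fy in facilities.points:
        d = _distances_to_point(template, fx, fy)
        k = np.exp(-(d**2) * inv)
        k[d > cfg.threshold] = 0.0
        total += k
    return AccessibilitySurface(grid=template.copy_with(total), method="KD", units="dimensionless")


def resample_to(surface: AccessibilitySurface, template: RasterGrid) -> AccessibilitySurface:
    """Nearest-neighbor resampling: look up the source value at each template
    cell center. Template cells outside the source extent become NaN."""
    src = surface.grid
    xs, ys = template.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    rows, cols, inside = points_to_cells(src, pts)
    if not np.any(inside):
        warnings.warn("template extent is disjoint from the source surface", stacklevel=2)
        raise ValueError("template and source extents do not overlap")
    out = np.full(pts.shape[0], np.nan)
    out[inside] = src.values[rows[inside], cols[inside]]
    values = out.reshape(template.nrows, template.ncols)
    return AccessibilitySurface(grid=template.copy_with(values), method=surface.method, units=surface.units)


def extract_at_points(surface: AccessibilitySurface, points: np.ndarray) -> np.ndarray:
    """Surface value of the containing cell per point; NaN when outside/nodata."""
    rows, cols, inside = points_to_cells(surface.grid, np.asarray(points, dtype=float))
    out = np.full(len(rows), np.nan)
    out[inside] = surface.grid.values[rows[inside], cols[inside]]
    return out
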