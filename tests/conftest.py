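import heapq
import math

import numpy as np
import pytest

from accessmap.grid import FacilitySet, RasterGrid
from accessmap.surfaces import FrictionSurface

WALK = 0.012  # min/m, 5 km/h


@pytest.fixture
def small_grid() -> RasterGrid:
    """10x10 projected grid, 1 km cells, origin at (0, 10000)."""
    return RasterGrid(values=np.zeros((10, 10)), x_origin=0.0, y_origin=10_000.0, cell_size=1_000.0)


@pytest.fixture
def uniform_friction(small_grid) -> FrictionSurface:
    return FrictionSurface(grid=small_grid.copy_with(np.full((10, 10), WALK)), mode="walking")


@pytest.fixture
def corner_facility(small_grid) -> FacilitySet:
    """Single facility at the center of cell (0, 0)."""
    return FacilitySet(points=np.array([small_grid.cell_center(0, 0)]))


# ---------------------------------------------------------------------------
# independent oracles (deliberately simple, no reuse of package internals)
# ---------------------------------------------------------------------------

def brute_force_ed(grid: RasterGrid, facilities: FacilitySet) -> np.ndarray:
    """Min-over-facilities distance per cell via explicit double loop."""
    out = np.empty((grid.nrows, grid.ncols))
    for r in range(grid.nrows):
        for c in range(grid.ncols):
            cx = grid.x_origin + (c + 0.5) * grid.cell_size
            cy = grid.y_origin - (r + 0.5) * grid.cell_size
            best = math.inf
            for fx, fy in facilities.points:
                if grid.crs_kind == "projected_m":
                    d = math.hypot(cx - fx, cy - fy)
                else:
                    d = scalar_haversine(cx, cy, fx, fy)
                best = min(best, d)
            out[r, c] = best
    return out


def scalar_haversine(lon1, lat1, lon2, lat2, radius=6_371_009.0) -> float:
    """Scalar haversine written from the textbook formula."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * radius * math.asin(min(1.0, math.sqrt(a)))


def spherical_law_of_cosines(lon1, lat1, lon2, lat2, radius=6_371_009.0) -> float:
    """Great-circle distance via the spherical law of cosines."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    cosang = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius * math.acos(min(1.0, max(-1.0, cosang)))


def brute_force_cost_distance(
    friction: np.ndarray, cell_size: float, sources: list[tuple[int, int]], connectivity: int = 8
) -> np.ndarray:
    """Plain heapq Dijkstra on an explicitly constructed edge list."""
    nrows, ncols = friction.shape
    offsets = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)]
    if connectivity == 16:
        offsets += [
            (1, 2), (2, 1), (2, -1), (1, -2), (-1, -2), (-2, -1), (-2, 1), (-1, 2),
        ]
    dist = np.full((nrows, ncols), math.inf)
    heap = []
    for r, c in sources:
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc in offsets:
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < nrows and 0 <= c2 < ncols):
                continue
            f1, f2 = friction[r, c], friction[r2, c2]
            if not (math.isfinite(f1) and math.isfinite(f2)):
                continue
            step = cell_size * math.hypot(dr, dc)
            nd = d + step * 0.5 * (f1 + f2)
            if nd < dist[r2, c2]:
                dist[r2, c2] = nd
                heapq.heappush(heap, (nd, r2, c2))
    return dist


def rank_then_pearson(x, y) -> float:
    """Spearman oracle: average-rank both vectors, then plain Pearson."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def random_friction_landscape(rng: np.random.Generator, nrows=20, ncols=20, with_barrier=True):
    """Random positive friction field, optionally with an impassable wall with one gap."""
    f = rng.uniform(0.002, 0.05, size=(nrows, ncols))
    if with_barrier:
        r = int(rng.integers(nrows // 4, 3 * nrows // 4))
        f[r, :] = math.inf
        f[r, int(rng.integers(0, ncols))] = 0.012
    return f
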