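"""Synthetic study-area generator with known ground truth.

Emulates the inputs of a national accessibility study at ~1 km resolution on
a projected grid: a walking friction surface (uniform base speed), a
motorized friction surface (fast along randomly placed road polylines),
impassable barrier strips, a population raster of Gaussian "town" blobs over
a rural floor, facility points placed proportionally to population, and
survey clusters whose per-respondent yes/no answers to the
distance-is-an-obstacle question follow a logistic model on the true
modelled accessibility with urban/rural and motorized/non-motorized stratum
effects plus a cluster-level random intercept.

Because the generating parameters are returned alongside the data, every
pipeline stage can be tested against known structure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from shapely.geometry import box

from .grid import (
    AdminPolygons,
    FacilitySet,
    RasterGrid,
    write_admin_geojson,
    write_facilities_csv,
    write_facilities_geojson,
    write_raster,
)
from .surfaces import (
    AccessibilitySurface,
    FrictionSurface,
    KernelConfig,
    cost_distance_surface,
    euclidean_surface,
    extract_at_points,
    kernel_density_surface,
)

__all__ = [
    "LandscapeConfig",
    "ClusterGenConfig",
    "make_landscape",
    "make_facilities",
    "make_clusters",
    "make_study_bundle",
]


@dataclass
class LandscapeConfig:
    """Geometry and friction parameters of the synthetic landscape.

    Walking friction defaults to 0.012 min/m (5 km/h); roads carry
    0.0012 min/m (50 km/h) in the motorized surface. Barriers are one-cell
    impassable strips with a single gap, imitating rivers or escarpments.
    """

    nrows: int = 200
    ncols: int = 200
    cell_size: float = 1_000.0
    base_walk_friction: float = 0.012
    road_friction: float = 0.0012
    n_roads: int = 8
    n_barriers: int = 2
    n_blobs: int = 6
    pop_floor: float = 5.0
    blob_population: float = 50_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_walk_friction <= 0 or self.road_friction <= 0:
            raise ValueError("frictions must be positive")
        if self.road_friction >= self.base_walk_friction:
            raise ValueError("roads must be faster than walking")


@dataclass
class ClusterGenConfig:
    """Survey-cluster generator parameters.

    The linear predictor of a respondent answering "distance is an obstacle"
    is ``a + b * MA_true + rural_shift * 1[rural] + nonmotorized_shift *
    1[non-motorized] + u_i`` with cluster effect ``u_i ~ N(0, re_sd)``.
    ``b`` is per unit of the driving accessibility surface (per meter for
    ED). Defaults give a population-mean PA near one third, about 35% urban
    respondents and roughly a quarter of households motorized, concentrated
    in towns.
    """

    n_clusters: int = 600
    urban_fraction: float = 0.35
    respondents_range: tuple[int, int] = (15, 40)
    intercept: float = -2.0
    slope: float = 2.0e-4
    rural_shift: float = 0.5
    nonmotorized_shift: float = 0.5
    motorized_prob_urban: float = 0.45
    motorized_prob_rural: float = 0.15
    re_sd: float = 0.5
    driving_method: Literal["ED", "CD_W"] = "ED"
    seed: int = 0


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _rasterize_polyline(nrows: int, ncols: int, r0, c0, r1, c1) -> tuple[np.ndarray, np.ndarray]:
    n = int(2 * max(abs(r1 - r0), abs(c1 - c0))) + 1
    rr = np.clip(np.round(np.linspace(r0, r1, n)).astype(int), 0, nrows - 1)
    cc = np.clip(np.round(np.linspace(c0, c1, n)).astype(int), 0, ncols - 1)
    return rr, cc


def make_landscape(cfg: LandscapeConfig) -> tuple[FrictionSurface, FrictionSurface, RasterGrid]:
    """(walking friction, motorized friction, population) for one landscape."""
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.nrows, cfg.ncols)

    walk = np.full(shape, cfg.base_walk_friction)
    motor = np.full(shape, cfg.base_walk_friction)

    # town centers first: roads connect them, population concentrates there
    centers = rng.uniform([0, 0], [cfg.nrows, cfg.ncols], size=(cfg.n_blobs, 2))
    for _ in range(cfg.n_roads):
        if cfg.n_blobs >= 2 and rng.uniform() < 0.7:
            i, j = rng.choice(cfg.n_blobs, size=2, replace=False)
            r0, c0 = centers[i]
            r1, c1 = centers[j]
        else:
            r0, c0 = rng.uniform([0, 0], [cfg.nrows, cfg.ncols])
            r1, c1 = rng.uniform([0, 0], [cfg.nrows, cfg.ncols])
        rr, cc = _rasterize_polyline(cfg.nrows, cfg.ncols, r0, c0, r1, c1)
        motor[rr, cc] = cfg.road_friction

    for _ in range(cfg.n_barriers):
        if rng.uniform() < 0.5:
            r = int(rng.integers(cfg.nrows // 4, 3 * cfg.nrows // 4))
            gap = int(rng.integers(0, cfg.ncols))
            walk[r, :] = np.inf
            motor[r, :] = np.inf
            walk[r, gap] = cfg.base_walk_friction
            motor[r, gap] = cfg.base_walk_friction
        else:
            c = int(rng.integers(cfg.ncols // 4, 3 * cfg.ncols // 4))
            gap = int(rng.integers(0, cfg.nrows))
            walk[:, c] = np.inf
            motor[:, c] = np.inf
            walk[gap, c] = cfg.base_walk_friction
            motor[gap, c] = cfg.base_walk_friction

    rr, cc = np.meshgrid(np.arange(cfg.nrows), np.arange(cfg.ncols), indexing="ij")
    pop = np.full(shape, cfg.pop_floor)
    sigmas = rng.uniform(3.0, 8.0, size=cfg.n_blobs)  # blob spread in cells
    for (br, bc), s in zip(centers, sigmas):
        dens = np.exp(-((rr - br) ** 2 + (cc - bc) ** 2) / (2 * s**2))
        pop += cfg.blob_population * dens / dens.sum()
    pop[~np.isfinite(walk)] = 0.0  # nobody lives on a barrier

    def grid(values: np.ndarray) -> RasterGrid:
        return RasterGrid(values=values, x_origin=0.0, y_origin=cfg.nrows * cfg.cell_size,
                          cell_size=cfg.cell_size, crs_kind="projected_m")

    return (
        FrictionSurface(grid=grid(walk), mode="walking"),
        FrictionSurface(grid=grid(motor), mode="motorized"),
        grid(pop),
    )


def _population_weighted_cells(population: RasterGrid, n: int, rng: np.random.Generator,
                               replace: bool = True) -> tuple[np.ndarray, np.ndarray]:
    pop = np.where(np.isfinite(population.values), population.values, 0.0).ravel()
    nonzero = pop > 0
    if not replace and n > int(nonzero.sum()):
        raise ValueError(f"cannot place {n} points on {int(nonzero.sum())} populated cells")
    idx = rng.choice(len(pop), size=n, replace=replace, p=pop / pop.sum())
    return np.divmod(idx, population.ncols)


def make_facilities(
    population: RasterGrid,
    n: int,
    placement: Literal["population_weighted", "uniform"] = "population_weighted",
    seed: int = 0,
) -> FacilitySet:
    """Place n facilities, proportional to population or uniformly, with
    sub-cell jitter so points do not sit exactly on cell centers."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if placement == "population_weighted":
        rows, cols = _population_weighted_cells(population, n, rng, replace=False)
    elif placement == "uniform":
        rows = rng.integers(0, population.nrows, size=n)
        cols = rng.integers(0, population.ncols, size=n)
    else:
        raise ValueError(f"unknown placement {placement!r}")
    jitter = rng.uniform(-0.499, 0.499, size=(n, 2))
    xs = population.x_origin + (cols + 0.5 + jitter[:, 0]) * population.cell_size
    ys = population.y_origin - (rows + 0.5 + jitter[:, 1]) * population.cell_size
    return FacilitySet(points=np.column_stack([xs, ys]))


def make_clusters(
    cfg: ClusterGenConfig,
    surfaces: dict[str, AccessibilitySurface],
    population: RasterGrid,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Survey clusters with logistic-model yes/no answers and ground truth.

    Cluster locations are population-weighted cell centers with jitter; the
    urban flag marks the ``urban_fraction`` of clusters with the highest
    local population density. Returns ``(cluster table, ground truth dict)``.
    """
    if cfg.driving_method not in surfaces:
        raise ValueError(f"driving surface {cfg.driving_method} not provided")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = cfg.n_clusters

    rows, cols = _population_weighted_cells(population, n, rng, replace=True)
    jitter = rng.uniform(-0.499, 0.499, size=(n, 2))
    xs = population.x_origin + (cols + 0.5 + jitter[:, 0]) * population.cell_size
    ys = population.y_origin - (rows + 0.5 + jitter[:, 1]) * population.cell_size

    local_pop = population.values[rows, cols]
    cutoff = np.quantile(local_pop, 1.0 - cfg.urban_fraction)
    urban = local_pop >= cutoff

    ma_true = extract_at_points(surfaces[cfg.driving_method], np.column_stack([xs, ys]))
    # clusters sampled on populated cells always have finite accessibility on
    # a connected landscape; guard anyway
    ma_true = np.where(np.isfinite(ma_true), ma_true, np.nanmax(ma_true[np.isfinite(ma_true)]))

    lo, hi = cfg.respondents_range
    n_resp = rng.integers(lo, hi + 1, size=n)
    u = rng.normal(0.0, cfg.re_sd, size=n) if cfg.re_sd > 0 else np.zeros(n)
    p_mot = np.where(urban, cfg.motorized_prob_urban, cfg.motorized_prob_rural)
    n_mot = rng.binomial(n_resp, p_mot)

    base = cfg.intercept + cfg.slope * ma_true + cfg.rural_shift * (~urban) + u
    p_yes_mot = _logistic(base)
    p_yes_nonmot = _logistic(base + cfg.nonmotorized_shift)
    yes_mot = rng.binomial(n_mot, p_yes_mot)
    yes_nonmot = rng.binomial(n_resp - n_mot, p_yes_nonmot)

    clusters = pd.DataFrame(
        {
            "id": [f"cl_{i:04d}" for i in range(n)],
            "x": xs,
            "y": ys,
            "urban": urban,
            "region_id": "r0",  # reassigned when admin tiling is applied
            "n_respondents": n_resp,
            "n_yes": yes_mot + yes_nonmot,
            "n_yes_motorized": yes_mot,
            "n_motorized": n_mot,
        }
    )
    truth = {
        "config": {**asdict(cfg), "respondents_range": list(cfg.respondents_range)},
        "seed": seed,
        "ma_true": ma_true.tolist(),
        "random_effects": u.tolist(),
        "p_yes_motorized": p_yes_mot.tolist(),
        "p_yes_nonmotorized": p_yes_nonmot.tolist(),
    }
    return clusters, truth


def make_admin_tiling(template: RasterGrid, n_tiles_x: int = 4, n_tiles_y: int = 3) -> AdminPolygons:
    """Rectangular tiling of the grid extent into administrative units."""
    x0, y1 = template.x_origin, template.y_origin
    x1 = x0 + template.ncols * template.cell_size
    y0 = y1 - template.nrows * template.cell_size
    dx = (x1 - x0) / n_tiles_x
    dy = (y1 - y0) / n_tiles_y
    polys, ids = [], []
    for iy in range(n_tiles_y):
        for ix in range(n_tiles_x):
            polys.append(box(x0 + ix * dx, y0 + iy * dy, x0 + (ix + 1) * dx, y0 + (iy + 1) * dy))
            ids.append(f"adm_{iy}_{ix}")
    return AdminPolygons(polygons=polys, ids=ids)


def assign_regions(clusters: pd.DataFrame, admin: AdminPolygons) -> pd.DataFrame:
    out = clusters.copy()
    regions = []
    for x, y in zip(out["x"], out["y"]):
        i = admin.containing(float(x), float(y))
        regions.append(admin.ids[i] if i is not None else "unassigned")
    out["region_id"] = regions
    return out


def make_study_bundle(
    out_dir: str | Path,
    landscape_cfg: LandscapeConfig | None = None,
    cluster_cfg: ClusterGenConfig | None = None,
    n_facilities: int = 80,
    kernel_cfg: KernelConfig | None = None,
    connectivity: int = 8,
    n_tiles: tuple[int, int] = (4, 3),
    seed: int = 0,
) -> dict:
    """Generate and write a complete synthetic study to ``out_dir``.

    Writes the friction and population rasters (GeoTIFF), the four
    accessibility surfaces, facilities (CSV + GeoJSON), the cluster table
    (CSV), the admin tiling (GeoJSON) and a ground-truth JSON. Returns a
    manifest dict of everything produced. Deterministic given ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

    landscape_cfg = landscape_cfg or LandscapeConfig(seed=sub[0])
    cluster_cfg = cluster_cfg or ClusterGenConfig(seed=sub[2])
    kernel_cfg = kernel_cfg or KernelConfig()

    walk, motor, pop = make_landscape(landscape_cfg)
    facilities = make_facilities(pop, n_facilities, seed=sub[1])

    surfaces = {
        "ED": euclidean_surface(pop, facilities),
        "CD_M": cost_distance_surface(motor, facilities, connectivity=connectivity),
        "CD_W": cost_distance_surface(walk, facilities, connectivity=connectivity),
        "KD": kernel_density_surface(pop, facilities, kernel_cfg),
    }
    clusters, truth = make_clusters(cluster_cfg, surfaces, pop)
    admin = make_admin_tiling(pop, *n_tiles)
    clusters = assign_regions(clusters, admin)

    paths = {
        "friction_walk": out_dir / "friction_walk.tif",
        "friction_motor": out_dir / "friction_motor.tif",
        "population": out_dir / "population.tif",
        "facilities_csv": out_dir / "facilities.csv",
        "facilities_geojson": out_dir / "facilities.geojson",
        "clusters": out_dir / "clusters.csv",
        "admin": out_dir / "admin.geojson",
        "ground_truth": out_dir / "ground_truth.json",
    }
    write_raster(walk.grid, paths["friction_walk"])
    write_raster(motor.grid, paths["friction_motor"])
    write_raster(pop, paths["population"])
    for method, surf in surfaces.items():
        p = out_dir / f"surface_{method.lower()}.tif"
        write_raster(surf.grid, p)
        paths[f"surface_{method}"] = p
    write_facilities_csv(facilities, paths["facilities_csv"])
    write_facilities_geojson(facilities, paths["facilities_geojson"])
    clusters.to_csv(paths["clusters"], index=False)
    write_admin_geojson(admin, paths["admin"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1)

    return {
        "seed": seed,
        "stage_seeds": {"landscape": sub[0], "facilities": sub[1], "clusters": sub[2]},
        "paths": {k: str(v) for k, v in paths.items()},
        "n_facilities": n_facilities,
        "n_clusters": len(clusters),
    }
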