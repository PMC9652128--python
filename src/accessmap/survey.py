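"""Perceived-accessibility index, rank correlations, and population summaries.

Perceived access (PA) is the per-cluster proportion of respondents who report
distance as an obstacle to obtaining medical care. Because the PA-MA
(modelled-accessibility) relationship is monotone but not linear — and KD runs
in the opposite direction to the distance/time methods — association is
measured with Spearman rank correlation, reported in absolute value with the
sign kept in metadata.

Cluster tables are plain pandas DataFrames with columns::

    id, x, y, urban, region_id, n_respondents, n_yes, n_yes_motorized, n_motorized

``n_yes`` counts "distance is an obstacle" answers among all respondents,
``n_yes_motorized`` the same among respondents of motorized households.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import AccessibilitySurface, RasterGrid
from .surfaces import extract_at_points

logger = logging.getLogger(__name__)

CLUSTER_COLUMNS = [
    "id", "x", "y", "urban", "region_id",
    "n_respondents", "n_yes", "n_yes_motorized", "n_motorized",
]

#: default accessibility-class boundaries, by surface units
DEFAULT_BREAKS = {
    "meters": [1_000.0, 5_000.0, 10_000.0, 15_000.0],
    "minutes": [10.0, 30.0, 60.0, 120.0],
}


@dataclass
class CorrelationRecord:
    """One Spearman coefficient: variable pair, stratum, |r_s|, sign, p, n."""

    pair: tuple[str, str]
    r_s_abs: float
    sign: int
    p_value: float
    n: int
    stratum: str = "all"

    @property
    def r_s(self) -> float:
        return self.sign * self.r_s_abs


def validate_clusters(clusters: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLUSTER_COLUMNS if c not in clusters.columns]
    if missing:
        raise ValueError(f"cluster table missing columns: {missing}")
    bad = (
        (clusters["n_yes"] < 0)
        | (clusters["n_yes"] > clusters["n_respondents"])
        | (clusters["n_motorized"] < 0)
        | (clusters["n_motorized"] > clusters["n_respondents"])
        | (clusters["n_yes_motorized"] > clusters["n_motorized"])
        | (clusters["n_yes_motorized"] > clusters["n_yes"])
    )
    if bad.any():
        raise ValueError(f"{int(bad.sum())} clusters violate count invariants")
    return clusters


def perceived_access(clusters: pd.DataFrame) -> pd.Series:
    """PA per cluster: share of respondents answering yes to the distance
    question. Clusters with zero respondents are dropped with a warning."""
    zero = clusters["n_respondents"] <= 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} clusters with zero respondents", stacklevel=2)
        clusters = clusters[~zero]
    return clusters["n_yes"] / clusters["n_respondents"]


def subgroup_perceived_access(clusters: pd.DataFrame, motorized: bool) -> pd.Series:
    """PA among (non-)motorized respondents only; NaN where the subgroup is empty."""
    if motorized:
        num, den = clusters["n_yes_motorized"], clusters["n_motorized"]
    else:
        num = clusters["n_yes"] - clusters["n_yes_motorized"]
        den = clusters["n_respondents"] - clusters["n_motorized"]
    return (num / den.where(den > 0)).astype(float)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Spearman r_s (Pearson on mid-ranks) with t-approximation p-value.

    Missing values are removed pairwise. Returns ``(r_s, p, n)``;
    ``(nan, nan, n)`` when n < 3 or either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return (np.nan, np.nan, n)
    r, p = stats.spearmanr(x, y)
    return (float(r), float(p), n)


def extract_ma_table(clusters: pd.DataFrame, surfaces: Sequence[AccessibilitySurface]) -> pd.DataFrame:
    """Cluster table augmented with one MA column per surface (``ma_<method>``)."""
    out = clusters.copy()
    pts = out[["x", "y"]].to_numpy(dtype=float)
    for surf in surfaces:
        out[f"ma_{surf.method}"] = extract_at_points(surf, pts)
    return out


def method_correlation_matrix(
    clusters: pd.DataFrame, surfaces: Sequence[AccessibilitySurface]
) -> tuple[pd.DataFrame, list[CorrelationRecord]]:
    """Pairwise Spearman correlations between the modelled methods.

    Returns the |r_s| matrix (unit diagonal) and the full records carrying
    sign, p-value and n. KD comes out negatively associated with the
    distance/time methods by construction.
    """
    table = extract_ma_table(clusters, surfaces)
    methods = [s.method for s in surfaces]
    mat = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    records: list[CorrelationRecord] = []
    for i, mi in enumerate(methods):
        for j in range(i + 1, len(methods)):
            mj = methods[j]
            r, p, n = spearman(table[f"ma_{mi}"], table[f"ma_{mj}"])
            sign = 0 if not np.isfinite(r) else int(np.sign(r)) or 1
            records.append(CorrelationRecord((mi, mj), abs(r), sign, p, n))
            mat.loc[mi, mj] = mat.loc[mj, mi] = abs(r)
    return mat, records


def _stratum_masks(clusters: pd.DataFrame, strata: Sequence[str]) -> dict[str, pd.Series]:
    masks: dict[str, pd.Series] = {}
    urban = clusters["urban"].astype(bool)
    for s in strata:
        if s == "all":
            masks["all"] = pd.Series(True, index=clusters.index)
        elif s == "urban":
            masks["urban"] = urban
        elif s == "rural":
            masks["rural"] = ~urban
        elif s == "region":
            for rid in sorted(clusters["region_id"].astype(str).unique()):
                masks[f"region:{rid}"] = clusters["region_id"].astype(str) == rid
        elif s not in {"motorized", "non_motorized"}:
            raise ValueError(f"unknown stratum {s!r}")
    return masks


def stratified_pa_ma(
    clusters: pd.DataFrame,
    surfaces: Sequence[AccessibilitySurface],
    strata: Sequence[str] = ("all", "urban", "rural", "motorized", "non_motorized", "region"),
    min_clusters: int = 3,
    subgroup_pa: bool = True,
) -> list[CorrelationRecord]:
    """Spearman(PA, MA) per method and stratum.

    Geographic strata (all/urban/rural/region) subset clusters and use the
    all-respondent PA. Transportation strata recompute PA within the
    (non-)motorized respondent subgroup of every cluster, since motorization
    is a respondent-level attribute, and cross with urban/rural when both
    kinds of strata are requested; pass ``subgroup_pa=False`` to reuse the
    all-respondent PA there instead (the subgroup then only gates which
    clusters enter, via a non-empty subgroup). Strata with fewer than
    ``min_clusters`` usable clusters are skipped with a log entry.
    """
    table = extract_ma_table(validate_clusters(clusters), surfaces)
    pa_all = table["n_yes"] / table["n_respondents"]

    geo = _stratum_masks(table, [s for s in strata if s not in {"motorized", "non_motorized"}])
    transport = [s for s in strata if s in {"motorized", "non_motorized"}]

    pa_variants: list[tuple[str, pd.Series, pd.Series]] = []
    for name, mask in geo.items():
        pa_variants.append((name, pa_all, mask))
    for t in transport:
        pa_sub = subgroup_perceived_access(table, motorized=(t == "motorized"))
        pa_t = pa_sub if subgroup_pa else pa_all.where(pa_sub.notna())
        pa_variants.append((t, pa_t, pd.Series(True, index=table.index)))
        for gname in ("urban", "rural"):
            if gname in geo:
                pa_variants.append((f"{gname}_{t}", pa_t, geo[gname]))

    records: list[CorrelationRecord] = []
    for surf in surfaces:
        ma = table[f"ma_{surf.method}"]
        for name, pa, mask in pa_variants:
            r, p, n = spearman(pa[mask], ma[mask])
            if n < min_clusters or not np.isfinite(r):
                logger.info("stratum %s skipped for %s (n=%d)", name, surf.method, n)
                continue
            sign = int(np.sign(r)) or 1
            records.append(CorrelationRecord(("PA", surf.method), abs(r), sign, p, n, stratum=name))
    return records


def correlation_records_frame(records: Sequence[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "var_a": [r.pair[0] for r in records],
            "var_b": [r.pair[1] for r in records],
            "stratum": [r.stratum for r in records],
            "r_s_abs": [r.r_s_abs for r in records],
            "sign": [r.sign for r in records],
            "p_value": [r.p_value for r in records],
            "n": [r.n for r in records],
        }
    )


def loess_curve(
    x: Sequence[float], y: Sequence[float], span: float = 0.75, n_grid: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Locally weighted (tricube) linear smoothing for visualizing PA-MA shape.

    Evaluated on an even grid over the x-range; returns ``(grid, fitted)``.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 10:
        raise ValueError("loess_curve requires at least 10 points")
    grid = np.linspace(x.min(), x.max(), n_grid)
    fitted = lowess(y, x, frac=span, xvals=grid)
    return grid, fitted


def population_by_class(
    surface: AccessibilitySurface,
    population: RasterGrid,
    breaks: Sequence[float] | None = None,
) -> pd.Series:
    """Share of population per accessibility class.

    Classes are right-closed: (-inf, b1], (b1, b2], ..., (bk, inf), so "less
    than 5 km" means accessibility value <= 5000 at cell resolution. Cells
    with nodata accessibility contribute to an ``unclassified`` share. Not
    defined for KD (dimensionless values have no class boundaries).
    """
    if surface.method == "KD":
        raise ValueError("population_by_class is not defined for the KD method")
    if breaks is None:
        breaks = DEFAULT_BREAKS[surface.units]
    breaks = [float(b) for b in breaks]
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])) or breaks[0] <= 0:
        raise ValueError("breaks must be strictly increasing and positive")
    acc = surface.grid.values
    pop = population.values
    if acc.shape != pop.shape:
        raise ValueError("surface must be resampled to the population grid first")
    pop = np.where(np.isfinite(pop), pop, 0.0)
    total = pop.sum()
    if total <= 0:
        raise ValueError("population grid is empty")
    unclassified = float(pop[np.isnan(acc)].sum())
    ok = ~np.isnan(acc)
    idx = np.digitize(acc[ok], breaks, right=True)  # 0..len(breaks)
    shares = np.bincount(idx, weights=pop[ok], minlength=len(breaks) + 1) / total
    labels = [f"<= {breaks[0]:g}"] + [
        f"({breaks[i]:g}, {breaks[i + 1]:g}]" for i in range(len(breaks) - 1)
    ] + [f"> {breaks[-1]:g}"]
    out = pd.Series(shares, index=labels, name=f"pop_share_{surface.method}")
    out["unclassified"] = unclassified / total
    return out
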