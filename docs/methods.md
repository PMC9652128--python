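# Methods

## Problem and design

Health-planning studies routinely map *modelled accessibility* (MA) to
facilities from GIS layers, while household surveys record *perceived
accessibility* (PA): the share of respondents in a sampling cluster who say
distance is an obstacle to obtaining medical care. This package implements
the full comparison between the two on a common raster frame:

1. four MA surfaces from one facility set — Euclidean distance (ED, meters),
   cost-distance over motorized and walking friction rasters (CD-M, CD-W,
   minutes), and a truncated-Gaussian kernel density of facilities (KD,
   dimensionless, higher = better access);
2. Spearman rank correlations between the methods and between PA and each
   method, overall and stratified by urban/rural, motorized/non-motorized
   respondents, and region;
3. a Monte-Carlo of DHS-style confidentiality displacement of cluster
   coordinates, quantifying how much geomasking attenuates the PA–MA
   correlations;
4. population shares per distance or travel-time class.

Rank correlation is used throughout because the PA–MA relationship is
monotone but nonlinear (a logistic shape fits survey data well) and KD runs
in the opposite direction to the other three methods; coefficients are
reported in absolute value with the sign kept in metadata.

## Raster model

All grids share one convention: row 0 is northernmost, `(x_origin,
y_origin)` is the outer corner of the top-left cell, the center of cell
`(r, c)` is `(x0 + (c+.5)s, y0 − (r+.5)s)`, and a cell's extent is half-open
(`[left, right) × (bottom, top]`, boundary points to the larger index).
Cells are square; rectangular cells are rejected rather than mishandled.
Projected grids use planar meters; geographic grids use haversine distances
on a sphere of radius 6,371,009 m. Internally nodata is NaN and
unreachable-but-valid is +inf; both become the nodata sentinel on disk.
GeoTIFF I/O is implemented directly over the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GDAL_NODATA, GeoKeyDirectory) via
`tifffile`; ESRI-ASCII is supported as a plain-text alternative.

## Accessibility surfaces

**ED** uses exact facility coordinates (no cell snapping) and the grid's
native metric. **CD** snaps facilities to their containing cells, then runs
one multi-source Dijkstra (`scipy.sparse.csgraph`) over the raster graph
with edge cost `distance(center_a, center_b) · (f_a + f_b)/2`, `f` being
friction in min/m; the arithmetic-mean conductance matches the behavior of
the cost-distance tools commonly used for this analysis. Connectivity is 8
by default, with 16 (knight's moves) available; with uniform friction the
raster metric exceeds the straight-line cost by at most ≈8.2% (8-conn) or
≈2.8% (16-conn), which is why walking cost-distance is nearly
rank-identical to ED on homogeneous landscapes. Multiple facilities in one
cell collapse to one source; facilities outside the grid are dropped with a
warning. **KD** sums an *unnormalized* Gaussian `exp(−d²/2σ²)` over
facilities, truncated to exactly 0 beyond a 15 km threshold. The bandwidth
is a free parameter; σ defaults to threshold/3 = 5 km, a choice made here
(no canonical value exists for this kernel), and k(0)=1 keeps summed values
in the low single digits, the familiar scale for this score.

Resampling between grids is nearest-neighbor (value at the template cell
center); whether smoother resampling is preferable is left open, and
nearest keeps extraction exactly reproducible.

## Survey analysis

PA per cluster is `n_yes / n_respondents`. Motorization is a
respondent-level attribute, so the motorized/non-motorized strata recompute
PA within each cluster's subgroup counts (`n_yes_motorized`,
`n_motorized`) and correlate those subgroup PAs with the cluster-level MA;
this is one defensible aggregation among several, and the cluster schema
carries the subgroup counts it needs. Spearman coefficients are Pearson
correlations of mid-ranks with the large-sample t approximation (df = n−2)
for p-values, no multiple-testing correction; strata with fewer than 3
usable clusters are skipped and logged. Population classes are right-closed
intervals `(a, b]` — "within 5 km" means value ≤ 5000 — with defaults 1, 5,
10, 15 km (ED) and 10, 30, 60, 120 min (CD); nodata-accessibility cells are
reported as an `unclassified` share so shares always sum to 1. KD is
excluded from class summaries because its values are dimensionless.
The `loess_curve` helper (tricube local-linear smoothing via statsmodels,
evaluated on an even grid) is for visualizing the PA–MA shape only.

## Displacement Monte-Carlo

Each cluster moves a uniform random distance in a uniform random direction:
up to 2 km (urban) or 5 km (rural), with 1% of rural clusters drawing their
distance from U[0, 10 km] instead — implemented as a per-cluster Bernoulli
replacing the maximum radius, not a second jump. Distance is
uniform-in-distance (not uniform-in-area), matching the published DHS
geomasking description; the choice affects attenuation magnitude. With an
admin-polygon constraint, draws are rejected until the point stays in the
polygon containing the *original* location (first match in file order);
after 1,000 failures the original point is kept with a warning. Offsets are
computed in map units, so displacement assumes projected (meter) grids.
Randomness is keyed by `(seed, replicate, cluster index)` through
`SeedSequence` spawn keys, making every replicate independently
reproducible and reruns bit-identical. The replication study reports, per
method and stratum, the baseline coefficient, the replicate mean/min/max,
and the share of replicates whose |r_s| fell below baseline.

## Synthetic study generator

The generator emulates a national study at desk scale (defaults: 200×200
cells of 1 km, 80 facilities, 600 clusters of 15–40 respondents, runs in
seconds): walking friction uniform at 0.012 min/m (5 km/h); motorized
friction 0.0012 min/m (50 km/h) along random polyline roads that mostly
connect town centers; optional impassable one-cell barrier strips with a
single gap; population as Gaussian town blobs over a rural floor (nobody on
barriers); facilities and clusters sampled proportionally to population
with sub-cell jitter. The urban flag marks the top `urban_fraction` (default
0.35) of clusters by local population density. Respondent answers follow
`P(yes) = logistic(a + b·MA_true + 0.5·rural + 0.5·non-motorized + u_i)`,
`u_i ~ N(0, 0.5)`, with `a = −2` and `b = 2×10⁻⁴` per meter of ED — chosen
once so PA rises from ~12% next to a facility to ~73% at 15 km, with the
cluster-level random effect reproducing the large PA scatter seen at a
given accessibility value in real surveys. Motorized-household probability
is 0.45 (urban) / 0.15 (rural), i.e. about a quarter of respondents
overall. On the default landscape the realized overall mean PA is ≈50%,
near the top of the range national surveys report. Admin units are a
rectangular tiling (default 4×3), the simplest valid geometry for the
constrained-displacement path.

What the generator does **not** emulate: real road-network topology,
traffic or seasonal impassability, facility-database incompleteness,
survey sampling weights, or respondent-level covariates beyond
motorization. Passing tests therefore demonstrate the pipeline's
correctness and its qualitative behavior (method concordance, stratum
ordering, displacement attenuation), not quantitative agreement with any
country's survey.

## Numerical choices and degenerate inputs

Dijkstra edge weights are exact IEEE doubles; ties in accumulated cost are
irrelevant to the returned surface. Constant vectors give an undefined
(NaN) Spearman coefficient rather than a number; pairs with missing values
are removed pairwise and n < 3 is undefined. Zero-respondent clusters are
excluded with a warning. Zero displacement radii are allowed and reproduce
the baseline exactly. A 1×1 raster round-trips. Facility sets must be
non-empty for any surface computation.

## Known limitations

- Cost-distance is isotropic: no slope-dependent walking speed or
  time-of-day traffic.
- Displacement in meters only (projected grids).
- No reprojection; all layers must share a CRS.
- The pipeline's "all clusters" correlations on synthetic data are higher
  than field studies report, because the generator's single logistic driver
  has no unmodelled heterogeneity beyond the cluster random effect.
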