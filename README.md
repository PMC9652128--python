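# accessmap

Do sophisticated accessibility models actually track how people experience
their access to health care? `accessmap` is a toolkit for answering that
question the way spatial epidemiologists do: compute several *modelled
accessibility* (MA) surfaces to health facilities on a raster frame, build a
survey-derived *perceived accessibility* (PA) index per sampling cluster,
and compare the two with stratified rank correlations — including a
Monte-Carlo of the confidentiality displacement (geomasking) that public
survey programs such as the DHS apply to cluster coordinates.

It is aimed at public-health and GIS researchers who want a reproducible,
fully synthetic-testable implementation of this comparison rather than a
one-off script tied to restricted microdata.

## The measures

For a facility set and a raster template, four surfaces:

- **ED** — distance in meters from each cell center to the closest facility
  (planar or great-circle);
- **CD-M / CD-W** — travel time in minutes accumulated over a friction
  raster `f` (min/m, motorized or walking) by multi-source Dijkstra, with
  edge cost `d(a,b) · (f_a + f_b)/2` between adjacent cells;
- **KD** — facility kernel density `Σ_j exp(−d_j²/2σ²)` truncated to 0
  beyond 15 km (σ = 5 km by default); the only measure where larger means
  better access.

Per cluster, `PA = n_yes / n_respondents` (share reporting distance as an
obstacle to care). Association is Spearman's `r_s` — the PA–MA link is
monotone but nonlinear, and KD has the opposite sign — reported as |r_s|
with the sign in metadata, overall and stratified by urban/rural,
motorized/non-motorized respondents, and region. The displacement study
re-draws cluster positions R times (≤2 km urban, ≤5 km rural, 1% of rural
≤10 km, optionally constrained to the admin unit), re-extracts the MAs and
recomputes every coefficient.

## Worked example

Generate a synthetic 120 km × 120 km study (roads, barriers, town blobs,
population-weighted facilities and clusters with a logistic PA link) and
compare the methods:

```python
from accessmap.synth import (LandscapeConfig, ClusterGenConfig,
                             make_landscape, make_facilities, make_clusters)
from accessmap.surfaces import (euclidean_surface, cost_distance_surface,
                                kernel_density_surface)
from accessmap.survey import method_correlation_matrix, stratified_pa_ma

walk, motor, pop = make_landscape(LandscapeConfig(nrows=120, ncols=120, seed=7))
fac = make_facilities(pop, 40, seed=8)
surfaces = [euclidean_surface(pop, fac),
            cost_distance_surface(motor, fac),
            cost_distance_surface(walk, fac),
            kernel_density_surface(pop, fac)]
clusters, truth = make_clusters(ClusterGenConfig(n_clusters=400, seed=9),
                                {"ED": surfaces[0]}, pop)
mat, _ = method_correlation_matrix(clusters, surfaces)
print(mat.round(3))
```

```
         ED   CD_M   CD_W     KD
ED    1.000  0.807  0.996  0.967
CD_M  0.807  1.000  0.814  0.790
CD_W  0.996  0.814  1.000  0.965
KD    0.967  0.790  0.965  1.000
```

Walking cost-distance is nearly rank-identical to plain Euclidean distance
(|r_s| = 0.996): on this landscape the friction field adds almost no
ranking information, while the motorized surface (which depends on the road
network) diverges most. Stratifying the PA–MA correlations:

```python
from accessmap.survey import correlation_records_frame
recs = stratified_pa_ma(clusters, surfaces, strata=("all", "urban", "rural"))
print(correlation_records_frame(recs)
      .pivot_table(index="var_b", columns="stratum", values="r_s_abs").round(3))
```

```
stratum    all  rural  urban
var_b
CD_M     0.725  0.555  0.668
CD_W     0.876  0.863  0.736
ED       0.874  0.865  0.728
KD       0.862  0.843  0.674
```

Rural clusters sit on the steeper, noisier part of the generated logistic
link, and the values confirm that the cheap ED measure tracks perceived
access as well as any of the costlier methods here.

The same pipeline is scriptable from the shell:

```sh
access synth --out bundle --seed 2
access surface --method ed --template bundle/population.tif \
    --facilities bundle/facilities.csv --out ed.tif
access correlate --clusters bundle/clusters.csv --surfaces ED=ed.tif \
    --strata all,urban,rural --out corr.csv
access run --out study --seed 9        # the full study in one command
```

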