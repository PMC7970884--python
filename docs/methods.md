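# Methods

## The composite index

A lake's degradation pressure is modelled as the product of two terms.

**Watershed pressure** is a weighted sum over seven criteria. Each
criterion's raw metric is aggregated over the lake's hydrographic basin —
the set of raster cells whose surface flow path reaches the lake — and
banded into an integer score *n*:

| letter | raw metric (units)              | default bands → n 1..5          | weight p |
|--------|---------------------------------|---------------------------------|----------|
| W      | wastewater discharges (count)   | breakpoints 1, 2, 4, 6          | 0.25     |
| R      | recreational land (fraction)    | .05, .10, .20, .35              | 0.10     |
| A      | agricultural + irrigated (fraction) | .10, .25, .50, .75          | 0.20     |
| S      | basin area (km²)                | 5, 25, 100, 500                 | 0.05     |
| T      | roads + railways in basin (km)  | 1, 5, 15, 50                    | 0.10     |
| I      | industrial sites incl. mines/quarries/dumps (count) | 1, 2, 4, 7  | 0.20     |
| C      | vegetated ground cover (fraction) | .20, .40, .60, .80 → 5..1 (inverse) | 0.10 |

Bands are half-open `[lo, hi)` with a value exactly on a breakpoint going to
the upper band and the top band closed above. Cover is inverse-scored:
more vegetation means less pressure. The wastewater score is shifted by the
basin's least-treated discharge (untreated +1, secondary treatment −1,
clamped to 1..5), since untreated effluent is the stronger pressure. The
weights follow the published WRASTIC weighting and are fully overridable in
the config; the band tables are documented defaults that a user with
calibrated regional tables should replace.

**Terrain hazard** is the per-cell sum of three 1/3/5 classes, averaged
over the basin (median and mode are selectable):

* *Sn* — slope band from Horn's 3×3 gradient (defaults: < 2° → 1,
  2–8° → 3, ≥ 8° → 5);
* *En* — exposure relative to the shore: the angular difference Δ between a
  cell's downslope direction (center bearing of its cardinal aspect class)
  and the bearing to the nearest lake cell. Δ < 45° → 5 (drains toward the
  lake), Δ > 135° → 1 (drains away), otherwise 3; flat cells and lake cells
  are neutral. The band edges are symmetric so that flipping a cell's
  aspect by 180° exactly swaps 5 and 1 and fixes 3;
* *Pn* — permeability class looked up from soil-texture codes (defaults:
  fine → 1, medium → 3, coarse → 5; higher permeability transmits the
  pollutant load more readily).

The product of the two terms is the final index; it is monotone
non-decreasing in every criterion score and in the hazard. With scores 1–5,
weights summing to 1 and hazard in [3, 15], the index spans [3, 75].

## Classification

Fixed default breakpoints t1 = 20, t2 = 40 divide that range into
natural (≤ t1), semi-degraded (t1, t2] and degraded (> t2); the lower bands
are closed above. No published calibration of the thresholds exists (field
calibration on sample lakes informed the original three-class scheme), so a
cohort-tertile mode is provided as the data-driven alternative and the mode
used is recorded in the run metadata.

## Terrain and hydrology

Slope and aspect use Horn's kernel with edge-replicated borders; internal
nodata cells are filled from their nearest valid neighbour before
differencing and masked out afterwards. Aspect is reclassified into the
eight cardinal/intercardinal sectors (N covering 337.5°–22.5°, each other
sector 45°, sector edges going to the upper band) plus a flat class for
slopes below 0.01°.

Flow routing is single-direction D8: priority-flood pit filling with lake
cells acting as sinks (they keep their elevation, so basins terminate at
lakes rather than draining through them), steepest-descent direction with
drop-per-distance weighting (diagonals √2), ties broken by the fixed
neighbour order E, SE, S, SW, W, NW, N, NE, and plateaus resolved by
breadth-first distance to the nearest draining cell across equal
elevations. Cells with no lower neighbour on the grid edge are outlets. A
lake's basin is the set of cells whose arrow-following path reaches any
lake cell — tested cell-for-cell against a brute-force path-walking oracle.

## Water delimitation

NDWI = (green − NIR)/(green + NIR) is positive over open water. The pixel
spectra are clustered by seeded k-means (k-means++ initialization, 50
iterations, 10⁻⁶ relative tolerance — a reproducible stand-in for an
interactive iso-clustering + manual reclassification step); every cluster
whose mean NDWI exceeds a threshold (default 0.0) is retained as water.
4-connected components of at least 3 cells (speckle suppression) become
lake polygons. A Tasseled-Cap wetness band is available with
config-supplied coefficients; the shipped vector is a placeholder, as TC
coefficients are sensor-specific.

## The synthetic scene generator

A scene emulates the input stack of a national assessment at desk scale.
Elevation rises linearly (grade 0.05) with distance from the nearest lake
center beyond the lake radius (3 cells at 10 m), so each lake is a
flat-floored local minimum and catchments approximate the nearest-center
partition; correlated Gaussian noise (σ = 0.1 m, smoothing length 2 cells)
roughens the land surface. Each lake carries a scalar degradation driver
d ∈ [0, 1]; inside its basin the expected land-use fractions are 0.45·d
agricultural, 0.10·d irrigated, 0.05·d industrial, 0.10·d recreational,
remainder natural vegetation (per-cell multinomial assignment); industrial
sites and wastewater discharges are Poisson with means 5·d and 2·d; one
transect road crosses the basin with probability d; band reflectances are
fixed water/land signatures plus Gaussian noise (σ = 0.02). Soil texture is
a three-code mosaic of smoothed-noise terciles, independent of d. All draws
come from one seeded generator: identical spec + seed gives identical
scenes.

A single scalar driver makes ordering recovery well defined: on a cohort of
200 independent single-lake scenes (48×48 cells — small enough that the
full pipeline runs on the whole cohort in well under a minute) the rank
correlation between d and the computed index is the headline check. What
the generator does **not** emulate: spatially clustered land-use (a seeded
multinomial is spatially white within a basin), realistic pedology or
hydrography, atmospheric effects in the bands, or correlated pressures
(e.g. population) beyond the single driver. Passing tests therefore show
that the pipeline recovers a monotone pressure signal it is pointed at, not
that the default bands are calibrated for any real region.

## Numerical choices and degenerate inputs

* Grid alignment must be exact (shape, origin, cell size); there is no
  resampling. Rasterization uses the cell-center rule with a documented
  last-feature-wins overlap tie-break.
* Spearman's rho is Pearson on midranks (average ranks on ties, the SPSS
  convention); significance is two-tailed, by t approximation with n−2
  degrees of freedom, or by permutation (exact enumeration for n ≤ 8,
  Monte-Carlo with a stated resample count above). |rho| = 1 under the t
  approximation returns p = 0 by convention. Constant sequences have
  undefined rank correlation and return NaN with a warning.
* Empty zones return fraction 0 with a warning; empty basins, empty lake
  masks and unmapped category codes raise with the offending values named.
* The intermediate "sum slope and permeability, reclassify, then combine
  with exposure" variant of the hazard construction is subsumed by the
  additive (Sn + En + Pn) form, which is the fully specified contract; the
  reclass tables remain overridable if a user wants a different composition.

## Known limitations

Score bands, weights and class thresholds are literature-informed defaults,
not a regional calibration; results on real layers should be read as
relative rankings unless the tables are locally validated. D8 routing
cannot split flow between branches, so basin boundaries on near-flat divides
are discretization-sensitive. The exposure operationalization (bearing to
the nearest lake cell) is one reproducible reading of "orientation of the
shore"; concave shorelines can make single cells switch class under small
aspect changes.
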