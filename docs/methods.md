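# Methods

## The estimation problem

Given georeferenced presence points for many species and co-registered
rasters of six hydrological variables — mean annual precipitation
(MAP, mm), driest-month precipitation (P_dry, mm), precipitation
seasonality (P_seas, %), actual and potential evapotranspiration (AET,
PET, mm) and the aridity index (AI = MAP/PET, stored as the
scaled-integer AI × 10⁴ convention of the source layers) — the package
estimates, per species:

- **habitat position**: the mean of each indicator over the species'
  points (the five indicators are MAP, AI, AET/PET, P_dry, P_seas);
- **habitat range**: max − min of each indicator, a proxy for niche
  breadth;

and from these the multivariate climate spaces, within-group overlap
statistics, geographic range sizes and association tests described
below. This is deliberately a presence-summary approach, not species
distribution modelling: it makes no assumptions beyond the records
themselves, at the cost of sensitivity to sampling effort (which the
sensitivity screen quantifies rather than corrects).

## Record cleaning

Three removal rules run in a fixed order so report counts are
unambiguous: (1) within-species exact duplicates, where coordinates
are compared after rounding to 4 decimal places (~11 m) and the first
record by `record_id` sort is kept — this makes the whole stage
independent of input order; (2) records within
`institution_tolerance_deg` (default 0.001°, Euclidean in degrees; 0
means exact equality) of any listed herbarium / living-collection
coordinate; (3) records outside the species' axis-aligned native box
(boundary inclusive). Species retaining fewer than `min_points`
(default 3) records are excluded entirely. A species with no native
box skips rule (3) with a logged warning rather than failing, since
range judgements cannot be automated without one. The per-species
report satisfies `n_input = n_retained + Σ removals` by construction
and is re-validated at run time.

## Extraction conventions

Grids are north-up with the origin at the upper-left corner; cell
intervals are half-open, `col = floor((lon − origin_lon)/cell)` and
`row = floor((origin_lat − lat)/cell)`, so a point exactly on a cell's
western or northern edge belongs to that cell. AET/PET is computed per
point and then aggregated (the layers are co-registered, so the
per-point ratio is well defined); cells with PET = 0 are nodata for
the ratio. Points outside the grid or on nodata in any required layer
are dropped and counted.

The collinearity screen fits, per variable pair over species means,
ordinary linear and quadratic least squares and reports
`max(r²_linear, r²_quadratic)`, flagging pairs above 0.70. The
quadratic is used as the non-linear family because it is the simplest
curvature-capable fit; a zero-variance variable yields an undefined
(NaN) pair rather than an error.

## Climate spaces

Position space decomposes species means, range space species ranges.
Values are transformed `log10(x + 1)` — the offset accommodates exact
zeros (P_dry, or any range when all points fall in one cell) — then
centered and scaled to unit sample variance, i.e. PCA on the
correlation structure, because the five indicators have heterogeneous
units. The component count is `min(5, n_species)`; variance fractions
therefore always sum to 1. Component signs are fixed by making each
component's largest-magnitude loading positive; PCA signs are
otherwise arbitrary and this convention makes score tables
reproducible. Group diversity in a space is the convex-hull area of
the group's (PC1, PC2) scores, computed for groups with ≥3 species;
collinear score sets have area 0.

## Overlap statistic

For indicator v, species i occupies `[min_i, max_i]` and
`overlap(i, j) = max(0, min(max_i, max_j) − max(min_i, min_j))`. The
group summary takes the mean and SD over **off-diagonal unordered
pairs**: the diagonal holds each species' own range, a within-species
quantity that would dilute a between-species statistic (a
`include_diagonal` flag restores the full-matrix convention for
sensitivity checks). Normalized overlap is mean pairwise overlap
divided by the group's mean species range; with the off-diagonal-pairs
mean it is bounded by 1, because each pair's overlap is at most the
smaller of the two ranges. By default only AI and P_seas are
summarized — the other indicators are strongly collinear with these —
but any indicator is accepted. A bundled published reference table for
terrestrial bromeliad groups is used to verify that the normalization
arithmetic reproduces its printed column.

## Geographic range

Extent of occurrence is the convex hull of a species' points, computed
in geographic lon/lat coordinates (matching standard GIS practice),
with area evaluated on the WGS84 ellipsoid. Because no geodesic
library is part of the package's dependency set, the area computation
is self-contained: geodetic latitudes are mapped to authalic latitudes
(the exact equal-area mapping of the ellipsoid onto its authalic
sphere, via the q-function ratio), and the spherical polygon excess on
that sphere is accumulated with the signed van Oosterom–Strackee
solid-angle formula over a fan triangulation. For polygons with
straight-in-lon/lat edges of sub-continental size this agrees with a
rigorous geodesic computation far beyond the precision of any reported
range size; the test suite holds it to 0.5 % of an independent
l'Huilier spherical-excess oracle and to 2 % of planar small-polygon
scaling. Hulls spanning ≥180° of longitude (antimeridian wrap) are
rejected explicitly; no species cohort this package targets needs
them. Degenerate hulls (<3 unique or collinear points) have area 0 and
are flagged.

## Hypothesis batteries

All regressions are ordinary least squares with r² the squared Pearson
correlation and two-sided p from the slope t statistic; log transforms
are uniformly `log10(v + 1)`. Position-vs-range regressions are
untransformed; range-size regressions use `log10(area_km2 + 1)`;
richness-vs-hull-area regressions log both sides. The range-size ANOVA
across functional types runs on `log10(area + 1)` because extent
distributions are heavy-tailed. No multiplicity correction is applied;
the report flags this. The sensitivity screen is the Pearson
correlation of per-species point count with each estimated range
(undefined when either is constant).

## Synthetic data: what it emulates, and what it does not

The generator exists so that every downstream stage can be validated
against known truth. Each climate layer is built from a block latent
field plus per-variable noise: the two block latents (overall moisture
behind MAP/AET/PET — PET with negative sign, since high evaporative
demand marks dry places — and seasonality behind P_seas/P_dry, P_dry
negative) each mix a deterministic large-scale gradient (60 % of
variance; moisture east–west, seasonality north–south) with uniform
noise convolved with a Gaussian kernel (default smoothing length 6
cells). Because smoothing leaves few effective degrees of freedom, the
latents are orthogonalized in-sample before the cross-block
correlation (default −0.3: wetter places are less seasonal) is mixed
in, so the realized latent correlation equals the target exactly
rather than only in expectation. Each variable is affinely rescaled to
`[base − amplitude, base + amplitude]` and clamped; defaults bracket a
humid-to-arid Neotropical gradient (e.g. MAP 200–2800 mm, P_seas
15–105 %), with PET kept strictly positive so AI is defined
everywhere. AI is derived per cell as `round(10⁴·MAP/PET)`.

Species presences are sampled over cells with probability proportional
to a product of Gaussian kernels `exp(−(v − opt_v)²/(2σ_v²))` over the
variables of each niche spec (computed in log space and normalized
from the best cell, so narrow kernels keep mass; a species whose best
cell underflows raises an error naming it), then placed uniformly
within the sampled cell plus optional jitter. Per-species random
sub-streams are keyed by a CRC-32 hash of the species name, so output
is independent of species insertion order. Contaminant injection
appends, per species, exact duplicates (ids constructed to sort after
their originals, so duplicate resolution keeps the clean copy),
records at fixed institution coordinates, and records displaced ~30°
out of the native box, all truth-labelled.

What passing these tests shows is that the pipeline's arithmetic,
conventions and statistical machinery behave as documented under the
data-generating assumptions stated above. What it does not show:
real occurrence data have spatially biased sampling effort, positional
error correlated with geography, taxonomic misidentification, and
climate layers with topographic structure far rougher than smoothed
noise — none of which the generator emulates. Parameter-recovery
results (e.g. Spearman ρ ≈ 0.9 between true breadth and estimated
range at 100 points/species) are therefore upper bounds on what real
data would support.

## Validation study designs and problem sizes

The canned studies in `hydroniche.studies` fix the conditions used by
the test suite and `scripts/acceptance.py`: a 120 × 100-cell landscape
at 0.05°; breadth recovery with 50 species × 100 points and true
breadths geometrically spanning 0.05–0.5 of the landscape's MAP value
range (a 10× span), optima drawn over the central 10th–90th percentile
band; the breadth-driven cohort with 40 species × 80 points sharing
one breadth scale across both climate blocks, so climatic tolerance
drives spatial spread; the fixed-extent negative control with 20
species × 40 points uniform in identical 1° boxes at random locations,
100 replicates; the two-block PCA check with 500 species and 0.9
factor loadings (population PC1+PC2 share ≈ 88.6 %); cleaning
validation on 12 species × 40 points with 2 duplicates, 1 institution
record and 2 out-of-range records per species; and ANOVA calibration
over 1000 null replicates of two n = 20 groups. These sizes give each
stochastic check comfortable margins while keeping the whole
validation run within seconds.

## Numerical choices and degenerate inputs

- Constant-response regressions return a defined null fit (slope 0,
  r² 0, p 1); constant-predictor regressions are reported missing.
- Zero-variance variables abort PCA with the variable named; constancy
  is detected on the raw transformed values (`ptp == 0`), not on a
  floating-point standard deviation.
- A group mean species range of 0 makes normalized overlap undefined
  (NaN), reported as missing rather than raised.
- ASCII grids are written with 17 significant digits so stacks
  round-trip bit-exactly; identical spec + seed reproduces identical
  rasters, occurrence tables and pipeline outputs byte for byte.
- The pipeline halts multivariate stages (with a manifest entry) when
  fewer than 3 species survive cleaning and summarization.

## Known limitations

- Native ranges are axis-aligned boxes; a species whose true range
  hugs a coastline or mountain arc may need a polygon refinement the
  cleaning stage does not implement.
- The geodesic area treats hull edges as straight in lon/lat (as GIS
  convex-hull tools do), not as geodesics; for continental-scale hulls
  the difference is real but small relative to the spread of EOO
  estimates.
- The overlap statistic is univariate by design; it does not measure
  joint (multivariate) niche overlap.
- Sampling-effort bias is measured, not corrected: the sensitivity
  screen reports the correlation between point count and estimated
  range, and users should treat strongly positive values as a warning
  that apparent breadth differences may reflect record availability.
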