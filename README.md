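# hydroniche

Hydrological habitat occupancy analysis for terrestrial plants, from
georeferenced occurrence records and bioclimatic rasters.

The package was built around the kind of question asked of large
aggregated point datasets (e.g. GBIF exports) for radiations such as
the terrestrial bromeliads: where does each species sit along the
water-availability axes of climate, how broad is its tolerance, and how
do those properties relate to geography and diversity? It provides a
tested, reproducible pipeline for:

- **record cleaning** — duplicate removal, herbarium/living-collection
  coordinate removal, out-of-native-range removal, and a ≥3-point
  retention rule, with a per-species conservation-checked report;
- **extraction and summaries** — sampling six co-registered layers
  (MAP, P_dry, P_seas, AET, PET, AI) at each point; per species and
  indicator *v*, habitat **position** `mean(v)` and habitat **range**
  `max(v) − min(v)`, plus a linear/quadratic collinearity screen;
- **climate spaces** — PCA of `log10(x + 1)`-transformed, standardized
  species means (position space) or ranges (range space), and
  convex-hull areas of group scores in PC1–PC2 as a diversity measure;
- **habitat overlap** — within-group pairwise interval overlap
  `max(0, min(max_i, max_j) − max(min_i, min_j))`, summarized as the
  off-diagonal mean/SD and normalized by the group mean species range
  to a dimensionless value in [0, 1];
- **geographic range** — extent of occurrence as the WGS84 ellipsoidal
  area (km²) of the convex hull of presence points;
- **hypothesis batteries** — position-vs-range regressions, log
  range-size vs. habitat-range regressions, richness vs. climate-space
  diversity across genera, a range-size ANOVA across functional types,
  and a sample-size sensitivity screen;
- **synthetic data** — seeded, spatially autocorrelated climate
  landscapes with a two-block (moisture vs. seasonality) correlation
  structure, Gaussian-kernel niche sampling with known truth, and
  labelled contaminant injection, so every stage is testable offline.

Rasters are read and written as ESRI ASCII grids (one plain-text file
per layer); occurrences and all outputs are CSV.

## Worked example

`examples/` contains one short script per capability. For instance,
the overlap statistic (`python examples/05_overlap_statistics.py`):

```
pairwise AI overlap matrix (diagonal = own range):
        wet_sp  mid_sp  dry_sp
wet_sp  6000.0  2000.0     0.0
mid_sp  2000.0  6000.0  1000.0
dry_sp     0.0  1000.0  5000.0

mean pairwise overlap 1000, mean species range 5667 -> normalized overlap 0.176
```

Three species with staggered aridity-index intervals overlap pairwise
by 2000, 1000 and 0 AI units; the mean pairwise overlap (1000) divided
by the mean species range (5667) gives a normalized overlap of 0.176 —
these species share about 18 % of a typical member's aridity interval.
The same script recomputes the printed normalization column of the
bundled published bromeliad overlap table and reports that all 16 rows
agree at 3 decimals.

The range-size example (`python examples/06_georange_and_hypotheses.py`)
builds a synthetic cohort in which niche breadth drives spatial spread
and prints the five OLS fits of `log10(area_km2 + 1)` on each
indicator's habitat range, all with positive slopes at p < 10⁻⁵ —
the qualitative signature expected when climatic tolerance limits
geographic extent.

A full run over files on disk goes through the CLI:

```sh
hydroniche simulate --config sim.yaml --out study --seed 3
hydroniche run --config pipeline.yaml        # clean -> extract -> pca -> overlap -> georange -> report
```

The `run` command writes every intermediate table plus a
`manifest.json` (parameters, input checksums, per-stage counts);
rerunning an identical config reproduces the outputs byte for byte.

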