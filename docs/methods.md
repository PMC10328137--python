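# Methods

This note documents the models, conventions and numerical choices behind
`nicheshift`, and what the synthetic validation does and does not establish.

## Observation model and synthetic data

The generator emulates community-science checklist data for two decades
("historic" 1970–1979, "current" 2010–2019) on a single equal-area grid:

- **Landscape.** Spatially autocorrelated random fields (white noise smoothed
  with a Gaussian kernel of configurable length, default 8 km) drive monthly
  minimum/maximum temperature (with a seasonal cycle and a south–north
  gradient), monthly precipitation (log-normal around a seasonal cycle),
  elevation, and five fractional land-cover classes (urban, forest,
  grassland, wetland, cropland; a softmax of per-class fields, summing to 1
  per cell). The coastline is the southern grid edge; fresh water is a set of
  seeded random polylines; distance layers are planar distances in km.
  Between periods, a configurable temperature delta (default +1 °C) is added
  to every monthly layer and a configurable fraction of cells (default 5%)
  swaps its dominant land-cover class. Precipitation, elevation and water are
  held fixed.
- **True niche.** Suitability is logistic in linear + quadratic predictor
  terms. The canned scenarios use a unimodal (Gaussian-bell) response to
  BIO5 (maximum temperature of the warmest month): height 2.0 (peak
  suitability ≈ 0.88) and width 0.8 SD of the landscape's BIO5 distribution,
  so the study region contains both clearly suitable and clearly unsuitable
  habitat, as a regional study extent would. A *stable* scenario uses the
  same response in both periods; a *shift* scenario moves the optimum
  (default 2 pooled SD). Shift scenarios use a unimodal response because a
  purely monotone response translated along its predictor changes only the
  intercept, not the occupied environments.
- **Effort.** Detection probability multiplies suitability by
  (1 − e^(−λd)) · bell(t): duration saturation λ = 3 h⁻¹ (one hour yields
  ≈ 95% of asymptotic detectability) and a Gaussian time-of-day factor
  peaking at 06:00 with width 6 h. Durations are exponential (mean 1.5 h,
  capped at 8 h), distances exponential (mean 2 km, capped at 12 km), party
  sizes geometric (capped at 12), start times uniform over 04:00–20:00 —
  deliberately wide so the quality filters and effort covariates both have
  work to do. Site selection is biased by exp(w·z) over a smooth random
  field (w = 1 by default), emulating uneven observer coverage; an optional
  sampling window confines effort to the interior of the grid so that a
  node buffer fits around the occupied range.

What the generator does *not* emulate: observer heterogeneity and learning,
taxonomic misidentification, spatial error in locations, protocol diversity,
temporal autocorrelation of visits, and real geographic projections. Passing
the validation experiments therefore shows the machinery is correct and well
calibrated under the stated generative model, not that any particular field
dataset satisfies that model.

## Checklist preparation

- Bounds are strict as worded: duration < 5 h, distance < 5 km, observers
  < 10. Presences outside an optional range polygon are dropped; optionally
  only checklists within a buffer (default 600 km) of a surviving presence
  are kept.
- Hexagonal thinning: flat-topped hexagons whose **short diagonal (width
  across flats) is 2.5 km** (circumradius 2.5/√3 km), anchored at the
  coordinate origin; the convention is configurable via `hex_size_km`
  because "2.5 km hexagonal grid" admits edge/width/spacing readings.
  Week = ISO-8601 week. Within each hexagon-week stratum one presence and
  one absence survive, drawn uniformly with a seeded RNG after sorting by
  checklist id, so the draw is independent of input row order.
- The 80/20 split is stratified by detection with largest-remainder
  allocation, guaranteeing both partitions contain both classes. In the
  pipeline the split is drawn **before** per-replicate thinning, so held-out
  rows never enter any replicate's training data; replicate stochasticity
  then comes from re-drawn thinning and balanced bootstraps.

## Environmental predictors

- BIO1–BIO19 follow the standard definitions; quarters are 3 consecutive
  calendar months with December–January wraparound, ties going to the
  earliest start month. BIO4 is 100 × the sample SD of monthly means. BIO15
  is the coefficient of variation of monthly precipitation **+ 1** (sample
  SD), matching the widely used `biovars` convention; a constant climate
  still yields exactly 0. All layer math propagates NaN.
- Collinearity pruning: while any retained pair has |Pearson r| > 0.7, the
  member of the worst pair with the larger variance inflation factor
  (regressing on all other retained predictors) is dropped; perfect
  collinearity is treated as infinite VIF. The retained set is data-driven,
  never hard-coded. In the pipeline the niche driver is re-added if pruning
  removed it in favour of a correlated proxy, since importance and partial
  dependence are reported for it.

## SDM ensemble

- Balanced random forest: per tree, n_presence draws with replacement from
  each class; trees are CART with Gini splits, `sqrt(p)` features per split,
  minimum leaf size 1 (conventional defaults — the method prescribes none);
  500 trees per replicate by default, 10 replicates. Score = vote fraction.
- Map predictions fix effort at day-of-year 91 (April 1), start hour 5 or 6
  (species presets), 1 h, 1 km, one observer. Provenance is contemporary /
  forecast / backcast according to whether the model's period matches the
  environment's.
- Importance: Gini impurity decreases summed over splits and trees within a
  replicate, normalized to percent, averaged across replicates. Partial
  dependence: 25 evenly spaced values spanning the predictor's observed
  training range, averaged over 1000 reference checklists drawn once per
  curve (shared across replicates — the replicate-wise SD then isolates
  model stochasticity); the marginal effect subtracts the curve minimum.

## Evaluation

- AUC is the Mann–Whitney probability (ties half). κ is computed at the
  model's own max-SSS threshold for both own- and opposite-period test sets,
  consistent with how the maps are binarized; whether the opposite-period κ
  should re-optimize its threshold is undetermined in the method's source,
  and the own-threshold choice is documented rather than inferred.
- Max-SSS candidates are the observed score values with classification
  score ≥ τ; ties break toward the smallest τ. Range-change maps use the
  same ≥ convention; areas are cell counts times the cell area of the
  declared equal-area grid.

## Niche overlap

- PCA is fit once on the pooled, z-scored occurrence predictors of both
  periods (units are incommensurable); the first two components define the
  space; occupancy grids are **raw binned frequencies**, not kernel
  densities — the frequency wording of the procedure is followed literally,
  and a Gaussian-kernel option (`smooth_sigma_bins`) exists but is off by
  default. This is a documented divergence risk against tools whose default
  smooths and background-corrects the density.
- Analog mask: a grid cell survives if its PC1 and PC2 midpoints fall within
  the observed score range of *each* period separately (range-box
  criterion); densities are renormalized after masking.
- The permutation null reassigns pooled occurrences to two groups of the
  original sizes; the pooled rows are put in a canonical (lexicographic)
  order first, so the null sample is invariant to input row order. The
  p-value uses the add-one convention, p = (1 + #{I_sim ≤ I_obs})/(n_sim+1),
  so p > 0 always; n_sim defaults to 100.
- Calibration note: with a stable niche **and zero environmental change**
  the two periods' occurrence distributions are identical and the test is
  exactly calibrated (verified on 200 replicate datasets). When the
  environment changes but the niche response does not — the pipeline's
  default stable scenario — the occupied environmental space can still move
  (the same response played out over a different landscape), and the test
  may legitimately reject; the test detects occupancy change, not response
  change. Forecast ΔAUC is the complementary signal that isolates response
  change.

## Connectivity

- R(s) = 100 − 99·(1 − e^(−cs))/(1 − e^(−c)) with c = 8 (strong
  literature-standard nonlinearity, configurable); endpoints R(0)=100,
  R(1)=1 are exact by construction.
- Raster network: 8-neighbour connectivity, edge conductance = mean of the
  two cell conductances, diagonals scaled by 1/√2; 4-neighbour available.
- Node pairs: 18 nodes (default) drawn uniformly by arc length along the
  perimeter of a buffer offset from the convex hull of the detections
  (600 km at continental scale; desk-scale runs use a few km via config so
  the ring fits the raster). Per-cell current is half the sum of absolute
  incident edge currents (source/sink cells set to 1 exactly); pairwise maps
  are summed unnormalized.
- The Laplacian systems are solved by **sparse direct LU**: one
  factorization of the grounded Laplacian (reference = first node) is reused
  for all C(n,2) right-hand sides. A direct solve is deterministic, exact to
  machine precision (subsuming the 1e-8 tolerance an iterative scheme would
  need), and cheaper when the factorization is amortized over many pairs.
  Correctness is verified against dense pseudoinverse solves and Kirchhoff
  balance on random grids.
- "Within the 75th percentile" is read as ≥ the 75th percentile (top
  quartile), computed per map over the range mask only, excluding the buffer
  area where currents are node-placement artefacts.

## Validation problem sizes

The replicated experiments in the test suite and the acceptance script use
desk-scale sizes chosen as the package's own validation conditions: 50×50 or
60×60 km landscapes at 1 km resolution; 3000–7000 checklists per period
(≥ 2000 surviving thinning); 200 replicate datasets of 500 occurrences per
period with 99 permutations each for null calibration and power; 10
replicate SDM fits for the transferability checks (3 forest replicates ×
150 trees each inside every fit); 10 replicates × 150 trees for the
single-run recovery experiment. The circuit oracle covers 20 random grids up
to 12×12 against dense solves.

## Known limitations

- The balanced forest's vote-fraction score is discrete (resolution
  1/(replicates × trees)); thresholds and κ inherit that granularity.
- Warren's *I* on raw 100×100-binned frequencies is depressed by sampling
  sparseness at realistic occurrence counts; observed values are comparable
  against their own permutation null, not across datasets of different size.
- The occupancy density is occurrence-only, with no availability/background
  correction; whether the original procedure corrected for availability is
  left open, and no correction is applied here.
- Connectivity change compares two current maps that share node placement;
  conclusions are conditional on the node draw, as in the underlying method.
- The synthetic effort model's parameters are free inventions (the source
  describes no generative observation process); they are fixed defaults, not
  estimates.
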