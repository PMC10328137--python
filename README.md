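# nicheshift

Temporal niche-shift inference from effort-annotated survey checklists.

Range expansions pose a recurring question for spatial ecologists: did the
species spread because newly suitable habitat appeared (environmental change
under a fixed niche), or because the species changed which environments it
occupies (a shift of the realized niche)? `nicheshift` implements a complete,
testable pipeline that separates these hypotheses from two decades of
detection/non-detection checklist data, of the kind produced by community
science platforms where complete checklists let non-detections stand in for
absences.

The pipeline builds a species distribution model (SDM) per time period and
asks three questions about change between the periods:

1. **Habitat availability** — contemporary, forecast and backcast suitability
   maps, their discrimination (AUC, Cohen's κ), temporal transferability
   (ΔAUC, Δκ = opposite-period − own-period performance), and four-way
   range-change maps after binarizing at the max-SSS threshold.
2. **Habitat associations** — per-predictor Gini importance, partial
   dependence / marginal-effect curves, land-cover occupancy, and a
   permutation test of niche similarity in a PCA environmental space using
   Warren's *I*.
3. **Habitat connectivity** — circuit-theory current maps over a
   negative-exponential resistance transform of suitability, with a
   75th-percentile high/low connectivity change classification.

A first-class synthetic-data module generates two-period landscapes with a
*known* true niche — stable or shifted by a stated amount — and effort-biased
checklists, so every stage of the pipeline can be validated against ground
truth without downloading anything.

## The model

Each checklist *i* records location, date, start time *t*, duration *d*,
distance, party size, and a detection flag *y*. The generative model used for
validation is

> y_i ~ Bernoulli( s(x_i) · (1 − e^(−λd_i)) · exp(−½((t_i − t₀)/w)²) )

where s(x) = logistic(β₀ + Σ β₁ⱼ xⱼ + Σ β₂ⱼ xⱼ²) is the true suitability of
the cell's environment x (bioclim variables BIO1–BIO19 derived from monthly
climate, fractional land cover, elevation, distance to fresh water and to the
coast), and the remaining factors are observation effort.

The SDM is a **balanced random forest**: every tree's bootstrap draws
presences and absences in equal number, so the extreme class imbalance of
checklist data cannot swamp the vote; the suitability score is the fraction
of trees voting presence, averaged over 10 independently trained replicates.
Before training, checklists are quality-filtered (duration < 5 h, distance
< 5 km, fewer than 10 observers), thinned to one presence and one absence per
2.5 km hexagon per ISO week, and split 80/20 stratified by outcome. Maps are
predicted at standardized effort (April 1, 1 h, 1 km, one observer).

Niche overlap between periods is Warren's
*I* = 1 − ½ Σ (√p₁ − √p₂)² over 100×100-binned occurrence densities in the
pooled two-component PCA space, compared with a null from randomly
reassigning occurrences to periods. Connectivity converts suitability to
resistance R(s) = 100 − 99·(1 − e^(−cs))/(1 − e^(−c)) and solves the raster
Laplacian for unit currents between all pairs of random nodes on a buffer
around the species range.

## Worked example

Run the full pipeline on a synthetic scenario whose niche optimum moves by
2 SD between periods:

```python
from nicheshift import run_pipeline

report = run_pipeline({
    "seed": 42,
    "scenario": {"kind": "shift", "n_checklists": 3000,
                 "landscape": {"grid_rows": 50, "grid_cols": 50}},
    "sdm": {"n_replicates": 5, "trees_per_replicate": 150},
})

m = report["metrics"]["historic"]
print(f"historic model: AUC own={m['auc_own']:.3f}, "
      f"forecast AUC={m['auc_opposite']:.3f}, dAUC={m['delta_auc']:+.3f}")
ov = report["overlap"]
print(f"niche overlap: Warren's I={ov['observed_I']:.3f} "
      f"(null mean {ov['null_I_mean']:.3f}), p={ov['p_value']:.4f}")
```

prints

```
historic model: AUC own=0.828, forecast AUC=0.393, dAUC=-0.435
niche overlap: Warren's I=0.045 (null mean 0.534), p=0.0099
```

Both change signals fire, exactly as they should for a shifted niche: the
historic model discriminates well in its own period (AUC 0.83) but collapses
when forecast onto the changed niche (ΔAUC −0.44), and the observed niche
overlap lies far below the permutation null (p ≈ 0.01). Under the stable
scenario (`"kind": "stable"`), ΔAUC stays near zero instead. The report also
carries suitable-area and range-change tallies, importance tables, partial
dependence, land-cover occupancy, and connectivity change counts.

The same workflow is scriptable from the shell:

```bash
nicheshift run -c config.yaml -o runs/demo --seed 42
nicheshift simulate|prepare|train|predict|evaluate|overlap|connect ...
```

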