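# vespasam

Species **abundance** modelling — not just occurrence modelling — for the
invasive yellow-legged hornet *Vespa velutina nigrithorax*, with risk
mapping for human health and honeybee losses.

Occurrence-based species distribution models (SDMs) answer "can the
species establish here?"; once an invader occupies an entire territory,
managers need "how many are here?" instead. `vespasam` implements a
species abundance model (SAM) workflow for trap-survey data and the
head-to-head comparison that motivates it: tree-ensemble regressions of
mean trap catch `x` (and `log(x+1)`) on bioclimatic and foraging-buffer
land-composition covariates, evaluated against occurrence models over
replicated stratified splits, followed by hazard x sensitivity risk
indices aggregated to administrative units. Because the underlying field
data are not public, the package ships a seeded synthetic-landscape
generator that reproduces the survey's statistical structure (skewed
negative-binomial catches, category composition, report-abundance
coupling), so the whole pipeline is testable end to end.

It is aimed at quantitative ecologists and invasion biologists who want a
reproducible, scriptable version of this workflow — or a testbed for
abundance-vs-occurrence methodology.

## The core quantities

- Abundance categories on the multi-year mean catch:
  Absence `x = 0`, Low `0 < x < 10`, Mid `10 <= x < 100`, High `x >= 100`.
- Buffer covariates: area (km^2) of each land-cover class within the 1 km
  worker foraging radius of a site.
- Model variants: {RF, GBM} x {raw, log1p} for abundance (RF with 1000
  trees, otherwise reference defaults); {RF, GBM} on presence/absence for
  occurrence.
- Evaluation: accuracy = MAE / mean(obs) (ideal 0); discrimination =
  Pearson r and calibration slope (ideal 1); AUC for occurrence variants.
  Best SAM by summed metric ranks, best SDM by mean AUC.
- Category discrimination: Kruskal-Wallis + Dunn (Bonferroni) compact
  letter display on final-model predictions.
- Correlation validation: `t = r sqrt(df) / sqrt(1 - r^2)`, df = n - 2.
- Risk: unit mean of `log(x̂+1)` (hazard) x population or colony count
  (sensitivity), classed into five quantile levels.

## Worked example

```python
from vespasam import pipeline

res = pipeline.run_pipeline(seed=0, n_rep=20)
print(res["summary"][["variant", "accuracy_mean", "pearson_r_mean",
                      "slope_mean", "auc_mean", "selected"]].round(3).to_string(index=False))
print("letters (SAM):", res["dunn_sam"]["letters"])
print("letters (SDM):", res["dunn_sdm"]["letters"])
print("reports r, t:", round(res["validation"]["reports"].r, 3),
      round(res["validation"]["reports"].t, 2))
```

prints (seed 0):

```
  variant  accuracy_mean  pearson_r_mean  slope_mean  auc_mean  selected
   rf_raw          0.781           0.694       1.523       NaN     False
 rf_log1p          0.742           0.639       3.047       NaN     False
  gbm_raw          0.937           0.620       1.064       NaN     False
gbm_log1p          0.707           0.640       2.084       NaN      True
   sdm_rf         28.100           0.197       0.044     0.746      True
  sdm_gbm         28.018           0.215       0.043     0.715     False
letters (SAM): {'Absence': 'a', 'Low': 'a', 'Mid': 'b', 'High': 'c'}
letters (SDM): {'Absence': 'a', 'Low': 'b', 'Mid': 'c', 'High': 'c'}
reports r, t: 0.398 5.4
```

Reading this: the abundance variants' scaled error sits far below the
occurrence variants' (whose probabilities are compared against max-scaled
abundance, hence the large accuracy values), and their Pearson r is much
higher — the abundance model is the better abundance predictor. The final
abundance model separates the Low, Mid and High abundance levels
(distinct Dunn letters a/b/c; its near-zero predictions at absence and
low sites overlap), while the occurrence model's establishment
probability saturates within the occupied area and cannot tell Mid from
High (shared letter c). Unit-level mean log-abundance correlates
positively with nest-removal reports per capita (r = 0.40, t = 5.4),
validating the hazard term of the risk indices.

The same pipeline is available from the shell:

```sh
vespasam run --seed 1 --n-rep 100 --out-dir out/
vespasam simulate --seed 1 --out-dir sim/          # rasters + tables only
vespasam evaluate --covariates out/covariates.csv --out-prefix out/eval
```

All outputs are plain text (CSV, GeoJSON, ESRI ASCII grids) and are
byte-identical across reruns with the same seed.

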