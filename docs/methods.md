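# Methods

`vespasam` re-creates, on fully synthetic data, an abundance-modelling
workflow for the invasive yellow-legged hornet *Vespa velutina nigrithorax*:
trap-survey counts are modelled from bioclimatic and land-composition
covariates with tree ensembles, the abundance models (SAMs) are compared
against occurrence models (SDMs), and the selected model's predictions feed
hazard x sensitivity risk indices at the administrative-unit level. This
note documents the models, the generator that stands in for the
(non-public) field data, the numerical choices, and what the synthetic
results do and do not establish.

## The modelling problem

The response at site *i* is the multi-year mean trap catch `x_i >= 0`
(1-4 yearly counts per site, averaged). Sites are classed as
Absence (`x = 0`), Low (`0 < x < 10`), Mid (`10 <= x < 100`) and High
(`x >= 100`); the integer field labels (1-9, 10-99) are generalized to
half-open intervals so fractional multi-year means always classify.

Covariates are six bioclimatic layers on a 1-km grid (Bio1, Bio3, Bio12,
Bio13, Bio14, Bio15, in native units) and seven land-composition areas:
the km^2 of each land-cover class within a 1 km radius — the worker
foraging range — around the site, computed on a fine (25 m) class raster.
A fine cell belongs to the buffer iff its centre is within the radius; the
class area is the cell count times the cell area. Buffers truncated by the
study-area edge use covered cells only and are flagged. Before fitting,
pairwise Pearson correlations among covariates (computed on site rows, the
rows models are fitted on) are filtered: variables are visited in a
priority order (by convention, frequency of use in earlier studies; here
the column order) and kept iff |r| <= 0.8 against everything already kept.
The greedy-by-priority rule makes the procedure deterministic and
idempotent; constant columns are treated as uncorrelated with a warning.

Four abundance variants are fitted — {random forest, gradient boosting} x
{raw count, log(x+1) response} — and two occurrence variants on the
binarized response (presence iff `x > 0`). Hyperparameters mirror the
reference R implementations' defaults: random forest with 1000 trees,
node size 5 and p/3 features per split for regression (node size 1,
sqrt(p) features for classification); gradient boosting with 100 trees,
depth 1, learning rate 0.1, bag fraction 0.5. log1p-variant predictions
are back-transformed with expm1; predictions on the count scale are then
clipped at 0 in both variants, because boosting can overshoot below zero
on either scale. Evaluation of
the log1p variant happens on the back-transformed (count) scale by
default; scoring on the fitting (log) scale is available via the
`sam_eval_scale="transformed"` option of the replicated evaluation, and
raw model-scale predictions via `AbundanceRegressor.predict_transformed`.

## Evaluation and selection

Each of `n_rep` replicates draws an independent category-stratified
70/30 split. Metrics on the test half:

- accuracy = mean(|pred - obs|) / mean(obs), ideal 0 (scale-invariant);
- discrimination = Pearson r between prediction and observation, plus the
  calibration slope (observation regressed on prediction; ideal 1). The
  calibration sense is the default because its ideal value of 1 matches
  the framework the workflow follows; the reverse regression is available
  via a flag.
- occurrence variants additionally get AUC (Mann-Whitney formulation,
  tie-aware), and their abundance metrics compare the establishment
  probability against observed abundance divided by its maximum over the
  dataset ("relative abundance"); accuracy then scales by the mean of the
  scaled observations.

The best abundance variant minimizes the sum of per-metric ranks
(accuracy ascending, r descending, |slope - 1| ascending; ties broken by
accuracy rank then listed order). The best occurrence variant maximizes
mean AUC. Final models are refitted on all sites without splitting; their
site predictions, grouped by observed category, are compared with a
tie-corrected Kruskal-Wallis test followed by Dunn z tests (tie-corrected
pooled variance) with Bonferroni correction over the 6 pairs, summarized
as a compact letter display (greedy insert-and-absorb; groups sharing a
letter are not significantly different at adjusted p < 0.05).

Correlation validation uses the exact identity `t = r sqrt(df) / sqrt(1 -
r^2)` with `df = n - 2`, two-sided p from the t distribution.

## Risk indices

Final abundance predictions are transformed to log(x+1) and averaged over
the coarse cells whose centres fall in each administrative polygon
(cell-centre containment, consistent with the buffer rule). Nest-removal
report counts are standardized to reports per capita. Risk is hazard x
sensitivity: the unit's mean log-abundance times residential population
(human-health index) or honeybee-colony count (honeybee-loss index).
Using the log-scale mean as the hazard matches the mapping scale of the
aggregation step; back-transformed means are a config alternative. Each
index is classed into five quantile levels (breaks at the 20/40/60/80th
percentiles — quantiles guarantee populated classes; the break method is
otherwise a free choice); with fewer distinct values than classes the
classing coarsens with a warning.

## The synthetic-landscape generator

No public accession exists for the field data, so the generator emulates
its statistical structure; its defaults are the package's study
conditions and are chosen once, as follows.

- **Geometry.** 40 x 40 km extent, 1 km climate grid, 25 m land-cover
  grid (the coarse cell must be an integer multiple of the fine cell, so
  25 m stands in for the 30 m-class native resolution). A landscape this
  size keeps a full study generable in seconds; the ratio of domain size
  to climate correlation length (5 km) is what matters for covariate
  variety, and is kept comparable to a country-scale domain with
  mesoscale climate gradients.
- **Climate.** Gaussian-smoothed white noise rescaled min-max into each
  variable's national range (e.g. annual mean temperature 2.75-17.41 C),
  so every layer attains its documented extremes. Annual and
  wettest-month precipitation share a latent field (mixing 0.55) to give
  realistic, sub-threshold correlation among covariates.
- **Land cover.** Seven classes by argmax over spatially correlated
  (1.5 km patch scale) unit-variance Gaussian scores with per-class mean
  offsets Monte-Carlo-calibrated so class prevalences approximate a
  forest-dominated national mix (forest 69 %, agriculture 19 %, urban
  5 %, ...). Scores are drawn at 200 m blocks and bilinearly upsampled.
- **Abundance process.** log mu = log(20) + 1.25 x summed effect terms,
  each term acting on the covariate rescaled to [0, 1] over its range:
  temperature rising with a high-end dip, precipitation-seasonality and
  wettest-month effects negative, forest monotone positive, grassland /
  agriculture / urban with negative hinge thresholds, barren / water /
  wetland inert. Yearly counts at occupied sites are negative binomial
  (size k = 2.0), giving the strongly right-skewed catches such traps
  produce (variance mu + mu^2/k > mu).
- **Occupancy envelope.** Presence probability is a sharp logistic in
  log mu (midpoint mu = 2.4, scale 0.2) capped at 0.9: poor habitat
  yields true absences, while even prime habitat retains a 10 %
  unexplained absence rate (failed colonisation, competition,
  disturbance). The cap is what makes the occurrence signal saturate
  within the occupied envelope — the empirical situation the
  SAM-vs-SDM comparison probes — while the abundance gradient across
  that envelope stays strong.
- **Survey.** 248 sites at distinct coarse cells, 1-4 survey years
  each (uniform; the field protocol reports only per-year totals, so the
  per-site year distribution is a free choice). These defaults reproduce
  the surveyed category composition 61/50/110/27 of 248 to within a few
  percentage points on average and a maximum mean catch of a few hundred.
- **Administrative units.** 159 Voronoi cells of uniform random seeds
  clipped to the extent (mirror construction, so polygons tile the extent
  exactly); populations and colony counts lognormal; report counts
  Poisson with expectation proportional to unit mean abundance x
  population (1e-5 per capita at unit abundance 1) with lognormal
  heterogeneity (sd 0.5), injecting the positive abundance-reports
  coupling the validation step should detect; an apiary appearance rate
  (percent) increases with log unit abundance plus noise. The real
  apiary questionnaire is province-level; the synthetic pipeline keeps
  one spatial resolution and accepts that mismatch.

What the generator does *not* emulate: real geography and coastlines,
island-exclusion curation, spatial sampling bias of trap placement,
inter-annual climate variation, species interactions, and the real
land-cover class geometry (patches are smooth blobs). Passing tests
therefore show that the workflow recovers the right patterns when its
assumptions hold, not that the published coefficients or maps are
reproduced.

## Numerical choices and determinism

Every stochastic step derives from `numpy.random.default_rng` seeded by
(config seed, stage constant), so one master seed reproduces all outputs
byte-for-byte, including CSV/GeoJSON files. Stratified splitting
delegates to scikit-learn with a per-replicate seed; per-category train
counts are within +-1 of 0.7 n_c. Degenerate inputs fail loudly: a
category with fewer than 2 sites (cannot stratify), single-class
occurrence training sets, constant inputs to correlation, zero mean
observation in the scaled MAE. Zero-population units and units without
cell centres become missing values with warnings, excluded from
correlations. |r| = 1 reports t = +-inf with p = 0.

## Problem sizes used in the checked runs

Replicated evaluations in the acceptance checks use 20 replicates over 20
landscape seeds at the survey scale (248 sites), and the acceptance script
defaults to 20 replicates; the study-scale default in the CLI remains 100
replicates. Pattern-recovery checks count seeds in which the expected
ordering holds (abundance model beating occurrence variants on accuracy
and Pearson r; all-distinct abundance letters with saturated occurrence
letters), mirroring how a scaled-down re-analysis would be judged.

## Known limitations

- Impurity-based (node-purity) importance is reported as mean +- sd of
  per-tree normalized importances; like its R counterpart it inflates
  high-cardinality variables and splits credit between correlated
  covariates.
- The occurrence model's establishment probability is compared to
  max-scaled abundance without recalibration; its "accuracy" is therefore
  dominated by the scale mismatch (values around 6), exactly as in the
  workflow it reproduces — it is a comparison device, not a fair error
  estimate.
- Voronoi units are convex and size-homogeneous compared to real
  administrative polygons, which makes zonal aggregation mildly easier
  than in production GIS work.
- Climate layers are min-max rescaled fields, so their marginal
  distributions are range-exact but not distribution-matched to real
  bioclimatic surfaces.
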