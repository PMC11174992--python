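# Methods

## The model

The package estimates where a species can live by combining three binary
suitability judgements per grid cell *i*:

```
CHS_i = TM_i ∩ S_i ∩ U_i
```

* **TM_i — climate suitability.** An ensemble of niche models fitted to
  presence and pseudo-absence points. Each base model *j* is scored on a
  held-out fold with the true skill statistic (TSS = sensitivity +
  specificity − 1, maximized over thresholds) and the rank-based AUC.
  Members with TSS > 0.7 are retained and averaged with TSS-proportional
  weights,

  ```
  W_j = r_j / Σ_h r_h,        EM_i = Σ_j W_j · X_ij,
  ```

  where r_j is member *j*'s TSS and X_ij its score at cell *i*. Because the
  weights are convex, EM_i always lies inside the envelope of member
  scores. The continuous EM map is binarized at the threshold maximizing
  TSS on the pooled held-out calibration points; future projections reuse
  this single threshold so that range changes reflect climate shifts, not
  threshold drift.

* **S_i, U_i — limitation models.** Soil classes (categorical, one-hot
  encoded) and UV-B (continuous) are fitted separately as
  presence-vs-background penalized logistic scorers — the standard
  maximum-entropy-equivalent GLM formulation of presence-background
  estimation. Skill is the mean test AUC over ten 75/25 train/test
  repeats; the final scorer is refit on all points and binarized at the
  threshold maximizing training sensitivity + specificity (the same argmax
  as max TSS, since the two criteria differ by the constant 1). Limitation
  layers are held at their baseline state in future projections.

The 2³ combinations of (TM, S, U) define habitat types I–VIII; type II
(all three suitable) is the comprehensively suitable "core" habitat.
Across *m* future scenario runs the certainty index

```
C_i = (1/m) Σ CHS_i
```

is the fraction of runs in which a cell is core habitat; the consensus
range is C_i **strictly** > 0.5, so a cell suitable in exactly half the
runs is excluded. The all-runs intersection ("merge", C_i = 1) is also
exposed.

Areas are spherical-quadrangle cell areas, A = R²·Δλ·(sin φ_top − sin
φ_bot) with R = 6371.0088 km, accumulated per habitat type and per change
class. Range change decomposes into unchanged/gain/loss, which is exactly
conservative: unchanged + loss = baseline suitable area and unchanged +
gain = future suitable area. Percent contraction is 100·(current −
future)/current, reported to two decimals. (Published studies
occasionally print values that disagree with this formula by a unit in
the last digit or more; the package always reports the formula's value.)

## Occurrence cleaning

Three standards: exact-duplicate removal plus at most one record per grid
cell (first record wins); records on nodata cells or outside the extent
are dropped with a logged count; greedy great-circle thinning keeps a
record iff it is > 10 km (haversine, R = 6371.0088 km) from every record
already kept. The greedy pass is order-dependent, so records are sorted
by (lat, lon) first; the output is idempotent under re-thinning and all
pairwise distances exceed the minimum.

## Predictor screening

Collinearity reduction runs on the values extracted at the occurrence
points, not over the whole raster — the niche is characterized where the
species occurs. Columns are standardized, PCA is fitted, and variables
are ranked by their maximum absolute loading over the leading components
reaching 90% cumulative variance (ties broken lexicographically). The
ranked list is traversed greedily, keeping a variable iff its |Pearson r|
with every kept variable is < 0.6. Zero-variance columns are excluded
before PCA. The output always satisfies the pairwise-correlation bound by
construction.

## Base learners

* **SRE** (surface range envelope): per-variable [2.5, 97.5] percentile
  interval of the presences; score 1 inside all intervals, else 0.
* **GLM**: logistic regression on standardized predictors fit by
  iteratively reweighted least squares with a 10⁻⁶ ridge term so the
  Newton step stays well-posed on separable data; linear predictor
  clipped to ±30 before the inverse logit.
* **RF, GBM, CTA, ANN, FDA, MAXENT** (registry entries): scikit-learn
  estimators adapted to the same contract (predictor rows in, [0, 1]
  scores out). GAM and MARS have no suitable backing library in this
  environment and are not registered; the registry is pluggable, so a
  caller can add any object with `fit`/`predict_score`.

Default training layout: 3 pseudo-absence sets × 500 uniform background
cells (presence cells and nodata excluded) × 10 random 80/20 train/test
splits per set, every algorithm fitted on every split — with 4 algorithms
that is the 120-member factorial. Pseudo-absences carry the same weight
as presences; class balance is left to the learner.

## Thresholds and ties

Candidate thresholds are the midpoints between consecutive sorted unique
scores plus 0 and 1: a finite scan that is provably exhaustive, since TSS
is constant between observed scores. Ties in the argmax resolve to the
smallest threshold. Note that tied maximizers are common on small score
sets — e.g. for presences {0.9, 0.8, 0.4} vs absences {0.7, 0.3, 0.2}
the maximum TSS of 2/3 is attained at both 0.35 and 0.75, and the rule
returns 0.35.

## Variable interpretation

Predictor contributions are permutation importances: the mean drop in
ensemble AUC over n_perm shuffles of one calibration column, clipped at
zero and normalized to sum to 100%. Contributions above 10% are called
dominant. The preferred range of a dominant variable is the
highest-density interval of its values over the suitable cells: a
Gaussian KDE is evaluated on a 512-point grid and the interval grows
outward from the mode, always toward the denser side, until it holds 50%
of the total density (the mass is configurable; mass = 1 spans the full
observed range). Group differences between scenario periods can be tested
with the tie-corrected Kruskal–Wallis H (chi-squared p-value, k − 1 df).

## The synthetic landscape

Tests and the acceptance script run on virtual landscapes because the
real inputs (global climate surfaces, soil maps, UV-B climatologies,
herbarium records) cannot accompany a test suite. The generator produces:

* continuous climate layers as Gaussian-smoothed white noise
  (autocorrelation scale = `correlation_length` cells, 8 by default),
  standardized and linearly mixed through the symmetric square root of a
  requested cross-correlation matrix — on a 100×100 grid the realized
  Pearson r is within roughly ±0.2 of the target;
* one categorical soil map made by quantile-slicing another smoothed
  field into contiguous patches (5 classes by default), mimicking mapped
  soil polygons;
* one continuous UV-B layer (an independent smoothed field);
* a virtual species with a known response — a rectangular envelope or an
  inverse-logit of a linear predictor — whose true suitability and true
  range are stored;
* occurrence samples drawn without replacement with probability ∝ true
  suitability × detection probability; nodata cells are never sampled;
* future scenarios as additive offsets on continuous climate layers only.

The default virtual species is a one-sided envelope on the first climate
axis (bio1 ≥ 1 in standardized units), occupying roughly 16% of the
landscape — a realistic prevalence for a habitat specialist and small
enough that uniformly drawn pseudo-absences are mostly true absences.
Default experiments use a 100×100 grid (10⁴ cells) and 200 presence
draws; these sizes keep a full factorial run in seconds while leaving
enough cells for stable KDE and importance estimates.

What the generator does **not** emulate: anisotropy and trends in real
climate surfaces, spatially biased sampling effort, coordinate error,
non-additive (pattern-changing) climate change, and soil maps correlated
with climate. Passing tests therefore demonstrate that the machinery is
correct and that the pipeline recovers a known truth under clean
conditions — not that any particular real species analysis is right.

## Reproducibility

All randomness flows from one master seed through named
`numpy.random.SeedSequence` substreams: `[seed, 0]` landscape, `[seed,
1]` occurrence sampling, `[seed, 2, pa_set]` pseudo-absence sets,
`[seed, 3, pa_set, run]` train/test splits, `[seed, 4, pa_set, run,
algo]` per-algorithm fitting, `[seed, 5]` limitation background,
`[seed, 6, rep]` limitation repeats, `[seed, 7]` permutation importance.
The pipeline ledger records per-stage parameters, SHA-256 array
checksums and timings; a rerun with the same config and seed reproduces
identical checksums.

## Known limitations

* The ensemble registry covers 8 of the 10 classical SDM algorithm
  families; GAM and MARS are absent (no backing library).
* The SRE member often scores below the 0.7 TSS retention cutoff — as the
  weakest classical algorithm it is frequently down-weighted to zero,
  which the retention rule is designed to do.
* Binarization calibrates on pooled held-out folds; with few occurrences
  the pooled folds overlap across runs, so the threshold is not fully
  independent of training data.
* Raster I/O is single-band ESRI ASCII text; fine for the grid sizes the
  package targets, inefficient for continental 1-km grids.
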