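# Methods

`radsurv` predicts the 3-year overall-survival status of locally advanced
lung-cancer patients from planning-CT radiomics of two regions of interest —
the gross tumor volume (GTV) and the whole lungs (with the GTV excluded) —
and evaluates the resulting classifier as a survival risk stratifier. This
note records the model, its assumptions, the numerical conventions, and the
choices made where the design was genuinely open.

## Preprocessing

Each ROI is cropped to its tight 3D bounding box. Voxels inside the box but
outside the ROI are marked zero for export parity; every statistic uses the
validity mask, never the zero values, so zero-marking is lossless by
construction. Intensities are resampled to 1 × 1 × 5 mm (trilinear for HU,
nearest-neighbour for the mask) and discretized with absolute binning:

    bin = floor((HU + 1000) / 10), clamped to [0, 399]

i.e. 400 bins of exactly 10 HU covering −1000..3000 HU. Out-of-range HU
(metal artefacts, sub-air values) is clamped to the edge bins rather than
rejected. Resampling uses grid-point alignment: output sample *j* sits at
physical *j*·target over the extent (*n*−1)·spacing, so resampling at the
native spacing is the identity, constants are preserved exactly, and linear
ramps interpolate to neighbour averages. Cell-centred alignment (the
SimpleITK convention) is the documented alternative; at these spacings the
difference is below half a voxel everywhere.

No interpolation kernel or scanner-calibration harmonisation beyond
absolute HU binning is attempted; multi-scanner HU drift is a known,
unmodelled source of variance in real cohorts.

## The 92-feature pool

46 features per ROI, names prefixed `TUMOR_` / `LUNG_`:

| family | n | features |
|---|---|---|
| GLCM | 7 | Homogeneity, Energy, Contrast, Correlation, Entropy_log10, Entropy_log2, Dissimilarity |
| GLRLM | 11 | SRE, LRE, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLNU, RLNU, RP |
| NGLDM | 3 | Coarseness, Contrast, Busyness |
| GLZLM | 11 | SZE, LZE, LGZE, HGZE, SZLGE, SZHGE, LZLGE, LZHGE, GLNUz, ZLNU, ZP |
| SHAPE | 3 | Volume_mL, Sphericity, Compacity |
| CONV | 7 | HUmin, HUmean, SUVstd, HUmax, HUQ1, HUQ3, TLG_mL |
| HISTO | 4 | Skewness, Kurtosis, Entropy_log10, Energy |

Conventions, chosen once and frozen:

- **Grey levels.** Texture matrices index levels as bin + 1 (1..400) so the
  reciprocal-level emphases (LGRE, LGZE, …) are always defined. Features
  built on level differences are unaffected by the offset.
- **Directions.** GLCM and GLRLM are computed per direction over the 13
  unique 3D directions at distance 1 and averaged; single-direction matrices
  (e.g. the +x run-length matrix of the lungs) remain accessible through
  `glrlm_matrix`.
- **Masking.** Only valid voxels enter any matrix; runs and neighbourhoods
  break at invalid voxels, and zero-marked voxels never contribute a grey
  level.
- **NGLDM** follows the classical neighbourhood-difference construction:
  per-level accumulated |level − mean(valid 26-neighbours)|, from which
  Coarseness, Contrast and Busyness are formed. An ROI with a single
  occupied level has Contrast = Busyness = 0 by convention, and a perfectly
  flat ROI (zero accumulated difference) reports Coarseness equal to the
  number of contributing voxels rather than infinity, keeping every feature
  finite.
- **"SUV"-named indices** keep their names but operate on HU:
  `CONV_SUVstd` is the population (divide-by-N) standard deviation of HU,
  `TLG_mL` = mean HU × volume in mL. Histogram skewness/kurtosis are
  computed on the binned values; kurtosis is excess kurtosis; both are 0
  for a zero-variance ROI.
- **Shape.** Volume = voxel count × voxel volume. Surface area comes from a
  marching-cubes mesh of the mask by default: voxel-face counting (kept as
  `area_method="voxel"`) overestimates smooth surfaces by up to ~50%, which
  would push the sphericity of a digitized ball to ~2/3 instead of the
  analytic limit of 1. Sphericity = π^(1/3)(6V)^(2/3)/A; Compacity is
  defined here as A^(3/2)/V (dimensionless, rising with surface
  irregularity) — the upstream tool this naming follows does not publish
  its exact formula.

Every texture feature is verified against an independent pure-Python
enumerator (pair/run/zone/neighbourhood loops) on random grids up to
6×6×3 with ≤5 levels, plus closed-form limits (constant ROI, single runs,
uniform histograms).

## Feature selection and model training

The classifier is a soft-margin linear SVM; death within 3 years is the
positive class. Features are standardized (center/scale estimated on the
training data, re-estimated inside every cross-validation fold) before
fitting — without this, hyperplane distances would be dominated by
HU-scaled features over unitless ones.

Selection is a genetic algorithm over binary feature-inclusion templates:

- **Fitness** of a template: leave-one-out cross-validated *balanced
  accuracy* of the SVM restricted to the included features. Balanced
  accuracy is robust to class imbalance; a parsimony tie-break prefers
  fewer features at equal score. A LOOCV fold whose training part is
  single-class predicts that class.
- **Evolution**: random initial population; each generation scores all
  templates (memoized), keeps the top `elite_fraction`, and fills the rest
  with offspring of tournament-selected parents (uniform crossover with
  probability `crossover_rate`, then per-bit mutation at `mutation_rate`),
  replacing the lower scorers. The best template of each generation is
  collected; the best of that group is the result.
- **Optional memetic refinement** (`local_search=True`): greedy single-bit
  hill-climbing on the collected best (up to 3 passes, accepting flips
  that raise the LOOCV score or match it with fewer features). It
  sharpens the fitness optimum but, at small n, a sharper LOOCV optimum
  is not always a better feature set — the wrapper's selection bias means
  noise subsets can out-score the truth — so it is off by default.
- **Defaults**: population 50, 100 generations with early stop after 20
  stagnant generations, mutation 0.02, crossover 0.8, elites 10%,
  init inclusion probability 0.5. All configurable; everything is
  reproducible from a single seed.
- **Speed**: LOOCV scoring goes through scikit-learn's low-level libsvm
  binding when available (verified prediction-identical to ``SVC`` and
  ~2.5x faster on LOOCV-sized folds), with a transparent ``SVC``
  fallback; template scores are memoized within a run.

After selection, the SVM regularization C is chosen by exhaustive LOOCV
search on the log grid {0.01, 0.1, 1, 10, 100}, ties toward the smaller C
(the stronger regularizer). The ε listed alongside C and γ for the linear
kernel is used as the optimizer stopping tolerance; γ is inert for a linear
kernel and is carried as a recorded field only. The final model is refit on
the whole training cohort; its decision variable is the signed distance to
the hyperplane, (w·x_std + b)/‖w‖, and ROC curves sweep a threshold over it
(trapezoidal AUC; ties contribute ½, equivalent to the Mann–Whitney U
statistic).

Hyperparameters are searched *after* selection, not co-evolved with the
templates.

## Evaluation

- **Confusion metrics** (death positive): TPR, TNR, F1, overall accuracy
  (correct/all) and average accuracy = (TPR + TNR)/2, all as percentages;
  the identity is asserted on every summary produced.
- **Importance weight** of a selected feature: retrain without it and take
  IW = AUC(full) − AUC(without); features are ranked by descending IW. The
  evaluation cohort is a parameter, so training-cohort and
  validation-cohort rankings are both producible.
- **Group ablation** removes every selected feature with a given name
  prefix (e.g. `LUNG_`) and reports both AUCs and their difference.
- **Cohort split**: uniform random 2:1; training size defaults to
  round(2n/3) with an explicit override (a 298-patient cohort reported as
  200/98 needs the override, since rounding gives 199).
- **Risk stratification** is a pure function of the predicted status:
  predicted survivors are low-risk, predicted deaths high-risk. Survival
  is compared by Kaplan–Meier curves (3-year OS read at t = 36 months) and
  the two-group log-rank test, unadjusted, matching two-group use.
- **Feature–indicator correlation**: pairwise-complete Pearson r between
  radiomic features and pulmonary-function / blood-gas indicators
  (FEV1/FVC%, DLCO%, pO2, AaDO2, SaO2); cells with under 3 complete pairs
  or a constant column are reported as unavailable (NaN), not errors.

## Synthetic data

The generators define the study conditions for every test:

- **Phantoms**: an ellipsoidal tumor (default 12×10×12 mm semi-axes,
  mean +30 HU) inside an ellipsoidal lung field (baseline −850 HU) on a
  64×64×16 grid at 1×1×5 mm. Texture is spatially correlated noise —
  white noise smoothed with a Gaussian kernel whose width is the
  correlation length (default 3 mm), rescaled to unit variance, then
  scaled by the heterogeneity amplitude in HU (tumor 60, lung 40). This
  moves run/zone statistics in the documented directions (more
  heterogeneity → shorter runs, more zones, higher SRE/RP, lower LRE). It
  does not emulate anatomy, vasculature, partial-volume effects or
  acquisition noise, so passing tests demonstrate pipeline correctness,
  not clinical performance.
- **Feature cohorts**: class labels Bernoulli(prevalence 0.5); features
  i.i.d. standard normal except a planted informative subset whose means
  shift by a stated standardized effect in the positive class. The planted
  recovery suite uses n = 60 patients, p = 30 features, 4 informative at
  shift 1.5 — a deliberately hard setting where single features are weak
  (per-feature AUC ≈ 0.86) and only a subset search succeeds.
- **Survival**: per-class exponential event times (Weibull optional),
  means (60, 12) months for predicted survivors/deaths by default,
  independent random censoring (rate 0.2) plus administrative censoring at
  120 months.

## Problem sizes and study-scale choices

The GA defaults above are for real analyses; the multi-seed suites
(20-seed planted recovery, 50-seed null calibration) run a reduced
configuration — population 24, 15 generations, early stop after 8
stagnant generations — which the package treats as adequate for p ≈ 30
screening problems. Null calibration scores one random template per seed
under a zero-effect generator; planted recovery counts runs whose
selected set contains at least 3 of the 4 informative features. Recovery
under these conditions is intentionally hard: at n = 60 the LOOCV wrapper
exhibits genuine selection bias (on some data realizations a subset of
two informative features plus noise out-scores every subset containing
three or more informative features), so the expected recovery rate sits
near, not far above, the 80% bar.

## Known limitations

- No bit-exact parity with any external radiomics tool is claimed; family
  conventions (grey-level offset, direction averaging, NGLDM accumulator)
  are documented above and locked by the oracle tests instead.
- LOOCV scoring refits one SVM per sample per template; cohorts beyond a
  few hundred samples will want a cheaper fitness (k-fold) — not provided.
- The phantom generator is a texture testbed, not an anatomical simulator.
- Pearson correlation and the log-rank test are reported without
  multiplicity adjustment, by design.
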