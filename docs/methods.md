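# Methods

`radsurv` implements a prognostic-imaging analysis for EGFR-mutant lung
adenocarcinoma treated with first-line EGFR tyrosine-kinase inhibitors
(TKIs): quantitative (radiomic) features are extracted from the segmented
tumour on baseline and first-follow-up CT, screened for reader stability,
redundancy and univariate prognostic value, and combined with clinical
factors in Cox proportional-hazards models of progression-free survival
(PFS). This note documents the models, conventions, defaults and known
limitations.

## Feature extraction

All features are computed in 3D from a Hounsfield-unit volume and a
binary tumour mask with anisotropic voxel spacing `(dx, dy, dz)` in mm.
Arrays are stored slice-major `(z, y, x)`; geometry code converts
explicitly. No resampling is applied by default.

### Grey-level discretization

Texture matrices need integer grey levels. Two modes
(`BinningSpec`):

* `fixed_count` (default, `N_g = 64` over the ROI min–max): makes
  texture features invariant to a constant HU offset; the default
  because the cohorts here mix scanners and contrast phases.
* `fixed_width` (default 25 HU): preserves the absolute contrast scale.
  Texture cutoff values are only transferable between datasets if the
  binning mode and parameters match, so the binning spec is carried in
  the feature configuration and reports.

A constant-intensity ROI maps to the single level 1.

### First-order features (15)

`mean, standard deviation, variance, skewness, kurtosis` are population
(biased) moments of the raw HU values; kurtosis is non-excess
(a Gaussian gives 3); skewness and kurtosis of a zero-variance ROI are
defined as 0. `C5 … C95` are percentiles of the raw HU distribution with
linear interpolation. Three names follow common in-house
texture-software conventions rather than a single standard, and are
therefore implemented as documented, configurable choices:

* `entropy` = −Σ pᵢ log₂ pᵢ over the discretized histogram;
* `homogeneity` = Σ pᵢ² (histogram uniformity);
* `energy` = Σ I(v)² (sum of squared HU over the ROI).

### Shape features (8)

* `volume` = voxel count × voxel volume (mm³); `effective diameter` =
  diameter of the equal-volume sphere.
* `surface area` comes from a marching-cubes iso-surface at level 0.5.
  The binary mask is anti-aliased with a 1-voxel Gaussian before
  iso-surfacing: a raw binary marching-cubes surface is a staircase that
  overestimates the area of smooth objects by 5–10 %. Smoothing shrinks
  convex objects slightly (mean-curvature flow), so the dimensionless
  sphere-similarity descriptors use the volume and area of the *same*
  mesh, letting the bias cancel:
  `sphericity` = π^{1/3}(6V)^{2/3}/A, `shape compactness 1` =
  V/(√π·A^{3/2}) (sphere limit 1/(6π)), `shape compactness 2` =
  36πV²/A³ (= sphericity³). The reported `volume` feature itself stays
  voxel-count based. A `voxel_faces` surface mode is available.
* `discrete compactness` is Bribiesca's contact-surface measure:
  shared voxel-face count divided by the maximum for the same voxel
  count, `A_c,max = 3(n − n^{2/3})`. The normalization is defined on
  face counts and deliberately ignores spacing anisotropy; the
  spacing-aware exposed-face area is available separately.
* `roundness` measures sphere-likeness from surface voxels only:
  `(d_inscribed / d_enclosing) × (1 − mean |rᵢ − r̄| / r̄)`, where the
  inscribed diameter is the Euclidean-distance-transform maximum
  (plus half a voxel diagonal, correcting the bias from evaluating the
  EDT at voxel centres only), the enclosing sphere is an iterative
  minimum-enclosing-ball of the surface voxel centres, and the second
  factor is the normalized mean radial displacement of surface voxels
  from the best-fit (mean-radius) sphere, capturing surface smoothness.
  Digitized spheres score ≥ 0.95, rising with radius; spiculation and
  elongation lower it monotonically.

### Texture features (GLCM 5, GLRL 1)

The grey-level co-occurrence matrix is accumulated over all 13 unique
3D directions at distance 1, summed, symmetrized and normalized.
Features: `angular second moment` Σp², `inverse difference moment`
Σ p/(1+(i−j)²), `contrast` Σ (i−j)²p, `entropy` −Σ p log₂ p, and
`moments`, implemented as the grey-level mean of the co-occurrence
distribution Σ i·p(i,j) (the order is configurable; the name is
ambiguous across texture packages).

The grey-level run-length matrix counts maximal same-level runs along
each of the 13 directions (background breaks runs), summed over
directions. `grey-level nonuniformity` GLN = Σ_g (Σ_l R[g,l])² / ΣR —
a run-concentration measure: large when runs pile up in few grey
levels. Note the direction of its dependence on texture strength is
binning-dependent: under fixed-bin-width binning, stronger texture
spreads runs over more levels and *lowers* GLN once the dynamic range
exceeds one bin.

### Wavelet features (8)

A single-level 3D *stationary* (undecimated) wavelet transform with
Coiflet-1 filters decomposes the mask's bounding box (1-voxel margin,
padded to even dimensions) into 8 sub-bands named by the filter applied
along x, y, z: `LLL … HHH`. The undecimated transform keeps every
sub-band on the original grid, so the mask applies unchanged; each
sub-band is re-discretized within the mask and its GLN computed. The
transform satisfies perfect reconstruction to ~1e−7, and axis swaps
permute the sub-band names accordingly (verified by test).

## Stability filtering

Features unstable under segmentation variability are excluded before any
modelling. The inter-reader intraclass correlation is ICC(2,1) — two-way
random effects, absolute agreement, single measures — from the classic
mean-squares decomposition; ICC(3,1) (consistency; invariant to a
reader-specific affine shift) is available. Features with ICC below 0.9
are dropped. Zero between-subject variance yields ICC = 0 with a
warning (no agreement information). The implementation is cross-checked
against `pingouin.intraclass_corr` in the test suite.

## Feature selection

Three feature sets are analysed: baseline, first follow-up, and percent
change `100·(followup − baseline)/baseline` (undefined for a zero
baseline; a feature that decreases under therapy is negative — the sign
convention was fixed against the worked numeric examples).

Per feature set:

1. **Redundancy grouping.** Features with pairwise Pearson r > 0.95 are
   linked; groups are connected components. The rule uses signed r by
   default (per the workflow's published description), with an |r| mode
   available. Constant features are excluded with a warning.
2. **Optimal-cutpoint dichotomization.** Each feature is dichotomized
   at the cutoff giving the most significant two-group log-rank split.
   Candidates are midpoints of consecutive sorted unique values;
   candidates leaving < 10 % of patients on either side are discarded
   (the minimum-p approach degenerates at extreme splits); ties go to
   the more balanced split, then the lower cutoff. The scan is exact
   (vectorized over all candidates) and matches exhaustive enumeration.
   Note the minimum-p approach inflates type-I error — a null feature
   yields p < 0.05 far more often than 5 % (quantified in the tests);
   downstream p-values are treated as a ranking device.
3. **Univariate screen.** A single-covariate Cox model on the
   dichotomized indicator gives each feature an HR, CI and Wald p; the
   smallest-p member represents each correlation group.

Surviving features from all three sets are pooled, p-values are
Benjamini–Hochberg adjusted, and the best `k = 4` features (smallest
adjusted p; ties by raw p, then name) enter the multivariate model —
keeping roughly ten events per candidate covariate at the study's
sample size.

## Survival modelling

Cox proportional-hazards fits maximize the Efron-tie-corrected partial
likelihood by Newton–Raphson (via `lifelines`; only Efron tie handling
is provided). Collinear covariates are rejected with the offending pair
named; constant covariates get coefficient 0 by convention; fits warn
below 10 events per covariate.

* **Radiomic model:** backward stepwise Cox on the top-k dichotomized
  features — iteratively drop the covariate with the largest Wald
  p > 0.05 and refit until all remaining p ≤ 0.05.
* **Clinical model:** candidate covariates (age dichotomized at its own
  optimal log-rank cutoff, sex, smoking, extrathoracic metastasis,
  EGFR exon-19 deletion, baseline diameter continuous per mm, RECIST
  response with responder = 1 so HR < 1 is protective) are screened at
  univariate p < 0.20, then backward stepwise.
* **Combined model:** a joint refit of the union of the covariates
  retained by the radiomic and clinical models (not a stack of the two
  linear predictors) — the union refit is the cleaner-defined choice
  when the published description is ambiguous.

Discrimination is Harrell's concordance index: over pairs where the
shorter observed time is an event, the fraction in which the
shorter-surviving patient has the higher linear predictor, prediction
ties counting ½ (equal observed times are not comparable). Confidence
intervals and model comparisons use a patient bootstrap (default
B = 1000) with the *original* coefficients applied to each resample
(no refitting), percentile CIs, and paired t-tests over the B paired
c-index differences. The whole analysis is a deterministic function of
(data, config, seed); reports serialize byte-identically.

The report schema is published as pydantic models
(`radsurv.pipeline.AnalysisReport`); loading a report re-validates it.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
exercised:

* **Phantoms** (`make_phantom`): ellipsoids (default radii 12 mm on a
  0.7×0.7×2.5 mm CT-like grid) optionally deformed by Gaussian surface
  bumps ("spiculation"), filled with a correlated Gaussian intensity
  texture (default correlation length 2 mm, variance 400 HU², mean
  40 HU — an enhancing solid nodule) over an aerated-lung background
  (−800 HU). Deterministic per seed.
* **Reader pairs** (`make_reader_pair`): a second contour is produced
  by adding a smooth zero-mean random field (SD 0.5 mm by default) to
  the signed distance of the boundary — interior and far exterior are
  untouched, mimicking slice-wise freehand variability. Dice with the
  original stays ≳ 0.95 at defaults; a floor (default 0.8) is enforced.
* **Cohorts** (`make_cohort`): default n = 48 patients. Follow-up
  features are unit-variance Gaussians (mean 10) with a configurable
  correlation structure including an r > 0.99 clone pair that exercises
  redundancy grouping; true log hazard ratios (default ln 2 on
  roundness, ln 1.5 on grey-level nonuniformity, per standardized unit)
  act on the follow-up values. A latent per-patient treatment benefit
  drives both the baseline→follow-up feature drift and the diameter
  shrinkage that defines RECIST response (≥ 30 % shrinkage), linking
  response, feature change and survival as in real cohorts. Event times
  are exponential given the hazard; the hazard scale is calibrated so
  the population median event time is exactly ln 2 / baseline-hazard
  (default 9.7 months — naive scaling misses the target because the
  survival mixture is not exponential under hazard heterogeneity).
  Censoring is independent exponential with its rate solved numerically
  to hit the target censored fraction (default 20 %). Clinical hazard
  contributions (age, baseline diameter) are configurable and can be
  switched off to obtain a correctly-specified 2-covariate model for
  parameter-recovery studies.

What the generator does *not* emulate: scanner/protocol heterogeneity,
reconstruction physics, partial-volume and contrast-timing effects,
non-proportional hazards, and informative censoring. Passing tests on
synthetic cohorts demonstrate the correctness and calibration of the
statistical machinery, not clinical validity on real CT data.

## Problem sizes and numerical choices

The test suite uses phantoms of ~20×36×36–36×48×48 voxels, reader
studies of 12–15 phantoms, cohorts of 48–2000 patients, 100-replicate
parameter-recovery designs at n = 500, and bootstrap sizes of 50–1000;
these sizes give stable assertions while keeping the full suite fast.
Cox convergence follows `lifelines` defaults; the cutpoint scan is
exact, with ties broken deterministically; minimum-enclosing-ball uses
a deterministic iterative scheme accurate to a fraction of a voxel
(the resolution of the surface itself); random numbers come exclusively
from explicit seeds (`numpy.random.default_rng`) — there is no hidden
global state.

## Reproducing the published table analysis

The deposited 48-patient feature/clinical table of the original study
is not redistributable with this package; `load_cohort_table` reads it
(XLSX or CSV) through a user-supplied column mapping
(`data/s1_schema_map.template.yaml` documents the expected keys). With
the table present, the acceptance test in
`tests/test_acceptance.py::TestStudyTableReproduction` reruns the full
analysis and compares cutoffs, hazard ratios and concordance indices
against the published values. Residual discrepancies, if any, would be
traceable to choices the original description leaves open (ICC variant,
binning, stepwise criterion, cutpoint constraints), all of which are
configurable here.

## Known limitations

* Only Efron tie handling for Cox fits.
* The ambiguity in "moments", first-order "homogeneity"/"energy" and
  the roundness displacement term means absolute feature values are
  comparable only within a fixed configuration.
* The bootstrap compares fixed linear predictors; it quantifies
  sampling variability of the c-index, not model-selection uncertainty
  (selection and stepwise fitting are not repeated per replicate).
* The optimal-cutpoint univariate p-values are anti-conservative by
  construction and are used for ranking only.
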