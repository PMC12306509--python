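# Methods

This note records the models the package implements, the conventions and
defaults behind them, and the design choices made where more than one
defensible option existed.

## The synthetic cohort

All development and validation runs on generated cohorts with known ground
truth; the generator is first-class, tested code, not a fixture.

**Anatomy.** A spherical "brain" (default radius 15 mm) on a 24³ grid of
1.5 mm isotropic voxels, with gray-matter values falling quadratically from
0.70 at the center to 0.25 at the edge and 0 outside.  Per-subject noise is
white Gaussian (sd 0.5 pre-smoothing) smoothed with an 8 mm FWHM Gaussian
kernel — smoothing belongs to the generator because preprocessing real
images is out of scope.  The framework itself is grid-size-agnostic; the
small grid keeps every study desk-scale.

**Planted group effects.** Each effect region is a sphere (center voxel,
radius in mm) with a standardized effect size d: exposed-group voxels
inside the region are shifted by d × (pooled empirical voxel sd), so the
realized per-voxel Cohen d converges to the configured d (verified to
|error| < 0.15 at n = 200/group over 20 seeds).  The sign convention is
exposed (DD) minus control (ODD); the default −0.35 plants a deficit of
the size a large matched cohort would report.

**Cognition.** Each of six domains (memory, visual-spatial, processing
speed, executive function, working memory, language) has a latent score
`Σ_r w_r · z(regional mean GMV) + N(0, noise_sd)`; raw tests load 0.8 on
their domain latent, with three timing-based tests emitted negatively
oriented (slower = worse) to exercise the sign-flip in the composites
stage.  By default executive function and processing speed are wired to the
planted temporal region — the two domains the exposure contrast should
show.

**Demographics.** The exposed group is drawn 3 years older before matching
(the one deliberate imbalance, so matching diagnostics have a known
direction); gender, education, TIV, and three comorbidity flags are
balanced by construction.  A 0–5 technology-use frequency item is drawn
consistently with group membership so the assignment rule can be
round-tripped.

**Follow-up.** `V_t2 = V_t1 (1 + rate · Δt) + scan noise`, with
`rate = base + delta · [exposed ∧ in decline region]` (defaults
−0.005/yr and −0.010/yr extra, i.e. the exposed group loses 1.5%/yr in the
planted frontal sphere).  Decline is multiplicative on baseline so volumes
stay non-negative for moderate rates and "percent per year" is natural;
negatives arising at extreme rates are clipped at 0 and counted.  Follow-up
intervals are 3.2 ± 0.3 years per subject.  Scan noise at t2 (sd 0.2
pre-smoothing) makes recovered rates noisy, as real segmentations are;
setting it and the interval jitter to 0 makes the rate computation an exact
round-trip (machine precision), which the rate-exactness study verifies.
Follow-up cognition advances each domain latent by a base slope, an
exposed-group extra slope, and a weight on the subject's standardized
decline-region rate — the last being the planted mediation pathway.

**What the generator does not emulate.** Cortical anatomy and folding,
registration error, scanner artifacts, site effects, non-Gaussian test
distributions, missingness mechanisms.  Passing recovery tests therefore
show the *estimators* behave as designed under clean conditions, not that
any particular real-data effect exists.

## Matching

Logistic regression of exposure on the configured covariates gives the
propensity score; greedy nearest-neighbor 1:1 matching without replacement
on the logit of the score, within a caliper of 0.2 sd of the logit, is the
most common published recipe and is what the package implements.  The visit
order of exposed subjects is shuffled under a fixed seed (ties broken by
subject id).  Perfect separation is flagged and falls back to an
L2-penalized fit unless the caller forbids it.  Balance is reported as
standardized mean differences, `(mean₁ − mean₀)/pooled sd`, before and
after matching.  Optimal/full matching and weighting are out of scope.

## Voxel-wise statistics

The group contrast is the t statistic on the group indicator in a per-voxel
OLS fit `GMV ~ group + covariates` (covariate adjustment inside the model,
not pre-residualization), two-sided p, df = n − rank(design).  FDR is fixed
to Benjamini–Hochberg (via statsmodels, cross-checked against an
independent step-up oracle).  Clusters use face (6-)connectivity with a
10-voxel minimum extent — conservative and standard for VBM; each cluster
reports size, peak |t| voxel in index and mm coordinates, and the atlas
label at the peak.  The brain mask is `mean gray matter > 0.2` across
subjects.

## Searchlight

The neighborhood of a voxel is every in-mask voxel whose center lies within
the radius in millimeters (affine-derived voxel sizes; center included).
The default 2 mm radius on a 1.5 mm grid gives 7-voxel spheres — the center
plus its six face neighbors; the 2.12 mm edge neighbors fall outside.

Features are PCA components of the sphere's centered (not scaled)
subjects × voxels matrix, keeping the smallest component count whose
cumulative explained variance reaches 80%.  Classification is a linear
soft-margin SVM with C = 1 under stratified 10-fold cross-validation with a
fixed shuffle seed; the map stores the pooled held-out accuracy (not the
per-fold mean — pooling is more stable at small n).  **PCA is fitted inside
each training fold** and applied to the held-out fold, so no test
information leaks into the features; a `pca_global` switch reproduces the
literal reduce-then-classify ordering for comparison.  Features come from
covariate-unadjusted volumes (covariates are adjusted only in the t-map
step); residualized inputs can be supplied for sensitivity analysis.
Zero-variance neighborhoods are flagged and scored by the majority class,
never fatal for the map.

Constrained regions are the FDR-significant t-map voxels with accuracy
strictly above the threshold (default 0.6); the remaining significant
voxels are excluded.  The two sets tile the significance mask exactly.

## Cognitive representation

At each constrained voxel the sphere's PCA features enter a linear model
predicting a domain composite.  Predictions are **out-of-fold** by default
(10-fold), because in-sample fitted values are optimistically correlated
with the outcome; an `insample` switch gives the literal fit-then-correlate
variant.

The permutation null needs care.  Held-out OLS predictions are *negatively*
correlated with the outcome under the null — fold-wise intercepts predict
each held-out subject from the other folds' mean, and for a leave-one-out
mean model that correlation is exactly −1; we measure ≈ −0.1 to −0.19 at
n = 100.  A null built by shuffling the fixed predicted vector is therefore
anticonservative for CV predictions (and conversely misses the in-sample
optimism).  The map instead permutes the **observed scores and re-applies
the entire prediction step to each shuffle**.  Because OLS predictions are
linear in the outcome (`pred = H y`, with H the CV or ordinary hat matrix),
each of the default 10,000 permutations costs one matrix multiply, and the
null is exact for whichever prediction mode is active.  The test is
one-sided on r — predictive skill means correlating *better* than chance,
whose level sits below zero for CV predictions — with the add-one
estimator `p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1)`.  The simple
shuffle-the-predictions scheme remains available (`permutation_null`) for
fixed prediction/observation pairs, where it is valid.  FDR is applied per
domain across constrained voxels (default level 0.001), matching per-domain
reporting; coverage = significant / constrained per domain.

## Longitudinal analysis

**Rates.** `(V_t2 − V_t1) / (V_t1 Δt)`, a signed fraction of baseline per
year (negative = atrophy); an absolute-difference mode is available.  The
convention is labelled explicitly wherever rates are reported because
"decline rate" is sign-ambiguous in common usage.  Zero-baseline voxels are
undefined (NaN), masked and counted.  Exactly two timepoints are assumed;
more would require per-subject least-squares slopes (documented extension,
not implemented).  Region rates are in-mask means over atlas labels.

**Cognitive change** for correlation and mediation is
`(follow-up composite − baseline composite) / Δt`.

**Mediation** is product-of-coefficients with two covariate-adjusted OLS
fits — `mediator ~ group + covariates` (a) and `outcome ~ mediator + group +
covariates` (b, c′) — and a 5,000-draw percentile bootstrap over subjects
for the indirect effect a·b and the proportion mediated a·b/c.  The
proportion is reported only when a·b and c agree in sign and |c| is
non-negligible; it is invariant to affine rescaling of the outcome.

**Growth model.** The combined mixed model implied by the two levels —
fixed effects for baseline age, gender, education, group, time, and all
four time interactions; correlated random intercept and slope; ML (not
REML) — is fitted with statsmodels MixedLM (lbfgs, Powell fallback).
Baseline age and education are mean-centered (intercept interpretability;
slope effects unchanged).  Non-convergence is flagged, never silent, and a
random-effect variance below 1% of the residual variance raises a boundary
flag: with only two observations per subject the slope variance is at the
edge of identifiability, so pipeline fits on two-wave data routinely carry
this flag — that is the honest answer, not an error.  The null
(intercept-only) model reports the ICC as between/(between + within)
variance.

## Numerical and reproducibility choices

- Every stage draws from `numpy.random.default_rng([seed, stage_offset])`;
  no global random state is touched.  Identical config + seed gives
  bit-identical volumes, tables, and maps.
- Voxel indices are 0-based; mm coordinates come from the affine; reported
  peaks carry both.
- Volumes are NIfTI-1, float32 on disk, 4-D stacks for cohorts; tables are
  CSV/TSV; results and manifests JSON.
- BH q-values come from statsmodels; the propensity model from statsmodels
  Logit; SVMs, PCA scaffolding, and fold splitting from scikit-learn; the
  per-voxel OLS, the searchlight PCA (plain SVD, for per-fold speed), and
  the permutation machinery are implemented here and tested against
  long-hand oracles.

## Study sizes used in validation

The validation studies (and the acceptance script) fix their own sizes as
part of the quoted conditions: planted-region recovery uses one cohort of
80/group with a |d| = 1.2 sphere; null calibration uses ten cohorts of
40/group; permutation uniformity uses 200 voxels at 500 permutations;
growth coverage uses 200 replicates of 200 subjects × 3 visits; mediation
coverage uses 20 simulations at n = 500 with 5,000 bootstrap draws.

## Known limitations

- The searchlight loop is pure Python over voxels; at desk scale a map
  takes tens of seconds, but real-brain grids would want batching.
- The representation stage's hat-matrix permutation requires the per-voxel
  predictor to be linear in the scores; a nonlinear predictor would need
  explicit refitting per permutation.
- Greedy matching is order-dependent by construction; the seed-shuffled
  visit order makes it reproducible, not optimal.
- The one-factor-per-domain loading model ignores cross-domain structure;
  externally estimated weights can be supplied instead.
- With two-wave data the growth model's random-slope variance is only
  weakly identified (see above); three or more waves are needed for stable
  variance components.
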