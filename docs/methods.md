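# Methods

`adhdconn` re-creates, as tested and reusable code, an ensemble pipeline for
automated ADHD diagnosis from resting-state fMRI of the kind fielded in the
ADHD-200 prediction competition: connectivity and leverage-score feature
extraction, staged classifiers combined by majority vote, a hierarchical
scoring metric, and association models for the motor-network correlations.
Because the consortium imaging data cannot ship with a package, the first
component is a synthetic cohort generator with known ground truth; every
downstream stage is exercised against it.

## The synthetic cohort generator

The generator is a model of the *statistical* structure the analysis
consumes, not of MR physics.

**Phenotypes.** Subject counts are specified per site x diagnosis
(TD, ADHD-combined, ADHD-hyperactive/impulsive, ADHD-inattentive); the
default table mirrors the training release of an eight-site consortium —
heavily TD-majority sites, two all-control sites, a rare hyperactive
subtype (~1%).  Ages and gender follow per-site distributions; each subject
has a latent IQ drawn around `iq_mean_td` (110) or `iq_mean_adhd` (100)
with SD 13, observed through four noisy instrument scores (verbal,
performance, two full-scale variants, measurement SD 3) that go missing
independently at a per-site rate (default 0.10).  A small per-site IQ
offset (SD 2) and scan-noise scale factor (SD 5%) stand in for site
effects.

**Scans.** Each subject's five M1 parcel signals are a stationary AR(1)
Gaussian process (unit variance, lag-one coefficient 0.3 — a mild
low-frequency character) whose cross-correlation matrix is the subject's
own: the diagnosis group's target matrix plus independent N(0, `corr_sd`)
jitter per pair on the correlation scale, clipped and spectrally projected
back to a valid correlation matrix when jitter breaks positive
semi-definiteness.  Jittering on the correlation scale (rather than on
Fisher-z) keeps the group *mean* equal to the target by construction; the
tanh back-transform of z-scale noise would shrink means toward zero by
about `r(1-r^2)sigma^2` (~0.015 at r = 0.45), a bias comparable to the
recovery tolerance we test.  The default `corr_sd` = 0.18 makes observed
per-pair SDs land near the ~0.19-0.20 reported between subjects once
finite-T sampling noise is added.

Default target matrices are the published group-mean inter-parcel
correlations for TD, combined and inattentive children; the rare
hyperactive subtype, for which no published row exists, uses the
overall-sample matrix.  All four defaults are positive definite (smallest
eigenvalue ~0.42).

Parcel voxels receive their parcel's latent signal plus white noise
(`voxel_noise_sd` = 0.2, low so that parcel-mean correlations attenuate by
well under 0.01 for parcels of 8+ voxels); other brain voxels receive
unit-variance white noise; a linear + quadratic drift with subject-jittered
amplitude (defaults 1.0 and 0.5 over normalised time) is added across the
brain and is exactly removable by the order-2 detrend.  Out-of-mask voxels
are zero.

**Motion.** `n_motion_voxels` (default 20) voxels drawn from the mask
periphery (1-voxel Chebyshev rind) and a central CSF block are overwritten
with heavy-tailed time courses — Student-t with 3 df, optionally mixed
(weight 0.7) with a cohort-level shared course to emulate a common
population direction of head motion — rescaled so their *sample* variance
is exactly `variance_multiplier` (default 8) times the baseline voxel
variance.  Rescaling to the realised SD keeps the planting property
deterministic despite the t(3) tail.  A smooth AR(1) table of 36 "motion
parameters" is emitted per scan as nuisance regressors.

**Template.** An ellipsoidal brain mask on a configurable grid (default
20 x 20 x 10); five disjoint cuboid parcels (default 3 x 3 x 2) placed in
the eroded interior with 1-voxel gaps, labelled 1-5 in the canonical order
VL, DM, PL, AL, DL; 264 seed voxels sampled uniformly from the mask.
Grids too small for the requested geometry raise a sizing error.  All
coordinates are 0-based voxel indices; NIfTI output uses an identity
affine (RAS+).

**Determinism.** All draws derive from `rng_seed` through disjoint named
streams (template / cohort / per-subject-per-session scans / site
effects), so identical configs give bit-identical cohorts and scans, and
subject k's scan does not depend on how many subjects precede it.

**What the generator does not model** — and hence what passing tests do
not establish about real data: hemodynamic response shapes, spatial
autocorrelation within tissue, scanner-specific spectra, registration or
segmentation error, realistic motion spike trains, and any true coupling
between phenotype and image beyond the group correlation matrices and the
IQ gap.  Results on this cohort demonstrate the *machinery* is correct and
calibrated, not that the classifiers would achieve similar accuracy on
consortium data.

## Preprocessing

Temporal-only, in the order detrend -> band-pass -> nuisance regression,
applied per voxel: least-squares polynomial detrend (order 2); an ideal
discrete-Fourier band-pass with the conventional resting-state window
0.01-0.1 Hz (exact and closed-form testable; a zero-phase Butterworth is
available); least-squares residualisation on an intercept plus confounds
(the scan's motion parameters by default), with linearly dependent
confound columns dropped via pivoted QR.  All three are linear projections
or Fourier masks, so composition never increases per-column variance.
Spatial steps (registration, smoothing, segmentation) are out of scope —
on real data they are done upstream by standard tools.

## Features

* **Motor network:** the mean time course of each of the five M1 parcels,
  then the 10 Pearson correlations of all pairs, ordered as the row-major
  upper triangle of (VL, DM, PL, AL, DL).  Correlations, not Fisher-z, are
  the features.
* **CUR / leverage selection:** per subject, the leverage score of each
  in-mask voxel time course — the squared mass of its coordinates in the
  top-`rank_k` right singular vectors of the column-centred T x V matrix —
  with the deterministic top-`c` (default 20) selected, ties to the lower
  voxel index.  `rank_k` defaults to `c`, making total score mass equal to
  the selection size.  The feature vector is the row-major upper triangle,
  diagonal included, of the 20 x 20 covariance matrix of the selected
  courses: 210 values (the diagonal carries variances; a 190-length
  pairs-only variant is available).  The fraction of selected voxels in
  periphery/CSF is reported as a motion flag.  Deterministic top-c by
  leverage is used rather than randomised CUR column sampling: the method
  is described as picking "the" highest-variability time courses, and
  determinism is needed for reproducible features.  Plain variance ranking
  is available as an alternative.
* **Seed connectivity:** mean time courses within a radius (default 1
  voxel in synthetic space; ~5 mm would be the real-data analogue) of each
  of the 264 seeds, correlations of all pairs (34,716 values), reduced
  across subjects by PCA.
* **Reductions:** PCA is a column-centred SVD with a deterministic sign
  convention (largest-|loading| entry positive); the CUR 210-vectors and
  the seed vectors are stacked across all subjects and reduced to 10
  components each (the retained count for the seed family is not recorded
  anywhere authoritative; 10 is the configurable default).  Multi-session
  subjects have feature rows averaged within subject before modelling.

## Models and ensemble

* **Random forest** (4-class) on the 10 motor correlations plus age,
  gender, site, handedness and the IQ measures.
* **Two-stage gradient boosting** — stage 1 classifies TD vs any-ADHD on
  all subjects; stage 2 classifies the subtype and is *trained on the true
  ADHD subjects* (training on stage-1-predicted ADHD would leak stage-1
  errors; prediction-time gating is unchanged: stage-1 TD is final).  Used
  twice: on the CUR components + demographics, and on the seed components
  + per-parameter motion SDs + demographics.
* **Majority vote** over the prediction sets, with a designated member
  (the CUR model, historically the strongest) breaking every tie — both
  2-2 and all-singleton patterns, since plurality is undefined there and a
  single stated mechanism covers both.
* Class imbalance is deliberately not reweighted by default: TD-majority
  cohorts push all models toward TD, which the scoring rule rewards;
  optional class weights are exposed.
* Forest/boosting hyperparameters are unrecorded for the original
  competition; conventional defaults are used (500 trees; 200 boosting
  rounds, learning rate 0.05, depth 3) and every fit is seeded.

## Scoring and evaluation

Per subject: 1 point for an exact label match, 0.5 when truth and
prediction are both ADHD but the subtype differs, 0 otherwise — including
the un-enumerated truth-TD / predicted-ADHD case, the only consistent
reading.  "Accuracy" is points as percent of subjects.  Binary metrics
collapse subtypes: sensitivity, specificity, Youden's J = sens + spec − 1,
and conditional subtype accuracy over correctly detected ADHD subjects.
Metrics with empty denominators return NaN markers rather than raising.
`split_cohort` reproduces the internal data-splitting design (184 reserved
subjects at the historical cohort size; proportional for smaller runs).

## Association models

Group means/SDs of each pairwise correlation for overall/TD/combined/
inattentive; three nested multinomial logistic models per pair on the
3-level outcome (hyperactive dropped, matching the outcome set the
original analysis states): pair only; plus age, composite IQ, gender,
handedness; plus site — each pair tested by a 2-df likelihood-ratio test.
The exact covariate sets of the original "Models 1-3" are unrecorded;
minimal -> demographic-adjusted -> site-adjusted is the natural nesting
and matches the discussion of site as an important (biologically
valueless) predictor.  Ten binary logistic models relate ADHD-vs-TD to
one pair plus the four demographics, with an optional site-adjusted
variant for direction-stability checks.  Raw p-values are reported with
no multiplicity correction, as in the original tables.  Numeric covariates
are standardised internally for fit stability (p-values are invariant);
separation or non-convergence flags the cell instead of raising.

## Phenotype preparation

Composite IQ = median of a subject's observed IQ measures (computed before
any imputation, so it reflects only real observations); all remaining
missing values are filled column-wise with the observed median
(quantitative) or mode (categorical) — the classic random-forest "rough
fix", which is idempotent here.  Mode ties break to the lexicographically
smallest level for determinism.

## Numerical choices and degenerate inputs

Ideal-filter band edges are inclusive within 1e-12; detrend requires
T > order + 1; zero-variance columns are errors for correlation, flags for
regression; leverage `rank_k` above the numerical rank is reduced with a
warning; the PSD projection clips eigenvalues at 1e-6 and renormalises the
diagonal; jittered correlations are clipped to |r| <= 0.999.  Derived RNG
streams use integer stream tags, never Python's salted `hash`.

## Calibration experiments and problem sizes

`scripts/acceptance.py` recomputes, from scratch: the 0.5-point scoring
case, and the pipeline-recovered mean PL,AL correlation under the
overall-sample targets and mean DM,DL correlation under the
combined-group targets, each over 500 simulated subjects at T = 150 on
the default 20 x 20 x 10 grid (a couple of minutes on one CPU).  The test
suite additionally checks: leverage selection against a full eigendecomposition
on 100 random matrices up to 12 x 12; planted-motion recovery and the
peripheral-fraction contrast between motion-planted and motion-free
cohorts; null calibration of the association p-values (200 replicate
cohorts of n = 300, where the 2-df chi-square and Wald approximations are
in their asymptotic regime) and power >= 0.8 for the DM,DL group gap at
n = 600; and an end-to-end run (~200 subjects, 16 x 16 x 8 grid, T = 60)
where the ensemble beats the all-TD baseline on a planted-effect cohort
and stays within permutation noise on a null cohort.  These sizes are the
package's chosen experiment scales; larger cohorts only tighten the
Monte-Carlo intervals.

## Known limitations

Headline external-test results of the historical competition (61%
points-accuracy, 94%/21% specificity/sensitivity) depended on a withheld
consortium test set and are not reproducible from synthetic data; this
package makes no attempt to match them.  The online-clustering/LDA/SVM
member of the original ensemble is under-specified in the record and is
supported only as an externally supplied prediction set plugged into the
vote.  Voxel-based morphometry and the consortium's spatial preprocessing
pipelines are out of scope.
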