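# Methods

## Scope and data model

The package quantifies dual-timepoint FET-PET for the tumor-vs-astrogliosis
question at three levels: per-biopsy-sample (point SUVs and TBR features),
per-patient (background reference panels), and per-voxel (delineation
masks). Timepoints are labelled 10 (early, 5–15 min after injection) and 60
(standard, 40–60 min). All SUVs are body-weight-normalized and unitless;
TBRs are ratios of SUVs and therefore invariant to a common calibration
factor, which the test suite asserts.

## Synthetic generator

### Marginal uptake distributions

Published uptake data come as five-number summaries (min, Q1, median, Q3,
max) per tissue class and timepoint. The default marginal model is the
quantile function obtained by monotone PCHIP interpolation through those
five points in (probability, log SUV) space. This choice is exact where the
data are informative — all five printed numbers are reproduced by
construction, draws never leave the printed range — and makes no parametric
claim between the knots beyond monotonicity and log-scale smoothness.

A two-parameter truncated lognormal (`family="lognormal"`) is available as a
cross-check. It is deliberately not the default: a lognormal is
log-symmetric about its median, while several printed rows have
log-asymmetric quartiles (e.g. astrogliosis at 60 min: Q1·Q3 = 1.867 vs
median² = 1.464), so no (μ, σ) can reproduce median and both quartiles
simultaneously; truncating to the printed range additionally shifts the
median when the range is asymmetric (for grade-4 early uptake, from 2.75
down to ≈ 2.39). The closed-form fit μ = ln(median),
σ = ln(Q3/Q1)/(2·z₀.₇₅) is exposed as `fit_lognormal_from_quantiles` and
reproduces the median and interquartile *ratio* exactly.

### Coupling the two timepoints

A sample's early and late SUVs are dependent, but no joint distribution is
published. A multiplicative model (SUV60 = SUV10 × kinetic factor × noise)
cannot match the late marginals: it forces Var(log SUV60) ≥ Var(log SUV10),
which the grade-4 row violates (σ-equivalent 0.38 at 60 min vs 0.51 at
10 min). The generator therefore uses a Gaussian copula: one latent standard
normal per sample drives both timepoints with correlation ρ (default 0.8),
and each timepoint's value is that latent quantile pushed through its own
calibrated marginal. Both marginals are exact; kinetic direction is the
ratio of calibrated medians (rising for astrogliosis, G2, brain, thalamus;
falling for plexus, sinus, G4). ρ = 0.8 encodes strong within-sample
tracking of uptake over 50 minutes; it affects only the joint feature
`module`, not any marginal statistic.

### Composition and missingness

Trajectory probabilities and histology-given-trajectory tables default to
the published cell proportions (total 284; trajectory totals 91/110/11/72;
astrogliosis 54, G2 45, G3 125, G4 60). The cohort had 262 complete cases of
284; which field was missing is not stated, so the generator blanks the
late SUV in an exact count of `round(missing_rate · n)` rows (default
22/284), drawn without replacement.

### Reference panels

Per-patient background values are drawn from the structure distributions at
both timepoints with the same copula. The printed plexus rows are the
structure's defining (maximum-value) measurement; no plexus ROI-mean
distribution is printed, so the panel models plexus mean = 0.85 × plexus
max — a fixed factor chosen so the mean sits close below the max of a small
(0.3–0.6 cm³) ROI, consistent with the early and late published cutoffs
coinciding for the two variants. Mean and max variants of a structure share
one latent draw (comonotone), so max ≥ mean holds by construction.

### Phantoms

The phantom is plumbing, not physics: concentric ellipsoids (core tissue,
default G3; a G2 shell; an astrogliosis shell) inside a FLAIR ellipsoid with
a CE subset, plus spherical plexus/thalamus/sinus/artery structures in the
contralateral half; unlabeled voxels are normal brain. Default grid
64×64×48 at 2 mm isotropic (scanner resolution in the source protocol was
below 4 mm). Each tissue class takes a single value per phantom — the
calibrated median by default, a patient-level draw with
`randomize_tissue=True` — plus additive Gaussian voxel noise (default
SD 0.05 SUV, clipped at zero; no published voxel-noise model exists). Both
timepoints share geometry exactly, standing in for perfectly co-registered
acquisitions. The phantom deliberately omits PET physics (attenuation,
scatter, partial volume, reconstruction), intra-class texture, and irregular
anatomy, so phantom-based results demonstrate the *logic* of the delineation
rules (which tissue compartments each threshold admits), not clinical
performance.

## Geometry conventions

World coordinates are continuous millimetres with the centre of voxel
(i, j, k) at (i+0.5)·voxel_size, 0-based. Sphere VOIs are parameterized by
nominal volume V with r = (3V/4π)^{1/3}; circle ROIs are one voxel-plane
thick (plane axis defaults to axial) with the in-plane radius from
area = V / slice thickness. Point SUVs are nearest-voxel reads without
interpolation; a coordinate exactly between two voxel centres resolves to
the lower index. Named structures validate their nominal volume against the
protocol ranges (brain sphere 10–20 cm³, thalamus 0.5–1 cm³, sinus
0.3–0.8 cm³, plexus circle 0.3–0.6 cm³, artery circle 3–5 mm³). The artery
ROI is below grid resolution by design; the implementation allows it,
emits a warning, and the default placement snaps it to a voxel centre so it
discretizes to one voxel. No partial-volume correction is applied anywhere.

## Features and rules

`tbr_plexus_*` divides by the plexus maximum (the structure's defining
measurement) and `tbr_plexus_roimean_*` by the plexus mean; the decision
tree's late plexus feature is taken as the max variant.
`module = |tbr_plexus_10 − tbr_plexus_60|` is the absolute difference of raw
TBRs, symmetric in the timepoints. Published TBR cutoffs are applied
strictly (>), the thalamus relative cutoffs inclusively (≥), following the
printed symbols. The dual-acquisition rule combines the early (> 1.0) and
late (> 1.2) plexus thresholds with OR — the reading consistent with the
reported sensitivity gain and specificity loss relative to the single late
threshold. In the published tree, a late plexus TBR of exactly 1.77 falls in
the intermediate branch ("between 1.05 and 1.77" read with an inclusive
upper bound), exactly 1.05 falls below it, and the intermediate branch with
module ≥ 3.19 is astrogliosis (the stated complement; the source labels only
the tumor regions).

## CART

Binary recursive partitioning: at each node the (feature, threshold) pair
maximizing the Gini impurity decrease over all features and all midpoints
between sorted distinct values; ties break toward the lower feature index,
then the lower threshold. Stops: pure node, node fraction below
`min_node_fraction` (default 0.05 — a minimum-node-size reading of a
direct-stop rule whose exact original form is proprietary), or `max_depth`.
Per-leaf p-values are Fisher exact tests of class membership in-node vs
out-of-node; they are descriptive and never drive split selection.
Resubstitution cost is the training misclassification rate;
cross-validation cost is the pooled held-out error over V shuffled folds
(default 10) with binomial standard error √(c(1−c)/n); per-fold costs are
retained. Cost-complexity pruning and surrogate splits are out of scope: the
tree-size check is the reported comparison of CV and resubstitution costs.

## ROC and diagnostics

AUC is the Mann–Whitney pair statistic (ties count ½), computed via
midranks; the test suite verifies equality with a brute-force pair count and
with the trapezoid rule over the operating points. The 95% CI uses the
DeLong structural-component variance (a percentile bootstrap is available as
a cross-check, with a coverage test). Candidate cutoffs are midpoints
between adjacent sorted unique scores; the Youden-optimal cutoff maximizes
sensitivity + specificity − 1 with ties broken toward higher sensitivity,
then the lower cutoff. Higher score always means tumor. Predictive values
from published rates use PPV = se·n₊/(se·n₊+(1−sp)·n₋) and
NPV = sp·n₋/(sp·n₋+(1−se)·n₊); printed rates are rounded to two decimals,
so consistency checks propagate a ±0.005 rate interval. Paired AUC
comparison is the DeLong test (normal approximation on the placement
covariance). Contingency percentages are within-column and rounded half-up
to integers, matching the published layout.

## Delineation

Masks are raw threshold contours — no connected-component filtering or
hole-filling. Background scalars always come from the reference panel,
never from inside the candidate region. The CE+2 cm comparator dilates the
CE mask by 20 mm using a Euclidean distance transform with anisotropic
voxel sampling. Mask comparison reports Dice, volumes in ml, and the A\B
volume; two empty masks count as identical.

## Problem sizes and determinism

Calibration checks use 10,000-sample tables and 10,000-patient panels
(medians stabilize well inside the 5% tolerance); oracle equivalence uses
200 random ROC instances (n ≤ 50) and ~20 CART tables (n ≤ 200); the
delineation comparison uses 20 phantom seeds at the default 64×64×48 grid.
Every random quantity flows from a single seed through
`numpy.random.SeedSequence` children; equal seeds give bit-identical
tables, phantoms and reports.

## Known limitations

- Synthetic samples are exchangeable within histology class: no per-patient
  random effects on biopsy SUVs, no spatial correlation along a biopsy
  trajectory, and no dependence of SUV distribution on trajectory beyond
  composition. Patient-level discrimination metrics (AUCs, tree accuracy)
  on synthetic cohorts therefore need not match the published patient-level
  values, and the package does not claim they do.
- The plexus mean-to-max factor is a modeling convention, not a published
  quantity.
- `module`'s distribution depends on the copula ρ, which is unidentified
  from printed marginals; the published tree's constants are applied as
  given, not refit.
- Phantom noise is additive white Gaussian; real PET noise is spatially
  correlated and intensity-dependent.
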