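# Methods

This note documents the models, conventions and design choices behind
`kinhet`, in the spirit of the methods documentation of statistical
packages: what is computed, under which assumptions, with which defaults,
and what the synthetic validation does and does not demonstrate.

## Kinetic voxel classification

Classification uses exactly three phases of the DCE series: pre-contrast
S0, first post-contrast S1, last post-contrast S_last. Two ratio rules
partition the tumor:

* enhancement gate: (S1 − S0)/S0 > 0.50, strict inequality;
* late change r = (S_last − S1)/S1: washout r < −0.10, persistent
  r > +0.10, plateau the closed band [−0.10, +0.10].

Boundary conventions mirror the clinical wording of the gates ("over 50%",
"more than 10%", "within a 10% range"): the gate and the washout/persistent
cutoffs are strict, plateau is closed. The denominator is the earlier
phase of each comparison. Both rules are ratios, so the subregion map is
invariant under any global positive rescaling of the series — this is
asserted by a property test — and classification is deliberately run on
**raw** intensities: an affine z-score map shifts numerator and
denominator differently and would corrupt the ratios. Voxels with
non-positive or non-finite baseline cannot be classified by a ratio rule;
they are excluded and counted in a quality report rather than silently
labeled.

With multiple lesions, only the largest 26-connected cluster of the tumor
mask is analyzed (6-connectivity is configurable). An exact voxel-count
tie is broken toward the component with lexicographically smallest
centroid, with a logged warning; ties are measure-zero in practice but the
rule keeps the pipeline deterministic.

## Kinetic-heterogeneity index

KH = −Σᵢ Pᵢ log₃ Pᵢ with 0·log 0 := 0 over the washout/plateau/persistent
proportions of enhancing voxels. The category count k is **fixed at 3**
regardless of how many components are present: the alternative (k = number
of non-zero components) would score a 50/50 two-component tumor as
maximally heterogeneous (KH = 1), contradicting the convention that ties
KH = 0 to single-component homogeneity with the three-category
normalization left intact. Consequences: KH ∈ [0, 1], KH = 0 iff one
component, KH = 1 iff equal thirds, and a 50/50 mixture scores
log 2 / log 3 ≈ 0.6309. The implementation is checked against an
independent brute-force evaluation to 1e−12 on random simplex points.

Peak enhancement is reported as the **maximum relative rise** (S1 − S0)/S0
over enhancing voxels — a scale-free quantity — and enhanced volume as
foreground voxel count × voxel volume in mm³. Tumors with no enhancing
voxel have an undefined profile and raise an error rather than emitting
zero-filled rows, mirroring the clinical practice of excluding cases whose
CAD output is insufficient. The predominant type is the arg-max proportion
with ties broken toward the more suspicious component
(washout > plateau > persistent); the worst type is the most suspicious
component with non-zero proportion.

## Preprocessing

Images are resampled to isotropic 1 mm voxels with cubic B-spline
interpolation (masks: nearest neighbour), preserving physical extent to
within one voxel. Intensity normalization is a per-patient z-score against
a reference-region (conventionally pectoralis muscle) mean and SD,
rescaled by 100; one shared affine map per patient is applied to every
phase that feeds feature extraction. The fixed discretization bin width of
25 is applied on this rescaled axis — the conventional pairing of a
z-score ×100 normalization with bin width 25. Normalization feeds feature
extraction only, never the kinetic rules (see above). Template
registration, bias-field correction and denoising are out of scope: no
parameters exist to pin them down, and guessed defaults would be worse
than documented absence.

## Radiomic features

The inventory is pinned by construction:
14 shape features + 13 image types × (18 first-order + n_GLCM + 14 GLDM +
16 GLRLM + 16 GLSZM), i.e. **1132** features at n_GLCM = 22 (whole-tumor
preset) and **1158** at n_GLCM = 24 (washout preset). The two GLCM
features dropped in the 22-set are SumAverage (redundant with twice the
joint average of a symmetric matrix) and MCC (the costliest); the
identity of the dropped pair is a configuration decision — the counts are
the contract, and the 22/24 discrepancy between the two ROI
configurations is reproduced, not "corrected".

The image bank is: original; Laplacian-of-Gaussian at σ = 1, 2, 3, 4 mm
(scale-normalized, σ² × response); and the 8 sub-bands of a single-level
3-D stationary wavelet transform (`coif1`), named by the per-axis
low/high-pass combination LLL…HHH. The stationary (undecimated) transform
keeps sub-bands on the input grid so a single ROI mask serves all 13
image types; inputs must be isotropically resampled first.

Discretization is fixed-bin-width (default 25) anchored at the ROI
minimum: level(v) = floor((v − min)/w) + 1. Anchoring at the minimum makes
all texture features invariant to adding a constant to the image, which is
asserted by a test. First-order moments, percentiles and energies use raw
intensities; Entropy and Uniformity use the discretized histogram.
Texture matrices use full 3-D aggregation: GLCM and GLRLM over the 13
unique 26-neighbourhood directions (features averaged across directions),
GLSZM zones and GLDM dependencies on the 26-neighbourhood (dependence
tolerance α = 0). Logarithms are base 2. Shape features are mesh-based
(marching cubes) for volume/area/sphericity, with principal-axis lengths
from the physical-coordinate covariance; on a voxelized ball, sphericity
approaches 1 from below with a staircase-surface deficit of a few percent
at radius ~9 voxels.

ROIs below 10 voxels (configurable) are rejected as degenerate and the
patient flagged, rather than producing unstable texture values.

## Synthetic data

The phantom generator emulates the geometry and kinetics that the
pipeline consumes, not MR physics. Voxel curves are piecewise linear in
phase index: baseline S0, first-post S0(1 + uptake), last-post
first-post × (1 + late_slope), intermediate post phases linear between
them — only the three named phases enter the kinetic rules, so
intermediate shape is immaterial. Default enhancing archetypes (baseline
100): washout uptake 1.0 / late −0.30, plateau 0.9 / 0.0, persistent
0.8 / +0.30 — each well clear of the 50% gate and ±10% band so that the
noiseless phantom is an exact-recovery oracle. Background tissue uses
uptake 0.15, below the gate. Default phantom: 48³ grid at 1 mm, ellipsoid
semi-axes (16, 14, 12) mm ≈ 11,000 tumor voxels, 8 post-contrast phases,
matching a pre + 8-phase clinical acquisition. Noise is additive i.i.d.
Gaussian per voxel-phase; its SD is a free parameter (no cohort noise
model exists to calibrate against), and Rician noise is a non-goal — the
enhancing-tissue regime of interest is high-SNR. Lobulation, when
requested, perturbs the ellipsoid radius by a degree-3 real spherical
harmonic normalized to unit peak amplitude; the perturbation is smooth
and bounded so masks stay connected.

The feature-cohort generator draws standard-normal features with the
first `n_informative` columns shifted by a standardized mean difference
in the positive class. Defaults — 200 patients, prevalence 0.5, 5 of 100
columns informative, effect 1.5 — give the model stage a recoverable but
non-trivial signal. Passing a shared label vector to two generator calls
yields paired "ROI" tables of the same patients with different effect
sizes, which is how the washout-versus-whole-tumor comparison is framed
synthetically: washout features carry effect 1.5, whole-tumor features
none.

What passing tests on these generators shows: the pipeline's rules,
formulas and no-leakage discipline are implemented correctly, and the
model stage detects signal where it exists. What it does not show:
performance on real breast MRI, where noise is structured, classes are
imbalanced, feature correlations are strong, and ROI signal is not
cleanly separable by construction.

## Modeling

The 7:3 split takes round(0.7 n) training patients (124 → 87/37) and is
stratified by outcome by default so small test sets retain both classes.
Screening (training rows only) removes zero-variance columns and, by
default, columns whose two-sided Mann-Whitney test has p ≥ 0.05; every
removal is recorded. The rank filter is configurable because on pure-noise
tables it can legitimately remove everything (by contract this raises an
error); the null-behaviour and paired-ROI validations therefore run with
the rank filter off, which exercises the same LASSO path on the full
column set.

The L1-logistic path uses a 30-point geometric λ grid from λ_max (the
smallest penalty with an all-zero solution) down three decades, 10-fold
stratified CV minimizing mean binomial deviance, and a refit on the full
training set at the winning λ (liblinear solver, seeded; the fit is a
deterministic function of the training values). Features are standardized
to training mean/SD, and the stored transform is applied unchanged at
test time. Radscore = intercept + Σ βⱼxⱼ on standardized features; the
intercept is harmless to ROC/DCA since both are invariant to monotone
maps. Decision curves use the logistic-calibrated probability
σ(Radscore), which for an L1-logistic model is its natural calibrated
probability.

AUC is the Mann-Whitney rank statistic (ties one half) with a
Hanley–McNeil asymptotic 95% CI; the operating point maximizes the Youden
index over observed scores with positives called at score ≥ cutoff.
Univariate kinetic-parameter ROC auto-orients so AUC ≥ 0.5 and records the
flip. Degenerate (constant) inputs are flagged, not errored, at the
evaluation stage.

## Problem sizes and numerical choices

Validation runs use ~11,000-voxel phantoms (exact recovery, proportions
within ±0.02 of specification by the law of large numbers), 1000-point
simplex checks at 1e−12, and 50-seed repetitions for the stochastic model
properties — sizes at which the binomial/CLT error bands in the tests are
comfortably discriminating. Proportion sums are validated to 1e−6;
entropy uses exact 0·log 0 handling rather than an epsilon. The λ grid
floor (1e−3 λ_max) bounds the solver's work on near-separable data;
liblinear tolerance is its default.

## Known limitations

* No real-data validation: the cohort that motivated this pipeline is not
  public, and its reported AUCs are not reproduction targets.
* The kinetic rules use three phases only; full-curve pharmacokinetic
  modeling (Tofts) is out of scope.
* Feature definitions follow IBSI conventions but are an independent
  implementation; numerical agreement with any specific extractor
  binary-for-binary is not claimed, while the inventory counts and the
  analytic limit behaviours are tested.
* The synthetic cohort's features are independent Gaussians; real
  radiomic features are heavily correlated, which typically inflates
  LASSO's selected-set variability.
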