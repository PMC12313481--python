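# kinhet

Intra-tumoral **kinetic-heterogeneity analysis for breast DCE-MRI**: voxel-wise
classification of dynamic enhancement curves into washout / plateau /
persistent subregions, a normalized-entropy heterogeneity index, radiomic
feature extraction from the whole tumor and the washout subregion, and
LASSO-logistic Radscore models of molecular subtype with ROC and
decision-curve evaluation.

The package is aimed at quantitative-imaging researchers who want a tested,
reusable implementation of the subregion ("habitat") workflow used in breast
MRI computer-aided diagnosis. Because clinical DCE-MRI cohorts in this area
are rarely deposited, the package ships a synthetic phantom and cohort
generator with exact ground truth, so every stage is verifiable end to end.

## The method

A DCE acquisition gives each voxel a time–intensity curve: a pre-contrast
value S0, a first post-contrast value S1, and a final post-contrast value
S<sub>last</sub>. Within a delineated tumor:

1. **Enhancement gate** — a voxel is *enhancing* iff (S1 − S0)/S0 > 50%.
2. **Curve typing** — each enhancing voxel is classified by its late relative
   change r = (S<sub>last</sub> − S1)/S1:
   *washout* (code 1) if r < −10%, *persistent* (code 3) if r > +10%,
   *plateau* (code 2) on the closed band |r| ≤ 10%. Washout is the most
   clinically suspicious pattern, persistent the most benign.
3. **Kinetic heterogeneity** — with P = (P₁, P₂, P₃) the voxel proportions of
   the three components among enhancing voxels,

   KH = −Σᵢ Pᵢ · log₃ Pᵢ ∈ [0, 1],  0·log 0 := 0,

   so KH = 0 for a single-component tumor and KH = 1 at equal thirds.
   Peak enhancement (max relative rise), enhanced volume (mm³), and the
   predominant / worst curve types complete the per-tumor summary.
4. **Radiomics** — 14 shape features plus 18 first-order and 68–70 texture
   features (GLCM/GLDM/GLRLM/GLSZM) per image type across a 13-image bank
   (original, 4 Laplacian-of-Gaussian scales, 8 stationary-wavelet
   sub-bands): exactly **1132** features for the whole-tumor configuration and
   **1158** for the washout-region configuration.
5. **Radscore** — stratified 7:3 split; screening and an L1-penalized
   logistic fit on training rows only, with λ at the minimum 10-fold
   cross-validated binomial deviance; Radscore = intercept + Σ βⱼxⱼ,
   evaluated by rank-statistic AUC with Youden-index operating metrics and
   decision-curve analysis (net benefit = TP/n − FP/n · p_t/(1 − p_t)).

## Worked example

```bash
python examples/simulate_and_segment.py
```

```
phantom: 11256 tumor voxels, realized class counts {1: 3395, 2: 3289, 3: 4572}
voxel agreement with ground truth: 100.0%
with noise SD 8 (baseline 100): 96.4% of tumor voxels keep their true class
```

A noiseless phantom is recovered voxel-perfectly because the archetype curves
sit well clear of the 50% gate and the ±10% band; moderate noise misclassifies
only boundary-straddling voxels. The per-tumor summary
(`examples/kinetic_profile.py`):

```
           washout_pct: 0.2575
           plateau_pct: 0.3331
        persistent_pct: 0.4095
 kinetic_heterogeneity: 0.9841
      peak_enhancement: 1.0000
       enhanced_volume: 11256.0000
      predominant_type: 3
            worst_type: 1
```

KH near 1 marks a thoroughly mixed tumor; any washout presence forces
`worst_type = 1` even though persistent voxels predominate. The modeling stage
(`examples/subtype_model.py`) recovers all five informative columns of a
synthetic cohort and generalizes (test AUC 0.999 at effect size 1.5):

```
selected 6 features at lambda = 0.0069
true informative columns recovered: ['feat_0000', ..., 'feat_0004']
train: AUC 0.996 (95% CI 0.985-1.000) ...
test:  AUC 0.999 (95% CI 0.990-1.000) ...
```

A thin CLI mirrors the library for per-patient shell use
(`kinhet simulate | segment | params | features | model`); NIfTI in, NIfTI /
CSV / JSON out.

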