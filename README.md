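# corrdiff

Correlated diffusion imaging (CDI) for multi-b-value diffusion-weighted
MRI, with an apparent-diffusion-coefficient (ADC) baseline, a synthetic
prostate phantom generator, and a voxelwise ROC / cross-validation
evaluation protocol.

## The problem

Prostate cancer is hard to delineate on any single diffusion-weighted
acquisition: depending on how the diffusion gradient pulses are applied,
the signal distributions of cancerous and healthy tissue can overlap
substantially.  Because dense tumour tissue restricts water diffusion,
its signal attenuates *less* than healthy tissue at every diffusion
weighting.  CDI exploits this consistency: instead of characterising a
voxel by the attenuation of one acquisition (or by a fitted decay rate,
as ADC does), it characterises the voxel by the **joint correlation of
signal attenuation across acquisitions**, computed over a small spatial
sub-volume.

## The signal mixing function

An acquisition is indexed by its b-value
`b = γ² G² δ² (Δ − δ/3)` (s/mm²), where `G`, `δ`, `Δ` are the gradient
pulse strength, duration and separation and `γ` is the proton
gyromagnetic ratio.  Given acquisitions `S_i` with b-values `b_i`, a
diffusion range `[q_α, q_β]` and a local sub-volume `V(x)` around voxel
`x`, the CDI signal is the expected product of the in-range signals under
their joint distribution over `V(x)`.  With that distribution realised
empirically, the map is the plug-in estimator

    C(x) = (1 / |V(x)|) · Σ_{x′ ∈ V(x)}  Π_{i : q_α ≤ b_i ≤ q_β} S_i(x′)

Restricted-diffusion (cancerous) tissue keeps all factors of the product
large, so lesions appear hyperintense on `C`; on the ADC baseline
(`ADC(x) = −` OLS slope of `ln S` against `b` over Ω = {0, 100, 1000}
s/mm²) they are hypointense.  Defaults follow the reference protocol:
`[q_α, q_β] = [0, 2000]` s/mm² and a 7 mm³ sub-volume realised at the
map's own voxel spacing.

No patient data ship with the package.  The phantom module generates
prostate-like volumes — an ellipsoidal gland (D = 1.5 × 10⁻³ mm²/s)
holding spherical lesions with restricted diffusion
(D = 0.7 × 10⁻³ mm²/s), mono-exponential decay per tissue, Rician
magnitude noise at SNR 20 — so the whole pipeline is testable end to end
with known ground truth.

## Worked example

```
$ corrdiff phantom generate --seed 7 --out-dwi dwi.nii.gz \
      --out-bval dwi.bval --out-labels labels.nii.gz
$ corrdiff cdi compute --dwi dwi.nii.gz --bval dwi.bval --out cdi.nii.gz
$ corrdiff adc compute --dwi dwi.nii.gz --bval dwi.bval --out adc.nii.gz
$ corrdiff evaluate roc --scores cdi.nii.gz --labels labels.nii.gz --out roc_cdi.csv
INFO corrdiff: Az=0.9994 empirical AUC=0.9997 separability=10.6639
$ corrdiff evaluate roc --scores adc.nii.gz --labels labels.nii.gz --negate --out roc_adc.csv
INFO corrdiff: Az=0.9983 empirical AUC=0.9998 separability=8.6211
```

The phantom is a 64 × 64 × 16 grid at the study-median resolution
(1.56 × 1.56 × 3.5 mm) acquired at b = {0, 100, 1000, 2000} s/mm².
`evaluate roc` pools the gland voxels (here 134 cancer, 8273 healthy),
fits a Gaussian to each class and reports the binormal ROC area
A_z = Φ(a/√(1+b²)), the nonparametric (Mann–Whitney) AUC as a
cross-check, and the Fisher separability ratio
(μ₁−μ₀)²/(σ₀²+σ₁²).  ADC scores are negated (`--negate`) so that higher
always means more cancer-like.  On this phantom CDI separates the lesion
from the gland slightly better than the ADC baseline by binormal A_z
(0.9994 vs 0.9983) and clearly better by Fisher separability (10.7 vs
8.6).  `evaluate loocv` additionally runs the two-class Gaussian
maximum-likelihood voxel classifier under leave-one-out cross-validation
over a manifest of cases and reports per-fold and pooled sensitivity,
specificity and accuracy.

All map outputs carry a JSON provenance sidecar (map kind, b-range or Ω,
neighborhood, source checksum).

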