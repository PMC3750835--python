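# Methods

## Signal model and the CDI estimator

Each acquisition of a multi-b-value DWI stack is a magnitude volume
`S_i(x)` with diffusion weighting `b_i = γ²G_i²δ_i²(Δ_i − δ_i/3)`
(s/mm²; γ is the CODATA proton gyromagnetic ratio,
2.6752218744 × 10⁸ rad s⁻¹ T⁻¹ — the acquisition module computes this
relation in SI units and converts at the API boundary only).  Scanners
report b-values rather than raw pulse parameters, so b-values are the
primary interface throughout and the pulse-parameter relation (with its
closed-form inverse for the gradient strength) is supporting math.

The correlated diffusion image is defined as the expectation of the
product of the in-range signals under their conditional joint
distribution over a local sub-volume `V(x)`.  That definition leaves the
estimator open; we use the plug-in estimator that takes the joint density
to be the empirical distribution of the signal vectors over `V(x)`:

    C(x) = (1/|V(x)|) Σ_{x′∈V(x)} Π_{i∈I} S_i(x′),
    I = {i : q_α ≤ b_i ≤ q_β}

This is the only computation consistent with the printed definition that
requires no further modelling assumptions.  Raw signals enter the
product by default; a normalise-by-b0 switch (divide each signal by the
voxel's mean b = 0 signal before mixing) is available and recorded in
provenance.  Products are computed directly in float64 — with the
typical |I| ≤ ~8 acquisitions and clinical signal scales this is far
from overflow, so no log-domain path is needed.

**Boundary handling.** `V(x)` is an axis-aligned box clipped at the
volume edge and averaged over the in-bounds count.  Padding would
fabricate signal outside the imaged volume; clipping does not.

**Implementation.** The box sum is computed by summation over a
zero-padded sliding window view, divided by the exact analytic in-bounds
count per voxel.  This reproduces a direct nested-loop evaluation to
float64 round-off (the tests compare against such an oracle at
1 × 10⁻¹⁰ relative tolerance, boundaries included).

## The sub-volume and its voxel realisation

The reference protocol assesses a 7 mm³ sub-volume.  The wording is
ambiguous between a volume of 7 mm³ (cube side 7^{1/3} ≈ 1.91 mm) and a
7 mm-sided cube (343 mm³); both readings are expressible through
`NeighborhoodSpec`, along with explicit per-axis voxel half-widths.

A physical extent is converted to half-widths per axis as the smallest
integer `h` whose spanned box `(2h+1)·spacing` covers the extent — the
centre voxel's own extent counts, so at 3.5 mm slices a 1.91 mm box is
covered by a single slice (`h = 0`).

The package default is the **7 mm³ volume reading realised at the map's
own spacing** — at the reference spacing of (1.56, 1.56, 3.5) mm this is
a single-slice 3 × 3 in-plane neighborhood.  A fixed 3 × 3 × 3 voxel
cube was considered and rejected as a default: with anisotropic clinical
spacing it spans 10.5 mm through-plane, an order of magnitude more
tissue than the stated sub-volume, and measurably smears small lesions
across slices (on the reference phantom it costs CDI its delineation
advantage over ADC precisely at the 4–6 mm lesion scale).  A voxel-cube
neighborhood remains available as an explicit option.

## ADC baseline

Per voxel, an unweighted ordinary-least-squares fit of `ln S` against
`b` over the acquisitions matching Ω (default {0, 100, 1000} s/mm²,
matched to stack b-values within 10⁻⁶); ADC is the negated slope clamped
below at zero.  Unweighted OLS is standard clinical practice for 2–3
b-values; weighted variants are out of scope.  Both the b-values and the
log-signals are centred before the slope computation so a constant
signal yields exactly zero.  Nonpositive signals (possible under noise)
are floored at 10⁻⁶ × the stack maximum and counted in provenance.

## Synthetic phantom

The phantom emulates a prostate-like scene: an ellipsoidal gland of
healthy tissue containing spherical lesions, in a fluid-like background.
Geometry is specified in millimetres against voxel-centre coordinates,
labels are rasterised crisply (each voxel belongs to exactly one
tissue), each tissue decays mono-exponentially, and the observed signal
is Rician: `sqrt((S+ε₁)² + ε₂²)` with independent zero-mean Gaussians of
scale `noise_sigma`, drawn from a generator seeded by the spec — so
identical specs give bit-identical output.

Reference phantom parameters (units, value, rationale):

| parameter | value | why |
|---|---|---|
| grid | 64 × 64 × 16 voxels | covers the gland with margin at modest cost |
| spacing | (1.56, 1.56, 3.5) mm | study-median DWI resolution |
| b-values | {0, 100, 1000, 2000} s/mm² | spans the ADC set Ω and the CDI range endpoint |
| healthy D | 1.5 × 10⁻³ mm²/s | literature-typical peripheral-zone diffusivity |
| cancer D | 0.7 × 10⁻³ mm²/s | restricted diffusion; typical tumour range |
| background D, S0 | 3.0 × 10⁻³ mm²/s, 150 | fluid-like: fast decay, low baseline |
| S0 (gland & lesion) | 1000 (equal) | contrast carried by D alone; neutral choice |
| lesions | spheres r = 4 mm and 6 mm | clinically small foci, the hard case |
| noise | σ = S0/20 (SNR 20 at b = 0) | realistic clinical echo-planar SNR |

What the phantom does **not** emulate: within-tissue heterogeneity
(voxels sharing a label have identical noiseless signal), partial-volume
mixing at tissue boundaries, zonal anatomy, perfusion (IVIM) and
kurtosis effects, coil profiles, motion and eddy-current artefacts.
Consequences for interpretation: per-voxel ADC on homogeneous tissue
with crisp labels is close to a best case for the baseline, and the
absolute A_z values on the phantom (≈ 0.999 for both maps) are far above
what heterogeneous clinical tissue yields; passing tests demonstrate
correctness of the computations and the direction of the CDI-vs-ADC
comparison, not clinical effect sizes.

## Evaluation protocol

Cancer is the positive class everywhere.  CDI maps enter as-is (lesions
hyperintense); ADC maps are negated first (lesions hypointense), so
higher always means more cancer-like; orientation is never auto-flipped.

**Binormal ROC.** Class-conditional Gaussians are fitted by sample
moments (mean, SD with n−1 denominator), giving intercept
`a = (μ₁−μ₀)/σ₁`, slope `b = σ₀/σ₁` and area
`A_z = Φ(a/√(1+b²)) = Φ((μ₁−μ₀)/√(σ₀²+σ₁²))`.  Moment matching was
chosen over ROC-curve maximum likelihood for determinism and exact
testability; the curve is sampled at ≥ 201 FPR points through
`TPR = Φ(a + b·Φ⁻¹(FPR))`.  The nonparametric empirical AUC
(Mann–Whitney, ties half; via scikit-learn) is always reported alongside
as a model-free cross-check.

**ML classifier and LOOCV.** Per-class Gaussians are fitted to voxel
intensities pooled unweighted across training cases
(maximum-likelihood: biased-denominator SD); classification compares
likelihoods without priors, ties resolving to healthy.  A relative SD
floor of 10⁻¹² × (|class mean| + 1) keeps degenerate constant-valued
fixtures evaluable; flooring is logged.  Leave-one-out cross-validation
holds out each case once; pooled metrics come from summed confusion
counts, so they are exact rationals of the counts.

**Separability.** The tissue-class separability statistic is the Fisher
ratio `(μ₁−μ₀)²/(σ₀²+σ₁²)` with population variances — a standard,
parameter-free choice for two-class contrast; other separability
measures would serve equally and none is canonical.

Evaluation operates at voxel level, consistent with the voxel-based
classifier; region-level aggregation is future work.

## Problem sizes

The test suite and the acceptance script run at desk scale: CDI oracle
comparisons on random stacks up to 12 × 12 × 6 × 4; Gaussian ROC checks
at 10⁴ samples per class; phantom studies on 10 seeded 64 × 64 × 16
cohorts (~8.4 × 10⁴ gland voxels pooled).  The entire suite completes in
a few seconds on one CPU.

## Known limitations

- The phantom's homogeneous tissues make absolute performance numbers
  optimistic for both maps (see above).
- The CDI map's value scale is the product of |I| signal intensities and
  is therefore acquisition-dependent; only comparisons within a
  consistent protocol are meaningful.  Display windowing is out of scope.
- The number and spacing of acquisitions inside the diffusion range is
  protocol-dependent; the package accepts any set and records it in
  provenance rather than prescribing one.
- Gradient-direction handling (.bvec) is intentionally absent: the
  method uses pulse strength/timing, and volumes are assumed
  direction-averaged (trace-weighted) per b-value.
- DICOM, scanner control and visualisation platforms are out of scope.
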