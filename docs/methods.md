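# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the open design decisions behind
tremornet. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

A `BrainMap` is a real-valued 3-D volume restricted to an analysis mask
on an axis-aligned grid (world coordinate of voxel (i,j,k) =
origin + index·voxel size). Rotated or sheared NIfTI affines are rejected
at read time rather than silently resampled: all maps in a study are
assumed co-registered to one template space, and keeping the coordinate
arithmetic affine-free makes every geometric operation exactly testable.

Preprocessing operators:

- **Intensity normalization** divides by the mean over a reference
  (brain-parenchyma) mask, so the reference mean is exactly 1 afterwards.
  The operator is idempotent. The parenchyma mask is accepted as a
  separate input from the analysis mask; nothing forces them to coincide.
- **Gaussian smoothing** is a separable convolution with
  σ = FWHM/(2√(2 ln 2)) per axis, converted to voxel units by the grid's
  voxel size. Out-of-mask voxels enter as zero and the output is
  re-masked, with no mask-weighted renormalization — the common
  neuroimaging convention; near the mask edge smoothed values are
  therefore attenuated, and tests that rely on kernel-sum preservation
  use interior signal only.
- **Block resampling** to an integer multiple of the voxel size averages
  the in-mask voxels of each block; the output voxel is in-mask iff at
  least half its block is. Non-integer ratios are rejected (no
  interpolation — a deliberate restriction that keeps block means exact).
- **Mirroring** about the midsagittal plane x = 0 is a rigid reflection,
  not a nonlinear warp: `left_to_right_bilateral` fills the empty
  hemisphere from the reflection; `average_to_left` averages each
  left-hemisphere voxel (world x < 0; x = 0 belongs to neither
  hemisphere) with its partner, mask-aware. Grids whose reflection does
  not map voxel centers onto voxel centers are rejected. The composition
  bilateral → average-to-left is the identity on left-only maps.

## Voxel-wise inference

The one-sample test on difference maps flips the sign of whole subject
maps: at each voxel t = mean/(sd/√n), and the FWE-corrected p of a voxel
is the fraction of permutations whose maximum statistic over the mask
reaches that voxel's observed statistic. When 2ⁿ ≤ n_perm all sign
patterns are enumerated, making the test exact, deterministic, and
seed-independent (n = 14 → 16,384 patterns); otherwise patterns are
sampled with the identity always counted, so p ≥ 1/n_perm. Voxels with
zero variance across subjects have no defined t; they are removed from
the inference mask and reported. Within a permutation, a zero-variance
voxel with nonzero mean yields t = ±∞, which only inflates the null
maximum (conservative). No TFCE or cluster enhancement is applied at
this stage; cluster inference lives in the connectivity GLM. Perfect
voxel fits in the regression variant (r² = 1) are capped at |t| = 1e8 so
maps stay finite; the p-ordering is unaffected.

## Spatial-null similarity (Moran spectral randomization)

Two smooth brain maps share large-scale spatial structure by
construction, so the naive permutation test that shuffles voxels —
destroying autocorrelation — wildly overstates significance. The MSR
test keeps it: spatial weights w_ij = 1/d_ij² between in-mask voxel
centers (mm), the eigenbasis of the doubly-centered weight matrix
(computed inside the orthogonal complement of the constant vector via a
Helmert rotation, so eigenvectors are exactly orthonormal and centered),
and **singleton** surrogates that keep the magnitude of the observed
map's loading on every eigenvector while randomizing only the signs.
Singleton surrogates preserve Moran's I exactly and the mean/variance up
to floating point (an explicit re-standardization pins them down).
p = (#{surrogate ρ ≥ observed ρ})/n_surr, ties counting toward the null;
a zero count is reported as the upper bound 1/n_surr with a flag, never
as p = 0. The default tail is one-sided (similarity); both the tail and
the tie rule are recorded in the serialized result. Weights are
unstandardized and symmetric (no row normalization), and the variant
name is stored for provenance.

The observed correlation is identical whichever side is permuted; the
p-values generally differ, so paired reporting (surrogates of each map in
turn) is built in. The dense eigenbasis is cubic in voxel count, so the
pipeline block-resamples maps entering MSR to 8 mm by default and caches
the basis per support; `build_weights` refuses masks above a configurable
cap (10,000 voxels) with advice to resample. The p-value is *not* exactly
invariant to monotone transforms of the permuted map (surrogates operate
on values); it is invariant for transforms of the non-permuted map, and
ρ is invariant for both — the test suite pins down exactly this.

## Alignment and outcome models

A patient's alignment is the Spearman correlation (primary) or the
unnormalized voxel product-sum (robustness metric) between their change
map and the template over the template's nonzero voxels — exact zeros
only, no magnitude threshold. Scores are z-scored across the cohort with
the sample (n−1) SD. Improvement is regressed on alignment z with OLS,
with stimulation amplitude (per patient: mean of the two hemispheres) as
covariate; the covariate-free model is always attached. The cohort-level
"average relative reduction" is reported both as the mean of per-patient
percentages and as the group-mean ratio, labeled. Confound screening
reports univariate Pearson associations, variance-inflation factors from
the all-parameter model, and joint-model partial tests at α = 0.05, with
no multiplicity correction across the small set of clinical models.

A subtlety the tests encode: with zero noise every change map is an
exact positive rescaling of the template, so the *rank* metric saturates
at 1 for all patients and carries no ordering; only the product metric
recovers the planted gain ordering exactly in the noise-free limit. The
parameter-recovery study therefore uses the product-sum metric (linear
in the planted gain) and checks the rank metric's positive association
separately. Two residual biases of order 2–3% affect the recovered
coefficient — the sample-SD z-scoring factor E[s] < 1 at n = 14 and
attenuation from map noise — and both sit inside the 2-SE Monte-Carlo
band asserted over 50 cohorts.

## Connectivity GLM and cluster correction

Signed connectivity maps are split exactly into positive and negative
parts (zeros belong to both as zeros; the parts sum to the original).
Per voxel, OLS across patients of Δᵢ(v) on intercept, conn⁺ᵢ(v),
conn⁻ᵢ(v) and demeaned amplitude — a fixed-effects model, since one
observation per patient supports no random effects. A connectivity
predictor that is zero for all patients at a voxel is dropped there and
recorded in a support mask; fits are batched by support pattern.

Cluster correction replaces random-field theory with permutation:
|t| above the two-sided t-quantile for the cluster-forming p (default
0.001; configurable) forms clusters under 26-connectivity (configurable
to 6), and the null of the maximum cluster extent (or mass) comes from
permuting the nuisance-residual space. The scheme is **Huh-Jhun**: per
voxel the data are rotated into an orthonormal basis of the reduced-model
residual space, where the n−q rotated observations are exchangeable under
normal errors, and the rotated vector is permuted. Plain Freedman-Lane
(permuting raw reduced-model residuals) double-projects the residuals
and was measurably conservative in the deep tail at n = 14/df = 10 in
this package's own null studies; the rotation restores nominal
family-wise error, which the acceptance study verifies over 200 null
replicates. The identity permutation is counted, so cluster p ≥ 1/n_perm.

## Simplified OrT/CVA

The covariance-pattern analysis is a documented simplification, defined
by this package rather than by reference software: (1) within-subject
centering of the 2n stacked maps, so condition contrasts drive the
decomposition; (2) PCA, keeping the first 5 spatial components
(a priori); (3) combining weights w ∝ S_d⁻¹·mean(d) over the
component-space On−Off differences d — the closed-form unit-norm
maximizer of the paired t of projected differences, with a ridge
fallback (1e-8·trace jitter, flagged) if S_d is singular; (4) the voxel
pattern normalized to unit norm, sign fixed so mean projected On−Off
difference is positive; (5) ordinal violations = subjects whose On
expression does not exceed their Off expression; (6) bootstrap over
subject *pairs* (100 iterations by default), sign-aligned to the point
estimate, giving per-voxel z = weight / bootstrap SD. Expression is
defined on the raw condition maps, so only expression *differences* (and
the pattern itself) are invariant to adding a subject-constant map; the
test suite asserts exactly that. No Monte-Carlo significance of the
ordinal trend is computed; the pattern is validated by MSR similarity
against the univariate t-map.

## Synthetic cohort generator

The generator defines the study conditions for all recovery and
calibration work. Defaults: n = 14 patients on a 24×28×24 grid at 4 mm
(≈ 8,500 in-mask voxels inside an ellipsoidal "brain" mask), chosen so
the dense Moran eigenbasis of any MSR support fits comfortably in
memory. The planted template network has bilateral positive
motor-cortical and cerebellar hubs and negative frontal and occipital
regions, smoothed at 8 mm; after smoothing, values below 1% of the peak
are zeroed so the "nonzero template" support stays hub-local (a Gaussian
tail would otherwise make every voxel nonzero). Per patient:

    off = baseline + s_i·T + ε_off
    on  = off + a_i·c_L·L + g_i·c_T·T + ε_on

with T the template, L a unit-peak Gaussian kernel (6 mm FWHM) at the
bilateral stimulation loci, ε Gaussian random fields smoothed to 8 mm
and rescaled to SD 0.05 on the normalized-uptake scale (≈ 5% of mean
uptake), c_L = 0.02 per mA (amplitudes uniform on 1.5–4.5 mA → 3–9%
local change), c_T = 0.05 per unit gain, and g_i ~ N(1, 1) — a cohort
that on average engages the network, so the group t-map shows the
template. Clinical couplings: trs_off = 8 + 130·s_i + η (η SD 1.5,
s_i ~ N(0.05, 0.02)), improvement = 50 + 15·g_i + η′ (η′ SD 12, i.e.
mean improvement 65% with a 33–100% spread like the study cohort;
univariate alignment-improvement R² ≈ 0.5–0.6), trs_on =
trs_off·(1 − improvement/100) floored at 0 — the floor censors
improvements above 100%, which is why noise-free identity tests select
seeds without censoring. VTAs are spheres at the stimulation loci with
radius 3 + 1·a_i mm; connectivity maps are the template plus smooth
patient noise (SD 0.1). All randomness flows through named per-patient
substreams of `SeedSequence(seed)`, recorded in the ground-truth record;
cohorts are bitwise reproducible.

What the generator does **not** emulate: PET count statistics and
scanner PSF, attenuation, nonlinear anatomy, FTM-TRS integerness
(scores are continuous; rounding is a config flag), finite-element VTA
geometry, and the covariance structure of a real normative connectome
beyond "template + smooth noise". Passing recovery tests therefore show
that the estimators recover the planted generative structure at
realistic noise levels — not that real PET data satisfy that structure.

## Validation studies and problem sizes

`tremornet.validation` packages the simulation studies the acceptance
script and test suite run: MSR calibration uses 200 replicate pairs of
independent 8 mm fields on a ~2,400-voxel 4 mm mask with 500 surrogates
per test (the shuffle baseline is run on the same data); sign-flip FWE
uses 500 null cohorts of n = 14 with exhaustive enumeration on a
~1,100-voxel mask; coefficient recovery uses 50 default-condition
cohorts; cluster studies use 20 effect and 200 null replicates with 200
permutations each. These sizes put the whole battery at a few minutes on
one core while leaving binomial confidence bands tight enough to detect
miscalibration.

## Known limitations

- Axis-aligned geometry only; no nonlinear registration, so the
  "mirroring" of lateralized templates is rigid.
- Dense spatial weights limit MSR supports to ~10⁴ voxels; resample
  first (the pipeline does this automatically).
- The permutation machinery assumes exchangeable (sign-flip: symmetric;
  Huh-Jhun: spherical) errors across subjects at each voxel.
- With one observation per patient the connectivity GLM cannot separate
  within- from between-patient connectivity effects.
- The OrT/CVA variant is not the reference implementation; its
  combining rule is this package's definition.
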