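# Methods

This note documents the models, algorithms and numerical choices behind
`petidif`, and what the synthetic validation does and does not establish.

## Problem setting

Kinetic quantification of TSPO-tracer PET in the mouse has no valid
reference region (TSPO is expressed in healthy brain, blood cells, vessels,
heart and lung) and arterial sampling is impractical at mouse blood volumes.
The package therefore estimates the arterial input function directly from a
dynamic whole-body scan and uses it for voxel-wise estimation of the total
volume of distribution, V_T.

## Constrained factor analysis and the IDIF

The dynamic image is modelled as

    S_i(t) = Σ_k a_k(i) f_k(t) + e_i(t),

with nonnegative factor curves `f_k` and factor images `a_k` (constraint
P1).  The blood factor must be unimodal with its maximum in the frame
spanning 30–60 s (P2) — a 1-min pump injection makes the vascular peak land
there reproducibly.  In tracer-dose mode a fourth factor absorbs specific
binding and the blood factor is softly shrunk toward a template derived
from presaturation (blocked-binding) scans (P3), which protects the IDIF
from tracer bound to blood and vessel TSPO.

Solution scheme:

1. **Subspace.**  Uncentered PCA of the masked voxel×frame matrix.  Three
   components are the canonical choice for the 3-factor presaturation mode;
   a K-factor model is given a max(3, K)-dimensional subspace, since K
   linearly independent factors cannot be represented in fewer dimensions.
2. **Initialisation.**  K-means (k-means++, 10 restarts, fixed seed) on the
   projected voxels.  Each centroid is then sharpened to its cluster's
   *apex*: the member (above a noise floor of 25 % of the cluster's maximum
   norm) furthest, relative to its own norm, from the span of the other
   centroids.  Centroids are averages of mixed voxels and therefore sit
   inside the data cone; apexes approximate its extreme rays — the purest
   expression of each physiological signal.  This apex-seeking step is what
   makes the factorisation identifiable: with all sources strictly positive
   in time, nonnegativity alone does not pin down the decomposition.
3. **Refinement.**  Alternating (a) exact per-voxel nonnegative least
   squares for the images — solved in closed form by enumerating the ≤ 2^K
   coefficient supports, vectorised over voxels; (b) least-squares
   re-estimation of the curves within the PCA subspace; (c) projection onto
   the constraints: nonnegativity clip, P2 projection of the blood factor
   (pool-adjacent-violators isotonic regression on each side of the peak
   frame), and P3 shrinkage `f ← (1−λ) f + λ·template` with the template
   rescaled to the factor's L2 norm, λ = 0.5.  Iteration stops when no
   factor changes by more than 1e-4 relative L2, when the fit residual
   stops improving (relative gain < 1e-5 three times in a row), or after
   200 iterations.  The residual-plateau rule matters: the split of the
   slowly-decaying tail between the blood and free factors is only weakly
   determined by the data, and without it the blood tail random-walks along
   a residual-flat direction on noisy data.
4. **Blood factor.**  Identified before refinement as the initial factor
   with the smallest relative L2 distance to its own P2 projection (ties go
   to the earlier peak), and then re-seeded directly from the data: the
   mean TAC of the most P2-feasible hot voxels (subspace-denoised).  A
   blood pool of a few hundred voxels does not always earn its own K-means
   cluster; the re-seed makes the blood initialisation independent of the
   clustering outcome.

Scale convention: factor images are normalised to unit maximum, curves
carry the amplitude (so a factor curve reads as the TAC of its strongest
voxel).  Calibration compares the summed factor reconstruction with the
whole-body TAC (in Bq) and applies the mean frame-wise ratio from 10 min
onwards — where the ratio is stable — to the blood factor curve.  The
ratio anchors to the total image signal and the curve to the strongest
blood voxel, both stable quantities; the blood factor's image-weight total
deliberately does not enter the amplitude, because how the unmixing
distributes small vascular coefficients across thousands of tissue voxels
varies between runs.  The calibrated curve is therefore proportional to
delivered activity and consistent across animals, at an overall scale set
by the whole-body bookkeeping (a partial-volume-afflicted proxy for
absolute blood activity — downstream V_T and dose-linearity need
consistency, not absolute Bq).

The calibrated curve can be fitted with a linear-rise + tri-exponential
model (weighted by frame duration, multi-start over three log-spaced rate
triplets) and metabolite-corrected with a population parent-fraction table.
The shipped table is a synthetic placeholder with a typical TSPO-tracer
shape and is meant to be replaced by a measured population curve.

## Basis-pursuit V_T and 4D resolution recovery

Twelve basis TACs are built by convolving the parent-plasma input with
exponentials at rates log-spaced from 1/(2·scan duration) to 1/(10 s)
(slower than the scan can resolve up to quasi-instant equilibration),
computed on a 1 s grid with the same recursion the phantom simulator uses,
then frame-averaged.  Each voxel TAC is fitted by weighted nonnegative
least squares over the basis plus a fractional-blood-volume column (the
input itself), with an optional L1 penalty expressed relative to the TAC's
own λ_max; the default λ = 1e-4 keeps the fit essentially unpenalised (the
nonnegativity constraint and the 13-column model already regularise
heavily) while exposing true basis pursuit through larger values.  The
penalised problem is reduced to plain NNLS against a shifted target, so
both paths share one exact solver.  V_T = Σ_j φ_j/θ_j over the exponential
columns; the blood column is excluded.

Resolution recovery is Van Cittert deconvolution against the denoised data
with α = 1 and nonnegativity clipping, using an isotropic Gaussian PSF
specified by its FWHM in mm; each round deconvolves then re-fits (denoises)
the iterate, and the V_T map is taken from the final fit.  Iteration 0
means denoise + V_T only.  A divergence detector aborts if the
deconvolution residual grows over three consecutive rounds.

Known model limits: the basis family does not span pure accumulation
(excretion-dominated voxels, effectively θ → 0) nor the raw vascular peak
beyond the blood column, so whole-image fit residuals concentrate in the
bladder and large vessels.  Within the model class (one- and two-tissue
kinetics with rates inside the θ range) restoration is accurate to well
under 1 %.

## Quantification

%ID/cc maps are duration-weighted mean concentration over a window
(default: the last 30 min of the scan) times 100/injected dose.  Regional
summaries use the seven-region scheme (left/right hippocampus, cortex,
thalamus; whole cerebellum).  Correlations against reference binding are
Pearson R with the two-sided t-distribution p-value (n−2 df), a Fisher-z
95 % CI and conventional significance stars; no multiple-testing
correction is applied, matching how such regional correlations are
conventionally reported.

## The phantom generator

Every voxel TAC is a nonnegative mixture of four temporal sources — blood
(the input itself), free tracer (input ⊗ exp, k2 = 0.5/min), specific
binding (input ⊗ exp, k2 = 0.1/min) and excretion (running integral of the
input) — over labelled solids: body background, lungs, heart blood pool,
aorta, kidneys, muscle, bladder and a seven-region brain.  The free and
specific sources are normalised so that a region's mixing weight equals its
V_T contribution (w = K1/k2), making analytic V_T bookkeeping exact:
V_T = w_free + w_specific.  The input model is a linear rise to a peak at
45 s (1-min pump injection) followed by a tri-exponential decay; the peak
amplitude scales with injected dose (0.4 cc⁻¹, i.e. a ~2.5 cc effective
early distribution volume).  The image is blurred by an isotropic Gaussian
PSF (default FWHM 1.6 mm, typical of a small-animal tomograph) and degraded
with Gaussian noise of variance proportional to activity/(frame duration);
the default noise scale gives roughly 10 % relative noise in tissue at
mid-scan activities, a realistic level for iteratively reconstructed mouse
PET.  All randomness is seeded.

Design choices worth flagging:

* **Near-pure pockets.**  Each source has a region where it dominates
  (aorta ≈ blood, muscle ≈ free, sclerotic hippocampus ≈ binding,
  bladder ≈ excretion).  This is the spatial-exclusivity premise the factor
  model itself rests on, and it is what makes exact source recovery
  testable; in its absence the nonnegative decomposition of strictly
  positive curves is not unique and no algorithm could recover the truth.
* **Factor-recovery fixture.**  Source-separation accuracy is scored on the
  unblurred, noiseless phantom: PSF blur leaves voxel TACs exact mixtures
  (so FA residuals stay near zero) but removes pure voxels, which bounds
  achievable curve purity; resolution loss is the deconvolution stage's
  problem, not the factor model's.
* **Longitudinal cohort.**  The quantification study renders four disease
  stages, three animals each (binding peaking early after the insult, then
  partially normalising), with stage-dependent systemic clearance (input
  decay rates scaled 0.9–1.1 per stage, ±5 % per animal) and
  injection-delivery scatter: the activity reaching the blood differs from
  the recorded dose (15 % SD here; real IDIF-peak-vs-dose correlations
  near 0.8 imply ~20 %).  Pooling stage × region group means (7 × 4 = 28
  points) is the design under which input-normalised V_T outperforms %ID:
  %ID inherits each animal's delivery and clearance scale, V_T measures
  its input from the image.  The controlled dose-linearity cohort uses 5 %
  delivery scatter (bench conditions) and spans a 3× dose range.

What the phantom does **not** emulate: sinogram-level (Poisson) noise and
reconstruction artefacts, scatter/randoms, motion, anatomical realism
beyond labelled solids, metabolite kinetics (parent fraction is unity in
phantom studies), spatially variant PSF, and continuous kinetic
heterogeneity within regions.  Passing tests therefore demonstrate
correctness and robustness of the algorithms under controlled conditions,
not clinical-grade performance on scanner data.

## Numerical choices

* Convolutions on a 1 s grid via the exact recursion
  `c[n] = e^{−rθ dt} c[n−1] + dt·x[n]`; simulator and fitter share the
  implementation, so on-grid rate recovery is exact to machine precision.
* Frame values are time-averages over each frame; all curve operations use
  frame mid-times.
* Images are assumed decay-corrected to injection time and co-registered;
  the toolkit neither decays nor resamples.
* scipy's active-set NNLS is the workhorse; on noisy, highly collinear
  designs it can cycle, in which case the bounded BVLS solver takes over.
* Degenerate inputs: all-zero TACs fit to zero; empty masks, zero-variance
  correlations, non-contiguous frame schedules and unit mismatches raise
  immediately with a message naming the offending quantity.

## Problem sizes

The shipped phantom is a 20×20×40 grid (1 mm voxels, ~9,200 body voxels)
with the 24-frame, 61.5-min reference framing — small enough that the
entire validation study (template construction, 20-phantom identification
study, 12-animal dose cohort, 12-animal longitudinal cohort, 15-iteration
resolution recovery) runs on one CPU core in minutes, while leaving every
stage's statistical behaviour observable.

## V_T scale conventions

Basis functions are built from the input at plasma-concentration scale:
`InputFunction.as_concentration()` undoes the whole-body calibration and
returns the blood factor at its native strongest-voxel scale (a Bq/cc
proxy), so V_T maps land near their physical mL/cc value.  Two biases
remain and are visible in the worked example: the blood pool's
partial-volume recovery (< 1) inflates V_T uniformly, and the estimated
input tail sits ~10 % below truth (the blood/free tail split is weakly
identified), inflating it further — together roughly +15 % on this
phantom, uniform across regions and animals, which is why regional
correlations are unaffected.
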