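# petidif

Image-derived input functions and kinetic quantification for dynamic
whole-body small-animal PET.

## The problem

Quantifying TSPO-tracer binding (a neuroinflammation marker) in the mouse
brain has no easy normaliser: TSPO is expressed in healthy brain tissue, on
blood cells, in vessel walls, heart and lung, so there is neither a valid
reference region nor a clean vascular ROI, and arterial blood sampling is
impractical at mouse blood volumes.  `petidif` implements a quantification
chain that needs neither:

1. **Image-derived input function (IDIF) by constrained factor analysis.**
   The whole-body dynamic image is decomposed as
   `S_i(t) = Σ_k a_k(i) f_k(t) + e_i(t)` with nonnegative factor images
   `a_k` and curves `f_k` (P1), a blood factor forced to a single early
   vascular peak in the 30–60 s frame (P2), and — for tracer-dose scans — a
   similarity constraint toward a template derived from presaturation
   (blocked-binding) scans (P3).  The blood factor is calibrated to Bq
   against the whole-body TAC, fitted (linear rise + tri-exponential
   decay) and metabolite-corrected with a population parent-fraction curve.
2. **4D resolution recovery and denoising (4D-RRD).**  Voxel TACs are
   fitted with a sparse nonnegative combination of basis functions
   `b_j(t) = (C_p ⊗ e^{−θ_j t})` (12 log-spaced rates plus a blood-volume
   column); Van Cittert deconvolution against the denoised data recovers
   resolution lost to the scanner PSF.  The total volume of distribution
   follows from the fitted coefficients: `V_T = Σ_j φ_j/θ_j`.
3. **Regional quantification.**  %ID/cc maps and V_T maps are summarised
   over a seven-region brain scheme and correlated (Pearson R, t-test
   p-values, Fisher-z CIs) against reference binding values.

A synthetic whole-body mouse phantom generator (blood pool, lungs, kidneys,
muscle, bladder and a seven-region brain composed from four kinetic
sources, PSF blur, frame-dependent noise, full ground truth) makes every
stage testable; see `docs/methods.md` for the models and their limits.

## Worked example

```python
import numpy as np
from petidif import (FAConfig, default_phantom_spec, render_phantom,
                     extract_factors, normalize_to_activity, whole_body_tac,
                     run_4d_rrd, regional_means)
from petidif.cli import make_presaturation_template, extract_idif

# a degraded whole-body scan (PSF blur + noise) with known ground truth
image, truth = render_phantom(default_phantom_spec(rng_seed=0))

# P3 template from simulated presaturation animals, then the IDIF chain
template = make_presaturation_template(n=3, seed=100)
model, ifn = extract_idif(image, template, fa_config=FAConfig(kmeans_seed=0))
print(f"blood factor: {model.blood_index}, "
      f"IDIF peak: {ifn.whole_blood.max():.3e} Bq, "
      f"calibration scale: {ifn.calibration_scale:.4f}")

# V_T map after 10 iterations of resolution recovery
result = run_4d_rrd(image, ifn, iterations=10, psf_fwhm=1.6)
table = regional_means(result.vt_map, truth.atlas, metric="V_T")
print(table[["region", "mean", "sd"]].to_string(index=False))
```

prints (exact values depend on the seed):

```
blood factor: 1, IDIF peak: 1.918e+03 Bq, calibration scale: 0.0010
           region     mean       sd
 hippocampus_left 3.341117 0.633731
hippocampus_right 3.677353 0.515079
      cortex_left 1.492235 0.374125
     cortex_right 1.637888 0.398615
    thalamus_left 2.289056 0.509928
   thalamus_right 2.240650 0.432723
       cerebellum 1.269419 0.394546
```

The blood factor is the one whose curve best satisfies the timed-peak
constraint; its calibrated peak tracks the injected dose.  Regional V_T
(mL/cc) estimates the equilibrium tissue-to-plasma concentration ratio —
the phantom's ground truth is the sum of the free and specific kinetic
weights per region (2.9/3.1 for the sclerotic hippocampi, 1.0 for the
cerebellum), so the lesion reads highest; the ~15 % overestimate is the
partial-volume and input-tail bias discussed in `docs/methods.md`.

The same stages are available from a shell:

```sh
petidif simulate --seed 0 --output out/phantom
petidif pipeline --seed 0 --output out/full-run
```

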