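# petki

Whole-body parametric imaging of the ¹⁸F-FDG net influx rate **K_i** with
reduced scanning time: simulation and voxelwise maximum-likelihood
estimation under three dynamic-PET protocols.

## The problem

Parametric K_i images quantify irreversible FDG trapping and improve lesion
specificity over SUV images, but conventionally require a 60-minute dynamic
scan. On a total-body scanner with very high sensitivity, two much shorter
alternatives become feasible:

* **P1** — the gold standard: a full 0–60 min dynamic scan
  (5 s × 30, 30 s × 15, 120 s × 25 frames).
* **P2** — dual-time-point scanning: only 0–4 min and 54–60 min
  post-injection (10 min of acquisition in two sessions).
* **P3** — dual-injection scanning: one 50–60 min window with a second
  tracer bolus injected at 56 min, so early-phase kinetics of the second
  injection are superimposed on the late phase of the first (10 min,
  single session).

`petki` implements the full chain for all three protocols on a digital
phantom with known kinetics: frame-schedule handling, protocol
simulation from a 60-min scan, plasma-input-function construction
(image-derived, hybrid, and dual-injection decomposition), a voxelwise
maximum-likelihood estimator of K_i, the Patlak reference method, and the
evaluation metrics (lesion region-growing, coefficient of variation,
Bland–Altman-style agreement).

## The model

Tissue activity follows the irreversible two-tissue-compartment model

    dC₁/dt = K₁ C_p − (k₂+k₃) C₁,   dC₂/dt = k₃ C₁,   (k₄ = 0)
    X(t) = v_b C_p(t) + C₁(t) + C₂(t)

which reduces algebraically to a Patlak-like basis form

    X(t) = v_b C_p(t) + K₁′ e^(−k₂′ t) ⊗ C_p(t) + K_i ∫₀ᵗ C_p ds

with K₁′ = K₁k₂/(k₂+k₃), k₂′ = k₂+k₃ and the net influx rate
**K_i = K₁k₃/(k₂+k₃)**. Frame values are treated as scaled-Poisson
distributed with frame duration as the count-scale surrogate; five
parameters (K_i, K₁′, k₂′, v_b, input delay) are estimated jointly per
voxel by an alternating schedule of MLEM-style multiplicative updates
(e.g. K_i ← K_i · Σw B_i X/X̂ / Σw B_i) and bounded profile searches for
k₂′ and the delay — 27 main iterations with 6 linear sweeps each
(162 multiplicative updates per linear parameter), 2 delay and 1 k₂′
subiteration per main iteration.

For P2 the unscanned 4–54 min gap of the input function is bridged by a
**hybrid input function**: a population bolus curve C_p0, scaled and
exponentially tilted to meet the measured IDIF segments continuously,

    C_p(t) = μ e^(−γ(t−t₁)) C_p0(t),  t₁ < t < t₂,
    μ = C_image1(t₁)/C_p0(t₁),  μ e^(−γ(t₂−t₁)) C_p0(t₂) = C_image2(t₂).

For P3 the pre-second-injection tail is fitted with C_B0·e^(−bt) and
subtracted from the window IDIF to isolate the second bolus; assuming both
injections share one bolus shape, the model input is the superposition
C_p(t) + bolus(t − t₀).

## Worked example

```python
import numpy as np
from petki import build_phantom, run_protocol
from petki.metrics import lesion_compare

phantom = build_phantom({"shape": (12, 12, 10),
                         "lesions": [{"center": (6.0, 2.0, 2.0)}]})
p1 = run_protocol("P1", phantom=phantom)   # full 60-min scan, IDIF
p3 = run_protocol("P3", phantom=phantom)   # dual injection, composite IF

print(p3.results.summary().round(4))
masks = [phantom.mask(lab) for lab in phantom.lesion_labels]
table, summary = lesion_compare(p1.results.maps.ki, p3.results.maps.ki, masks)
print(table[["lesion", "n_voxels", "mean_ki_ref", "mean_ki_test",
             "percent_diff"]].round(5).to_string(index=False))
```

prints

```
             mean      sd     min     max
parameter
Ki         0.0023  0.0046  0.0000  0.0199
K1p        0.0711  0.1320  0.0288  0.5834
k2p        0.7365  0.9539  0.3059  3.0000
vb         0.1809  0.3377  0.0301  0.9822
delay      0.0738  0.2615  0.0000  1.0000
 lesion  n_voxels  mean_ki_ref  mean_ki_test  percent_diff
      0        46         0.02       0.01992       -0.3601
```

The summary rows are whole-body statistics of the five fitted maps (K_i and
the rate constants in min⁻¹, delay in seconds; the `max` column is
dominated by the blood pool, where v_b → 1). The lesion table compares the
mean lesion K_i of the 10-minute dual-injection protocol against the
60-minute gold standard on the same voxels: here they agree to 0.36%, the
phantom-scale statement of the protocol-equivalence result.

A command-line interface covers the same pipeline:

```bash
petki pipeline --protocol P3 --seed 7 --out-dir run1/       # simulate→IF→fit→metrics
petki protocol build --id P3 --out schedule.json
petki fit ml --dyn dyn.nii.gz --if if.csv --out-prefix maps_
```

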