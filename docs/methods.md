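# Methods

This note documents the models, numerical choices and design decisions
behind `petki`, and what the synthetic-phantom results do and do not show
about real data.

## Scanning protocols and frame handling

All times are seconds from the first injection; frames are half-open
`[start, end)` intervals. The three schedules are

| protocol | framing | acquired time |
|---|---|---|
| P1 | 5 s × 30, 30 s × 15, 120 s × 25 (0–3600 s) | 3600 s |
| P2 | 5 s × 30, 30 s × 3 (0–240 s); no scan to 3240 s; 120 s × 3 | 600 s |
| P3 | 120 s × 3 (3000–3360 s), 5 s × 30, 30 s × 3; injections at 0 and 3360 s | 600 s |

Both reduced protocols are derived from a simulated full P1 acquisition,
never simulated independently (except in consistency tests): P2 keeps
exactly the frames inside `[0, 240) ∪ [3240, 3600)`; P3 copies the
120-s-aligned frames before the second injection and, after it, adds the
early-phase frames (shifted by 3360 s) onto the late-phase activity.
Because the P1 late frames are 120 s long and the P3 post-injection framing
is 5 s/30 s, the late activity is resampled assuming it is **constant
within each original 120-s frame**. Late-time FDG activity changes slowly,
so this introduces <1% error relative to a direct forward simulation with
the composite input (verified in the tests); constant-within-frame
resampling is the simplest alignment consistent with summing images and
is this package's choice.

All images are decay-corrected activity concentrations (kBq/mL), the
convention of clinical reconstructions, so no decay term appears in the
kinetic model. A PET frame measures integrated counts, so the per-frame
model value is always the **time average** over the frame, never a
midpoint sample.

## Kinetic model

The irreversible two-tissue-compartment model with plasma input C_p:

    dC₁/dt = K₁C_p + k₄C₂ − (k₂+k₃)C₁
    dC₂/dt = k₃C₁ − k₄C₂
    X = v_b C_p + C₁ + C₂

Units: K₁ in mL/min/mL, k₂–k₄ in min⁻¹, v_b dimensionless, all
nonnegative, v_b ≤ 1. The fitted model sets k₄ = 0 (FDG-6-phosphate is
essentially trapped in tumor cells); k₄ > 0 is allowed in the phantom for
model-mismatch experiments. With k₄ = 0 the Laplace-domain reduction

    C₁+C₂  ⇔  K₁ (s+k₃) / (s(s+k₂+k₃)) · C_p(s)
           =  [K_i/s + K₁′/(s+k₂′)] · C_p(s)

gives the basis form `X = v_b C_p + K₁′ e^(−k₂′t)⊗C_p + K_i ∫C_p` with

    K₁′ = K₁k₂/(k₂+k₃),   k₂′ = k₂+k₃,   K_i = K₁k₃/(k₂+k₃).

These are the unique coefficients making the basis form an identity with
the ODE solution; the identity is enforced by test (50 random parameter
draws, <0.5% of the TAC peak — measured ≈0.008%).

### Numerics

* Fine time grid: Δt = 1 s (shortest frame is 5 s; the bolus peak is
  resolved to sub-percent quadrature error). Integration/convolution
  outputs are converted to kBq·min/mL so min⁻¹ rate constants yield kBq/mL.
* `expconv` uses the exact first-order recursion for trapezoid-in-interval
  integration, `y[n+1] = a·y[n] + Δt/2·(a·v[n] + v[n+1])`,
  `a = exp(−k₂′Δt)`, implemented as a linear filter.
* `solve_2tc` (phantom truth and oracle) integrates the ODE directly with
  LSODA (rtol 1e-8, max step 2Δt) and linear interpolation of C_p — a path
  independent of the convolution machinery it validates.
* The input delay is modeled as `C_p(t−δ)` with zero-fill before
  injection; |δ| ≤ 60 s. Dispersion is not modeled.
* Frame averages are read off one cumulative trapezoidal integral per
  curve, evaluated at (possibly shifted) frame boundaries; shifting
  commutes with convolution and integration, so delayed bases reuse the
  undelayed fine-grid curves.

## Maximum-likelihood estimation

Voxel values are modeled as scaled-Poisson with the frame duration as the
count-scale surrogate: the objective is `L = Σ_t w_t (X_t ln X̂_t − X̂_t)`
with `w_t ∝ duration`, max-normalized. Folding frame lengths into the
weights is algebraically equivalent (for the update ratios) to folding
them into C_p and C_i.

The linear coefficients (K_i, K₁′, v_b) have MLEM-style multiplicative
updates, e.g. `K_i ← K_i · Σ w B_i (X/X̂) / Σ w B_i`; each is an EM
coordinate step, so a sweep never decreases the likelihood (asserted
numerically on 1000 random voxels). v_b is clipped to [0, 1] (projection
onto the physical set). A prediction floor ε = 1e−9 kBq/mL guards 0/0 on
empty frames.

The alternating schedule per voxel (defaults): 27 main iterations, each
with 6 sweeps of the linear triplet (162 multiplicative updates per linear
parameter in total, by instrumented counter), 2 delay subiterations and
1 k₂′ subiteration. Initial values K_i = 0.01, K₁′ = 0.05, k₂′ = 1.0
min⁻¹, v_b = 0.05, δ = 0 s — mid-range physiological values;
multiplicative updates need strictly positive starts. k₂′ is bounded to
[0.01, 3] min⁻¹; the delay search grid is −10…+30 s in 1-s steps.

### Nonlinear updates

The delay subiteration is a local 3-point grid search; the k₂′
subiteration a bounded geometric pattern search (step factor starts at
1.6, expands ×1.3 on an accepted move, shrinks toward 1 otherwise). Both
move only on strict improvement, with ties broken toward the smaller
value, so the aggregate likelihood trace is monotone.

A plain coordinate move with the linear coefficients frozen stalls: the
likelihood valley is strongly curved in (k₂′, K₁′) and (δ, v_b, K₁′), and
frozen-coefficient comparisons misorder candidates even arbitrarily close
to the optimum. Candidate evaluation therefore re-adapts the linear
triplet with 8 MLEM sweeps — symmetrically for the incumbent, so the
accept/reject decision approximates a profile-likelihood comparison and a
rejected incumbent keeps its adapted coefficients as free monotone
progress. With this scheme the default schedule recovers all parameters of
every parenchymal phantom tissue to ≤0.3% (k₂′ ≤0.3%, delay exact for
both 0 s and 8 s true shifts) on noiseless data.

Two documented limitations:

* **Blood-pool voxels** (v_b = 1, no tissue compartment) sit on the
  parameter-space boundary where K₁′ = 0 makes k₂′ unidentifiable; the
  alternating fit approaches v_b = 1 only asymptotically (≈0.92 after 27
  iterations) while the K_i error stays <0.5% of the phantom's K_i range.
  Parameter-recovery claims therefore refer to parenchymal tissues.
* Per-voxel fits are independent; results are identical regardless of
  processing order or chunking (vectorized in lockstep, no cross-voxel
  state).

Inside `fit()` the K₁′-basis frame averages are read from a dense
precomputed table (128 log-spaced k₂′ values × the delay grid) by
log-linear interpolation (≤0.02% error); `make_basis` itself is exact and
is what the identity tests check.

### Patlak reference

Ordinary least squares of `X/C_p` against `∫C_p/C_p` over frames starting
at or after t* = 1200 s (20 min), unweighted, per voxel; the slope is K_i,
the intercept lumps v_b with the equilibrated convolution term. With a
multi-exponential bolus input the convolution/C_p ratio still drifts
slightly after 20 min, giving Patlak a small negative bias (~4e−4 min⁻¹
here) that is negligible for lesions (<0.3% relative) but large relative
to the tiny K_i of muscle or liver (−6% relative). The nonlinear estimate
reading higher than Patlak in low-uptake background is the well-documented
behavior of the two estimators, not an implementation artifact; the tests
assert relative agreement where equilibrium holds and absolute-scale
agreement elsewhere.

## Input functions

* **Population bolus**: the Feng sum-of-exponentials model
  `(A₁t − A₂ − A₃)e^(−λ₁t) + A₂e^(−λ₂t) + A₃e^(−λ₃t)` with the classic
  published FDG coefficients as defaults (A₁ = 851.12 kBq/mL/min,
  A₂ = 21.88, A₃ = 20.81 kBq/mL, λ₁ = 4.1339, λ₂ = 0.01043,
  λ₃ = 0.1191 min⁻¹). Any tabulated curve can be supplied via CSV.
* **IDIF**: per-frame mean over the blood-pool mask, linearly interpolated
  at frame midpoints to the 1-s grid with constant end extrapolation. On
  the sharply rising bolus the first ~4 frames carry a 1–2% (of peak)
  curvature error of midpoint interpolation; beyond them agreement with
  the true frame averages is <0.5%.
* **Hybrid (P2)**: μ and γ are fixed by continuity at t₁ = 240 s and
  t₂ = 3240 s (exact by construction). μ absorbs any scale difference and
  γ any single-exponential tilt between the population curve and the
  patient's true input, so whenever the population shape matches the truth
  up to scale×tilt the bridge is exact.
* **Dual-injection decomposition (P3)**: the pre-t₀ tail is fitted with
  `C_B0 e^(−bt)` by nonlinear least squares on the linear scale
  (log-linear initialization, time re-referenced to the window start —
  fitting in absolute time is numerically ill-conditioned), extrapolated
  past t₀ and subtracted; negative residuals are clipped at zero. The
  pre- and post-injection IDIF segments are interpolated independently so
  no sample mixes tail and bolus activity. The measured tail exists only
  on [3000, 3360) s; its role as the late-phase anchor over the full
  window is taken by the fitted exponential (smooth through the second
  injection), with t₂ = 3000 s for the hybrid bridge — a design choice of
  this package.
* **Composite input**: first input plus `dose_ratio ×` bolus shifted to
  t₀ = 3360 s; superposition is exact because the model is linear and
  time-invariant in C_p. `dose_ratio` defaults to 1, matching simulation
  of the dual injection by direct image addition.

## Synthetic phantom

Default grid 32×32×48 voxels at 3.125 mm in-plane / 2.89 mm slice (a
total-body reconstruction grid scaled to desk size; the full grid is
config-reachable). Regions: elliptical muscle body, liver, two kidneys, an
axial blood-pool cylinder (v_b = 1; the IDIF source) and three spherical
lesions of 13.8 mm equivalent diameter. Default kinetics (min⁻¹ units;
generator choices in the physiological FDG range, not measured constants):

| tissue | K₁ | k₂ | k₃ | v_b | K_i |
|---|---|---|---|---|---|
| muscle | 0.03 | 0.3 | 0.01 | 0.03 | 0.00097 |
| liver | 0.6 | 0.5 | 0.005 | 0.10 | 0.0059 |
| kidney | 0.3 | 0.6 | 0.02 | 0.15 | 0.0097 |
| lesion | 0.1 | 0.4 | 0.1 | 0.05 | 0.020 |
| blood | 0 | 0 | 0 | 1.0 | 0 |

Liver and kidney k₃ are set low so lesions are the K_i hotspots, as in
FDG oncology; the kidney value does not attempt to model renal excretion
(a known mismatch of the irreversible model). Noiseless TACs are computed
once per label by the ODE solver, frame-averaged and broadcast — exact for
piecewise-constant phantoms. Noise is scaled-Poisson applied to the
reconstructed-activity domain: `Poisson(v·s·d)/(s·d)` for count scale s
(counts per kBq/mL per second, default 1.0 — a few hundred to a few
thousand counts per late muscle frame) and frame duration d, so variance
scales as 1/(s·d). Noise replicates reuse the cached noiseless simulation.

### What the phantom does and does not emulate

It reproduces the temporal structure of the three protocols, realistic
bolus-shaped inputs, tissue-contrast ranges and duration-dependent
scaled-Poisson noise. It does **not** model anatomy (XCAT-level), motion,
attenuation/scatter physics, reconstruction correlations between voxels,
injection-site residual activity, renal excretion, inter-session
registration for P2, or patient-to-patient input-function shape
variability — in particular, the default population curve is shape-matched
(up to scale) to the simulated truth, so protocol-equivalence results
bound the error of the protocol/IF machinery itself, not of population
mismatch in real patients. Passing tests therefore demonstrate
correctness of the chain under its own assumptions, not clinical accuracy.

## Evaluation metrics

Lesion segmentation: 26-connected region growing from the hottest voxel of
a user-supplied search region, admitting voxels ≥ 90% of the regional
maximum (inclusive; connectivity and threshold are configurable design choices). Noise surrogate: coefficient of
variation (sample SD/mean, n−1) in a uniform muscle region. Agreement:
per-lesion percent difference of mean K_i on identical masks, summarized
as mean ± SD across lesions; equivalent diameter is that of the
volume-matched sphere.

At 100 replicates × 100 muscle voxels the voxel-K_i variance of both
reduced protocols is ~27× that of P1; P2 and P3 are statistically
indistinguishable (ratio 1.01 against a ~3% two-standard-error band), so
the P2-vs-P3 noise comparison is asserted as "P3 no worse than P2 within
sampling error" rather than as a strict inequality.

## Problem sizes used

Unit tests run on a 12×12×10 phantom; noiseless recovery and the Patlak
comparison run on the default 32×32×48 phantom; the noise study uses 100
replicates of a 100-voxel muscle region plus the lesion, fitted per
replicate for all three protocols. These sizes make the whole suite and
the acceptance script each complete in minutes on one CPU while keeping
every assertion at full voxelwise fidelity.
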