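# Methods

This note records the statistical model, the numerical conventions, and the
design choices behind `wormescape`, including what the synthetic-data
generator does and does not emulate.

## Observation model

A trial is a signed centre-of-mass velocity trace sampled at 60 Hz for 15 s
(pixels/s; positive = forward), with a 0.1 s infrared-laser pulse of current
I ∈ [0, 200] mA at t = 1 s. The modelling view of a trial is the profile
**v**: the trace smoothed with a 500 ms Gaussian filter, subsampled at
12 Hz, and restricted to 1.0–3.3 s (28 points; the wider 1.0–4.0 s window,
37 points, is kept for inspection). A trial is *active* when its maximum
reverse speed in the model window exceeds 10 px/s (strictly), else *paused*.

The generative model is a two-state mixture:

    P(v|I) = P(p|I) · N(v; u_p, Σ_p) + (1 − P(p|I)) · N(v; f(I)·u_a, Σ_a)
    P(p|I) = 1 / (1 + (I/I0)²)
    f(I)   = I1 + I / (1 + I/I2),   I2 ∈ (0, ∞]

Decoding inverts this with Bayes' rule on a 0–200 mA grid (1 mA step)
against a stimulus prior; the posterior expectation Ī is the decoded
("perceived") current. Treated cohorts are always decoded with the control
model, so a shift in Ī reflects perception, not refitted machinery.

## Fitting

- **I0** maximises the Bernoulli likelihood of the active/paused labels;
  1-D bounded search on log I0 over [1e−2, 1e4] mA after a 241-point grid
  pre-scan; absolute tolerance 1e−9 on log I0. Both all-active and
  all-paused label sets are boundary-degenerate and raise.
- **u_p, Σ_p** are the mean and 1/n covariance of the paused profiles.
- **u_a, Σ_a** at fixed (I1, I2) have closed forms: u_a = Σᵢvᵢf(Iᵢ)/Σᵢf²(Iᵢ)
  pointwise, Σ_a the full 28×28 1/n covariance of the residuals
  vᵢ − f(Iᵢ)u_a. With Σ_a profiled at its ML value, the outer objective
  reduces to log det Σ_a(I1, I2).
- **Outer search.** The profiled surface is a very flat curved valley and a
  second local basin exists (a linear-f solution with large I1), so the
  outer optimiser is derivative-free Nelder-Mead over (I1, q = 100/I2) —
  a parameterisation in which both axes are O(1–10) and the linear regime
  I2 = ∞ is the soft boundary q ≤ 0. A coarse 9×7 grid pre-scan seeds three
  extra simplex starts in addition to ten random restarts
  (I1 ~ U(−100, 100), 1/I2 ~ U(0, 0.2)); the best optimum is kept. A fitted
  1/I2 below 1e−6 (I2 beyond ~5000× the instrument range) is reported as
  I2 = ∞. Quasi-Newton search with numerical gradients was found to stall
  on this surface and is not used.
- **Identifiability.** f′(0) = 1 by construction, which pins the template's
  overall scale; no further normalisation of u_a is applied during fitting.
- **Ridge.** Covariances whose condition number exceeds 1e10 receive
  ε·mean(diag)·Iₙ with ε = 1e−6 (logged); rank-deficiency that ridging
  cannot repair raises.

## Gaussian normalisation and effective T

Velocity samples are temporally correlated, so the Gaussian components use
T, the effective number of independent time points, in the (2π)^(T/2)
prefactor: T = (model-window duration, 2.3 s) / τ, where τ is the first
lag at which the pooled autocorrelation of mean-subtracted profiles falls
below 1/e (linear interpolation between integer lags, floored at one 12 Hz
frame). The quadratic form is kept at its full 28-point dimension — the
convention under which the paused and active components are compared on a
common footing; the config switch `quadform_scale: T_over_D` rescales the
quadratic form by T/28 instead. Because T enters both mixture components
identically, it shifts log-likelihoods by a common factor and has little
effect on decoding.

## Preprocessing conventions

- "500 ms Gaussian filter" is implemented as σ = 125 ms truncated at ±2σ
  (total support 500 ms). At each output sample the kernel is restricted to
  in-range inputs and renormalised to unit mass — a one-sided Gaussian at
  the edges that preserves constants everywhere. Filter width has little
  downstream effect, so any documented convention serves.
- Subsampling takes t = lo + k/12 for all k with t ≤ hi, endpoints
  inclusive on the aligned grid: 37 points on [1, 4] s, 28 on [1, 3.3] s
  (last point 3.25 s). The ~10-frame post-stimulus latency is retained.
- Classification uses the *filtered* 12 Hz model-window profile.

## Bins, effects, bootstrap

- The five presentation/analysis bins are equal-count rank bins of the
  *control* currents (rank r of n maps to bin ⌊r·5/n⌋): 200 trials give
  exactly 40 per bin; remainders land in the lower bins. Other values
  (treated currents, resampled cohorts) are assigned by midpoint edges
  between adjacent bins.
- ΔI pairs every control trial with the treated trial of nearest applied
  current (reuse allowed; ties to the lowest treated index) and averages
  Ī_control − Ī_treated within each control bin. Self-comparison gives
  exactly 0.
- The bootstrap (B = 1000 by default) resamples both cohorts with
  replacement, refits the whole control pipeline (pause current, templates,
  scaling, prior), re-pairs, and recomputes ΔI; SDs over replicates give
  per-bin Z scores. Replicate fit failures are retried with fresh restarts;
  more than 5 % failures aborts. Everything is reproducible bit-exactly
  from the seed. A fixed-model bootstrap (`refit=False`) exists for smoke
  tests and underestimates the error bars.
- The power curve repeats this while drawing n treated trials with
  replacement from one stimulus bin, giving Z(n).
- The stimulus prior is a Gaussian KDE (Silverman bandwidth) of the
  observed currents, boundary-reflected at 0 and 200 mA and renormalised on
  the grid; a uniform prior is available. The prior defaults to the control
  cohort's currents since only the control model decodes.

## Synthetic-data generator

The generator exists so that every stage has a ground truth. Its defaults
are the assay's published conditions: currents uniform on [0, 200] mA,
states Bernoulli from the sigmoid pause model, forward baselines
13 ± 9 / 9 ± 7 / 13 ± 10 px/s (control / ibuprofen / mutant), correlated
Gaussian noise with σ = 5 px/s and exponential covariance with a 0.2 s
correlation time, and per-genotype parameters (I0 = 25.9 / 26.6 / 51.6 mA,
I1 = −4.5 / −4.5 / 66.5, I2 = 45 / 12 / ∞, a one-frame (83 ms) mutant
response lag).

The canonical active template is an **invented fixture**: a constant
forward bias plus, scaled by the reversal depth, a negative Gaussian lobe
(centre 1.8 s, width 0.35 s) and a sigmoid recovery. Its shape parameters
were chosen once so the reversal minimum falls in the 1.5–2 s range; real
templates exist only as figures and are not reproduced. The template
returned by `canonical_template` is the smoothed-and-subsampled view of the
continuous curve, normalised to min = −1 on the model grid, so a noise-free
simulated trace processed through the pipeline equals f(I)·template
*exactly* (smoothing is linear). Raw traces are generated at 60 Hz so the
full filter → subsample path is exercised; the forward baseline is applied
strictly pre-stimulus for active trials and decays over ~0.4 s for paused
trials. f(I) can be negative at small currents (f(0) = −4.5 for the
control) and is applied as-is.

What passing recovery tests show: the fitters invert the generator's own
model at the published parameter values. What they do not show: robustness
to real-worm features the generator omits — posture-dependent velocity
structure, non-Gaussian or non-stationary noise, trial discards, omega-turn
kinematics, inter-worm template variability.

Cutoff-based classification selects trials partly by their noise
realisation (a generated-active trial near threshold is kept or dropped by
its noise), so end-to-end recovery of (I0, I1, I2) from raw traces carries
a small selection bias (≈ +2 mA on I0, ≈ +1 on I1 at the default noise
level); recovery tests budget for it. Recovery from profiles generated
directly at 12 Hz with known labels is unbiased to sampling error.

## Problem sizes in tests

Unit and property tests run on cohorts of 200–1500 simulated trials with
2–10 optimiser restarts and bootstrap depths of 2–150; the recovery
benchmarks use 10,000 trials (pause current) and 2,000 profiles (scaling
parameters), sizes at which the sampling SDs are a few percent of the
recovered values. The full-pipeline bootstrap at B = 1000 is the intended
production setting, not the test setting.

## Known limitations

- σ²_m is defined by subtraction (σ²_I − σ²_res, clipped at 0, with
  clipping reported) and σ²_res via model predictions f(Ī_bin)·u_a at the
  bin-mean current — the operational reading under which the variance
  identity is exact. Population (1/n) variances throughout; a
  sample-variance option exists but breaks exact additivity.
- The pause-current uncertainty is reported as a bootstrap SD; likelihood
  curvature is not used.
- No per-worm random effects; no time-warping alignment (the mutant's lag
  is a property of the simulator, not corrected by the fitter); no
  hyperalgesia-specific analysis, though ΔI is signed.
- With N_treated < N_control, treated trials are reused across pairs, which
  correlates paired differences; bootstrap SDs absorb this.
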