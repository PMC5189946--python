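# wormescape

Decoding the *perceived* heat-stimulus level from the stereotyped escape
behaviour of individual *Caenorhabditis elegans*.

In a thermal-nociception assay a brief infrared-laser pulse (current
0–200 mA, heating roughly proportional to the current) is delivered to the
head of a crawling worm, and its signed centre-of-mass velocity is recorded
at 60 Hz for 15 s (positive = forward; stimulus at *t* = 1 s). Some worms
pause; the rest mount a stereotyped escape — reversal, omega turn, forward
motion in a new direction. `wormescape` implements the statistical pipeline
that turns such recordings into a per-trial readout of the stimulus level
the worm *perceived*, which makes analgesic-like effects of drugs or
mutations measurable on a continuous scale, with honest error bars and a
sample-size calculator. A generative simulator of escape trials makes every
stage testable without access to recordings.

## The model

Each trial's smoothed, 12 Hz-subsampled velocity profile **v** (28 points on
1.0–3.3 s) follows a two-state mixture:

- **State.** The worm pauses with probability
  P(p|I) = 1 / (1 + (I/I₀)²), where I₀ is the *pause current* (the current
  at which pausing and escaping are equally likely); otherwise it is active.
- **Paused trials:** **v** ~ N(**u**_p, Σ_p) — a near-zero template,
  independent of the current.
- **Active trials:** **v** ~ N(f(I)·**u**_a, Σ_a) — a stereotyped escape
  template **u**_a scaled by the saturating function
  f(I) = I₁ + I/(1 + I/I₂).
  The unit small-current slope of f pins the template's scale, so (I₁, I₂)
  are identifiable; I₂ = ∞ is the linear, non-saturating limit. The
  Gaussian normalisation uses T, the number of effectively independent time
  points (window duration / velocity correlation time).

(I₁, I₂) are fitted by nested maximum likelihood — **u**_a and Σ_a have
closed forms at fixed (I₁, I₂); the outer 2-D search is restarted from ten
initial points. Bayes' rule with an empirical stimulus prior then yields
the posterior P(I|**v**) on a 1 mA grid; its expectation Ī is the decoded
(perceived) stimulus.

Downstream analyses: a per-time-point variance decomposition
σ²_total = σ²_I + σ²_ind and σ²_I = σ²_m + σ²_res (how much behavioural
variance the current could explain, and how much the template model actually
does); the collapse **v**/f(I), which tests stereotypy directly; and the
treatment-effect estimator ΔI — every treated cohort is decoded with the
*control* model, each control trial is paired with the treated trial of
nearest applied current, and the mean decoded difference per equal-count
current bin measures the perceived-stimulus reduction, with SDs and Z
scores from a bootstrap that refits the entire pipeline, plus a Z-vs-n
power curve for experiment design.

## Worked example

```python
import wormescape as we

spec = we.paper_preset("control")             # I0=25.9 mA, I1=-4.5, I2=45.0
cohort, truth = we.simulate_cohort(spec, 400, seed=0)
V = we.VelocityPreprocessor().transform(cohort.velocity_matrix)
I = cohort.currents_mA

model = we.EscapeResponseModel(n_restarts=5, random_state=0).fit(V, I)
print(f"pause current I0 = {model.I0_mA_:.1f} mA")
print(f"scaling: I1 = {model.active_.I1_:.2f}, I2 = {model.active_.I2_:.1f} mA")

treated, _ = we.simulate_cohort(we.paper_preset("ibuprofen"), 400, seed=1)
Vt = we.VelocityPreprocessor().transform(treated.velocity_matrix)
est = we.bootstrap_effect(V, I, Vt, treated.currents_mA, model,
                          B=40, seed=2, refit=True)
for c, d, z in zip(est.bin_centers_mA, est.delta_I_mA, est.z_score):
    print(f"bin {c:5.0f} mA: dI = {d:6.1f} mA   Z = {z:5.1f}")
```

Output:

```
pause current I0 = 25.3 mA
scaling: I1 = 2.07, I2 = 58.7 mA
bin    21 mA: dI =   15.3 mA   Z =   5.1
bin    68 mA: dI =   63.9 mA   Z =  15.6
bin   109 mA: dI =   99.9 mA   Z =  26.4
bin   149 mA: dI =  127.1 mA   Z =  35.4
bin   184 mA: dI =  132.5 mA   Z =  35.1
```

The fitted pause current (25.3 mA) recovers the generating 25.9 mA; the
scaling parameters recover their generating values up to the sampling
scatter of a 400-trial cohort. The ΔI rows say that, decoded through the
control model, the simulated ibuprofen-like cohort (saturation I₂ = 12 mA
instead of 45 mA) perceives a strongly reduced stimulus at mid and high
currents — this synthetic effect is much stronger than a real drug effect
because the simulator's noise floor is far below that of real worms.

The same pipeline is scriptable from the shell:
`wormescape simulate | preprocess | fit | infer | effect | power`
(see `wormescape --help`).

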