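# if1kinetics

Kinetic analysis of IF₁ inhibition of the mitochondrial F₁-ATPase, at the
single-molecule and ensemble level.

F₁-ATPase is a rotary molecular motor: ATP hydrolysis in the α₃β₃ stator
drives the γ subunit counterclockwise in 120° steps, each step split into
an ATP-binding dwell (0°/120°/240°) and a catalytic dwell ~80° later. The
mitochondrial inhibitor protein IF₁ arrests the motor at the catalytic
dwell essentially irreversibly under hydrolysis conditions, and is ejected
when the rotor is forced backwards (the ATP-synthesis direction) past a
threshold angle. This package implements the quantitative analyses that
characterise that behaviour, together with a stochastic simulator that
generates bead-rotation traces, coupled-assay progress curves and
magnetic-tweezers manipulation outcomes with known ground truth, so every
analysis stage is testable end to end.

It is intended for single-molecule biophysicists and enzymologists who
need a reference implementation of:

* **Pause statistics** — segmentation of 30 fps angle traces into pauses
  (≥ 1 s) and rotation episodes; ATP-binding dwell angles by 120°-periodic
  clustering; the inhibited-pause angle Δθ relative to the binding dwell,
  reduced to [0°, 120°); classification of pauses into ADP inhibition
  (tens of seconds, recovering) versus IF₁ arrest (≥ 480 s or terminal).
* **Dwell-time fitting** — single- and double-exponential fits,
  `y = N_rot e^(−t/τ_rot)` and `y = N_sp e^(−t/τ_sp) + N_lp e^(−t/τ_lp)`,
  by right-censored maximum likelihood (terminal pauses censored at the
  record end) or by binned least squares.
* **Slow-binding inhibition kinetics** — the two-step scheme
  `F₁ + IF₁ ⇌(k_on, k_off) F₁·IF₁ →(k_lock) F₁·IF₁^lock` gives a
  progress curve `y(t) − y₀ = V∞t + (V₀ − V∞)/k_app · (1 − e^(−k_app t))`
  with `k_app = k_lock[IF₁]/(K_M + [IF₁])` and
  `K_M = (k_off + k_lock)/k_on`; the package fits the curve, the
  concentration dependence, and the residual (plateau) activity.
* **Stall-and-release statistics** — P_ON ± √(P_ON(100−P_ON)/N) per
  (stall angle, stall time) cell, a logistic-ramp activation-hazard model
  `k_act(θ)` with threshold, and its binomial maximum-likelihood fit with
  profile-likelihood intervals for the threshold angle.
* **Rotational energetics** — stall work τ·θ, its molar equivalent, and
  the minimum proton-motive-force voltage `2πτ/(n·e)` needed to reverse
  the motor (≈ 196 mV for 40 pN·nm and 8 H⁺/turn).

## Worked example

Simulate a molecule rotating at 1 mM ATP after introduction of 3 µM
inhibitor, segment and classify its pauses, then fit the matching
ensemble assay:

```python
from if1kinetics.rotary_sim import (EnsembleAssayConfig, MotorConfig,
                                    ObservationConfig,
                                    simulate_ensemble_progress,
                                    simulate_trajectory)
from if1kinetics.trajectory_analysis import classify_pauses, detect_pauses
from if1kinetics.inhibition_kinetics import fit_progress_curve, residual_activity

motor = MotorConfig(if1_entry_rate=0.05)       # ~20 s rotation before arrest
obs = ObservationConfig(fps=30, angle_noise_sd=6.0, duration=120.0, seed=42)
trace = simulate_trajectory(motor, obs)
pauses = classify_pauses(detect_pauses(trace),
                         trace_end=float(trace.time[-1] + 1 / trace.fps))
for p in pauses:
    print(f"{p.start:7.2f}-{p.end:7.2f} s  angle {p.mean_angle % 360:6.1f} deg  {p.label}")

curve = simulate_ensemble_progress(
    EnsembleAssayConfig(if1_conc=3e-6, absorbance_noise_sd=2e-3), seed=42)
fit = fit_progress_curve(curve)
print(f"k_app = {fit.k_app:.4f} /s   V0 = {fit.v0:.2e} AU/s   Vinf = {fit.vinf:.2e} AU/s")
print(f"residual activity = {residual_activity(curve):.3f}")
```

prints

```
   6.70-  45.67 s  angle  320.0 deg  ADP
  51.60- 120.00 s  angle  319.9 deg  IF1
k_app = 0.0375 /s   V0 = -7.35e-04 AU/s   Vinf = -1.93e-06 AU/s
residual activity = 0.134
```

The molecule pauses twice at a catalytic angle (320° ≡ 80° mod 120°): a
39 s pause that recovers (ADP inhibition) and a terminal arrest (IF₁).
The ensemble curve loses activity with an apparent rate of 0.0375 s⁻¹ —
close to the k_lock plateau of 1/30 s⁻¹, as expected for 3 µM inhibitor
far above K_M — and retains ~13% of its initial rate 350 s after
injection, the slow-binding plateau `|V∞|/|V₀|` not yet fully locked.

A command-line interface mirrors the library:

```sh
if1kin simulate trace --seed 3 --out trace.csv
if1kin analyze-trace --trace trace.csv
if1kin simulate ensemble --out curve.csv && if1kin fit-progress --curve curve.csv
if1kin energetics --torque 40 --protons 8 --angle 200
```

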