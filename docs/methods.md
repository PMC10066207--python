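# Methods

This note documents the models, default parameters, numerical choices and
known limitations of `if1kinetics`. Angles are degrees on the unwrapped
scale, counterclockwise (hydrolysis) positive; times are seconds;
concentrations molar.

## Rotary trajectory model

The simulator generates the latent rotor path as a continuous-time Markov
dwell sequence. Each 120° step consists of an ATP-binding dwell at
`a + 120k` (exponential wait at rate `k_bind = k_on^ATP·[ATP]`, default
3×10⁷ M⁻¹s⁻¹ so that 1 mM ATP makes binding effectively instantaneous and
~30 nM produces the binding-limited three-dwell regime) and a catalytic
dwell at `a + 120k + 80°` (exponential wait at `catalytic_rate`, default
200 s⁻¹, i.e. 5 ms — a placeholder, since catalytic dwells are
unresolvable at 30 fps). Sub-steps are instantaneous; the 10°–20° short
pauses of the full mechanochemical scheme are deliberately omitted.

Two inactivation channels act at catalytic angles only, reflecting the
observation that inhibited molecules stop at the catalytic dwell:

* **ADP inhibition** — a per-catalytic-dwell Bernoulli event (the
  per-turn probability, default 0.002, is converted exactly to a
  per-dwell probability via `1 − (1−p)^{1/3}`), with pause duration drawn
  from a one- or two-component exponential mixture (default mean 20 s,
  within the 10–30 s range characteristic of the phenomenon). A Bernoulli
  entry per dwell was chosen over a continuous hazard because pauses
  occur at discrete catalytic angles; either choice fits dwell data.
* **Inhibitor (IF₁) arrest** — a continuous hazard `if1_entry_rate`
  (default 0.05 s⁻¹, the value that reproduces a ~20 s mean rotating
  time at 3 µM inhibitor and saturating ATP; the rate is proportional to
  inhibitor concentration) competing with catalytic exit. The arrest
  duration is exponential with mean `if1_pause_tau`: infinite for the
  wild-type inhibitor (irreversible on experimental timescales), finite
  for destabilised variants (~254 s and ~60 s are the regimes of the two
  N-terminally truncated variants the activation model parameterises).
  By default the inhibitor cannot associate during ADP pauses
  (`allow_if1_during_adp=False`), treating the ADP-inhibited state as off
  the association pathway; the flag exposes the alternative.

The observed trace samples the latent staircase at `fps` (default 30)
and adds i.i.d. Gaussian angular noise per frame (no bead-linkage
compliance model). Random numbers are drawn in a fixed documented order —
the event loop in simulated-time order, then one block of per-frame
noise — so a (seed, config) pair is bit-reproducible. The exact expected
rotating time of the competing-risk scheme,
`E[T] = (1/q)·(1/k_bind + 1/(r + k_cat))` with `q = r/(r + k_cat)`,
serves as the oracle for law-of-large-numbers tests.

What the generator does *not* emulate: bead hydrodynamics and drag
(observed rotation rates are therefore set by the chemical rates alone),
low-frequency drift, molecule-to-molecule angular disorder, torque
fluctuations during stalls, and Fo coupling. Passing round-trip tests
therefore demonstrates correctness of the analysis pipeline under ideal
observation statistics, not robustness to instrumental drift.

## Ensemble three-state scheme

The coupled-assay simulator solves the linear system for the fractions
(free, encounter complex, locked) under pseudo-first-order inhibitor
excess, by eigendecomposition of the rate matrix; the locked state is
absorbing (zero eigenvalue handled analytically, `(e^{λt}−1)/λ → t`).
The instantaneous ATPase rate is proportional to free + encounter-complex
fractions (the encounter complex is still catalytically active), and the
absorbance integrates that activity:
`A(t) = A₀ − ε·l·v·(t_inj + ∫ active dt)`. Defaults: ε = 6220 M⁻¹cm⁻¹
(standard for NADH at 340 nm), path 1 cm, A₀ = 1.2 AU (~0.2 mM NADH),
100 s⁻¹ per-enzyme turnover at 1 nM enzyme, injection at 180 s, 1 s
sampling, 2 mAU observation noise available. The ATP-regenerating couple
is idealised as fast: ATP constant, ADP never accumulates. An independent
matrix-exponential (`scipy.linalg.expm`) solution is used as the test
oracle; the two routes agree to ≤ 10⁻⁸ across random parameter sets.

Note on the single-exponential approximation: fitting the
exponential-plus-linear model to the exact three-state curve recovers the
slow eigenvalue of the rate matrix, which exceeds the hyperbolic
steady-state prediction `k_lock[I]/(K_M+[I])` by a factor
`≈ 1 + a·k_lock/(a+k_off+k_lock)²` (a = k_on[I]). The default study
conditions (k_on = 10⁶ M⁻¹s⁻¹, k_off = 0.02 s⁻¹, k_lock = 1/30 s⁻¹,
[I] ≥ µM) keep this discrepancy ≤ ~1%, well inside fit uncertainty at
realistic noise.

## Pause detection

A pause is a maximal interval over which the angle stays within
`angle_window` of its local median, lasting at least `min_duration`
(default 1 s). The window defaults to 30° — a quarter step, the value
that separates adjacent dwells at realistic noise; the algorithm warns
when the window is below 3× the robust frame-to-frame noise estimate.
Implementation: median-3 pre-filter against isolated outliers; sliding
windows of `min_duration` flagged flat when their angular range is ≤
2×window; covered frames merged into runs; runs split recursively at the
largest internal jump until each piece sits within the band (this
resolves back-to-back dwells at different angles); pieces of the same
dwell re-joined across gaps ≤ 3 frames; boundaries refined against each
segment's median without crossing neighbours. Segment statistics use
interior frames (2-frame trim) to avoid boundary contamination. On
simulated traces with 5–10° noise this recovers pauses ≥ 1.5 s with ≤ 2
frames boundary error and no spurious pauses during multi-rps rotation.

Binding-dwell references fold pause angles on a 120° period (circular
mean), assign each pause to the nearest of three classes and return
duration-weighted circular means. The inhibited-pause angle Δθ is the
pause angle minus the reference, reduced to [0°, 120°) — equivalent to
measuring from the binding dwell immediately preceding in the hydrolysis
direction — and summarised by a Gaussian (mean, SD); pauses are pooled
across molecules, with the single-pause SD reported as NaN. Circular
statistics are used throughout so samples straddling the reduction
boundary are handled correctly.

Classification rules: ≥ 480 s, or terminal without recovery → IF₁;
recovered within the ADP range (default 5–100 s) → ADP; otherwise
unclassified.

## Dwell-time fits

Default method is right-censored maximum likelihood: for the single
exponential τ̂ = Στᵢ/n_uncensored (SE τ̂/√n_unc); naive MLE on truncated
data is demonstrably biased low, which the tests exhibit. The
two-component fit maximises the censored mixture likelihood (Nelder–Mead
on logit-weight / log-τ coordinates, initialised from a median split of
the durations), with SEs from a finite-difference Hessian on the natural
parameters. Fits are flagged unidentifiable when the time constants are
within a factor of 3 or a component carries < 5% of events. Binned least
squares (`histogram_ls`, bin width τ̂/5 by default) is provided for
literal reproduction of histogram-based analyses; censored events are
excluded from histograms.

## Progress-curve and concentration fits

The exponential-plus-linear model is fitted by Levenberg–Marquardt
(lmfit) on the window starting 2 s after injection (the stated
convention), time re-zeroed at injection, with secant-slope initial
guesses from the first and last fifths of the window. A curve whose early
and late slopes agree to 10⁻⁶ (relative) is treated as a line and k_app
flagged unidentifiable rather than fitted; k_app is also flagged when it
hits its bounds or its SE exceeds its value. Residual activity is the
ratio of centred 30 s regression slopes at injection+350 s versus just
before injection (the window length is a package choice — not specified
by the underlying protocol — and configurable), clipped to [0, 1.05].
The k_app–concentration hyperbola is fitted by least squares, weighted
1/SE² when SEs are given; when every concentration is ≤ 0.1×K̂_M only
the ratio k_lock/K_M is identified and the fit is flagged.

## Stall-and-release

P_ON is reported in percent with SD = √(P_ON(100−P_ON)/N); the unit of
analysis (trials or molecules) is selectable because both conventions
appear in manipulation work, and the choice is recorded in the estimate.
Excluded trials must carry an explicit reason string and are tallied, not
silently dropped.

The activation hazard is parameterised as
`k_act(θ) = k_max · logistic((θ_thr − θ)/w)` plus a spontaneous hazard
1/τ_spont: zero for stalls shallower than the threshold, saturating
beyond. This functional form is a package construct — the measurements
constrain only sampled (angle, time) points — and defaults
(θ_thr = −180°, k_max = 0.55 s⁻¹, w = 15°, τ_spont = ∞ for the wild-type
inhibitor) reproduce the characteristic phenotype: no activation up to
−120°, ~60% at −200° for 2 s, > 90% at −320° for 5 s, and ~3%
spontaneous release in 2 s when τ_spont = 60 s (destabilised variant).
A manipulation integrates the hazard along the full clamped path
(ramp–stall–ramp at 0.5 rps by default, trapezoid quadrature on a ≤ 1°
grid); `predict_pon` summarises the stall-only hazard unless a ramp rate
is supplied. The surface fit maximises the binomial likelihood over
(θ_thr, k_max) with w and τ_spont held fixed (they are rarely identified
by sampled designs), multi-started Nelder–Mead, with a 95%
profile-likelihood interval for the threshold obtained by walking outward
in w/10 steps and interpolating the deviance crossing at 1.92. Complete
separation (all-ON/all-OFF) is flagged and pins k_max at its boundary.
Simulation checks show the profile interval is well calibrated (deviance
at the generating threshold matches χ²₁).

Release outcomes are scored ON when the median-smoothed post-release
trace advances ≥ 360° within a 10 s window (chosen because rebinding at
µM inhibitor takes ~18 s and rarely truncates the window), OFF when it
never leaves a ±45° band around the pause angle, and excluded otherwise.

## Energetics

Stall work is τ·θ (pN·nm, θ in radians); molar work multiplies by
10⁻²¹·N_A; the minimum pmf voltage is 2πτ·10⁻²¹/(n·e) in mV. CODATA
values of N_A and e are used; rounding to 2 significant figures is a
reporting helper only and never applied to stored values. Whether
friction or elastic losses should be added to the ejection-energy
estimate is an open question deliberately left out.

## Problem sizes

The test suite and acceptance script use: 10 random parameter sets for
the scheme oracle; 200 replicate curves (2 mAU noise) for progress-curve
recovery plus a 6-point concentration series; 500 draws per dwell-time
fit; 50 trajectories of 60 s at 30 fps (noise 5/8/10°) for the pause
round trip and 25 binding-limited molecules of 300 s for the Δθ
recovery; 200 trials per (angle, time) cell over 7 angles × 3 stall
times for the activation surface. These sizes give standard errors small
enough to resolve the biases each test guards against while keeping the
whole battery to a few seconds.

## Known limitations

* No drag or compliance: observed step dynamics are instantaneous, so
  analyses that depend on step shape cannot be exercised.
* The ADP-inhibition entry statistics (per-turn probability) and the
  catalytic dwell time are placeholders at saturating ATP; they shape
  test regimes, not scientific conclusions.
* The decrease-then-recover ensemble kinetics of the shortest inhibitor
  truncation has no stated mechanism and is deliberately not fitted.
* The activation-surface functional form is not mechanistic; fitted
  thresholds are comparable across datasets only under the same form.
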