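"""Stochastic generative model of single-molecule F1 rotation and its assays.

The simulator emulates the three kinds of record the downstream analyses
consume, with known ground truth:

* **Rotary trajectories** — the gamma subunit advances in 120 deg steps,
  dwelling at ATP-binding angles (0/120/240 deg, exponential waits at rate
  ``k_bind = atp_binding_rate_constant * atp_conc``) and at catalytic angles
  (+80 deg, exponential waits at ``catalytic_rate``). ADP-inhibited pauses
  (tens of seconds) enter at catalytic angles as a per-dwell Bernoulli
  event; inhibitor (IF1) arrest enters as a continuous hazard while the
  motor occupies a catalytic dwell and holds the angle for an
  exponentially distributed time (infinite for the wild-type inhibitor,
  which never releases spontaneously). The observed angle is the latent
  staircase plus i.i.d. Gaussian noise per frame.

* **Ensemble progress curves** — the two-step slow-binding scheme
  F1 + I <-> F1.I -> F1.I(locked), solved as a linear three-state system
  under pseudo-first-order inhibitor excess; the NADH-coupled absorbance
  decreases in proportion to the cumulative turnover of the still-active
  species (free + encounter complex).

* **Manipulation outcomes** — a magnetic-tweezers ramp-stall-ramp angle
  clamp; the probability that the inhibitor is ejected (ON) is the
  survival complement of the activation-hazard integral along the clamped
  path.

Random numbers are drawn in a fixed order (event loop first, in simulated
time order; then one block of per-frame observation noise), so a given
(seed, config) pair reproduces a trace bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import AngleTrace, ProgressCurve, StallTrial, TraceSegment

__all__ = [
    "MotorConfig",
    "ObservationConfig",
    "EnsembleAssayConfig",
    "ManipulationProtocol",
    "simulate_trajectory",
    "simulate_ensemble_progress",
    "species_fractions",
    "apply_manipulation",
    "simulate_release_trace",
    "ground_truth_pauses",
    "expected_rotating_time",
]


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass
class MotorConfig:
    """Kinetic scheme of the rotary motor.

    Defaults describe bovine MF1 at 1 mM ATP with 3 uM wild-type inhibitor:
    ATP binding is effectively instantaneous, catalytic dwells last ~5 ms,
    ADP-inhibited pauses of ~20 s occur on ~1% of turns, and the inhibitor
    arrests the motor irreversibly (infinite pause) after ~20 s of rotation.
    """

    binding_angles: tuple = (0.0, 120.0, 240.0)
    catalytic_offset: float = 80.0  # deg past the binding angle
    atp_binding_rate_constant: float = 3.0e7  # /M/s
    atp_conc: float = 1.0e-3  # M
    catalytic_rate: float = 200.0  # /s  (placeholder: unresolved at 30 fps)
    adp_entry_prob_per_turn: float = 0.002
    adp_exit_taus: tuple = (20.0,)  # s
    adp_exit_weights: tuple = (1.0,)
    if1_entry_rate: float = 0.05  # /s while in a catalytic dwell
    if1_pause_tau: float = math.inf  # s; inf = irreversible (wild type)
    allow_if1_during_adp: bool = False
    rotation_direction_sign: int = +1  # +1 counterclockwise (hydrolysis)

    def __post_init__(self) -> None:
        for name in ("atp_binding_rate_constant", "atp_conc", "catalytic_rate"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if not (0.0 <= self.adp_entry_prob_per_turn <= 1.0):
            raise ValueError("adp_entry_prob_per_turn must be in [0, 1]")
        if self.if1_entry_rate < 0 or not math.isfinite(self.if1_entry_rate):
            raise ValueError("if1_entry_rate must be finite and non-negative")
        if self.if1_pause_tau <= 0:
            raise ValueError("if1_pause_tau must be positive (may be inf)")
        if len(self.adp_exit_taus) != len(self.adp_exit_weights):
            raise ValueError("adp_exit_taus and adp_exit_weights length mismatch")
        if any(t <= 0 or not math.isfinite(t) for t in self.adp_exit_taus):
            raise ValueError("adp_exit_taus must be finite and positive")
        if any(w < 0 for w in self.adp_exit_weights) or sum(self.adp_exit_weights) <= 0:
            raise ValueError("adp_exit_weights must be non-negative with positive sum")
        angs = sorted(a % 360.0 for a in self.binding_angles)
        if len(angs) != 3 or any(
            abs(a - (angs[0] + 120.0 * i)) > 1e-9 for i, a in enumerate(angs)
        ):
            raise ValueError("binding_angles must be congruent to a, a+120, a+240 mod 360")
        if self.rotation_direction_sign not in (+1, -1):
            raise ValueError("rotation_direction_sign must be +1 or -1")

    @property
    def binding_rate(self) -> float:
        """Pseudo-first-order ATP binding rate, /s."""
        return self.atp_binding_rate_constant * self.atp_conc

    @property
    def adp_entry_prob_per_dwell(self) -> float:
        """Per-catalytic-dwell Bernoulli probability equivalent to the
        configured per-turn probability (three catalytic dwells per turn)."""
        p = self.adp_entry_prob_per_turn
        return 1.0 - (1.0 - p) ** (1.0 / 3.0)


@dataclass
class ObservationConfig:
    """Camera model: sampling rate, angular noise and record length."""

    fps: float = 30.0
    angle_noise_sd: float = 5.0  # deg
    duration: float = 60.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.fps) and self.fps > 0):
            raise ValueError("fps must be positive")
        if self.angle_noise_sd < 0:
            raise ValueError("angle_noise_sd must be non-negative")
        if self.duration < 1.0 / self.fps:
            raise ValueError("duration must cover at least one frame")


@dataclass
class EnsembleAssayConfig:
    """NADH-coupled ATPase assay with slow-binding inhibitor injection.

    The extinction coefficient default (6220 /M/cm at 340 nm, 1 cm path)
    is the standard NADH value; ``initial_absorbance`` corresponds to
    ~0.2 mM NADH.
    """

    if1_conc: float = 3.0e-6  # M (in large excess over enzyme)
    k_on: float = 1.0e6  # /M/s
    k_off: float = 0.02  # /s
    k_lock: float = 1.0 / 30.0  # /s; locked-state mean time 30 s
    initial_rate_per_enzyme: float = 100.0  # ATP/s per enzyme
    enzyme_conc: float = 1.0e-9  # M
    nadh_extinction_coefficient: float = 6220.0  # /M/cm
    path_length: float = 1.0  # cm
    injection_time: float = 180.0  # s
    duration: float = 600.0  # s
    sampling_interval: float = 1.0  # s
    initial_absorbance: float = 1.2  # AU
    absorbance_noise_sd: float = 0.0  # AU, per-sample Gaussian

    def __post_init__(self) -> None:
        if self.if1_conc < 0:
            raise ValueError("if1_conc must be non-negative")
        for name in ("k_on", "k_off", "k_lock", "initial_rate_per_enzyme",
                     "enzyme_conc", "nadh_extinction_coefficient", "path_length",
                     "sampling_interval"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if not (0 <= self.injection_time < self.duration):
            raise ValueError("injection_time must lie within [0, duration)")

    @property
    def km(self) -> float:
        """Half-saturation concentration (k_off + k_lock) / k_on, M."""
        return (self.k_off + self.k_lock) / self.k_on


@dataclass
class ManipulationProtocol:
    """Magnetic-tweezers angle-clamp protocol.

    ``target_angle`` is signed relative to the inhibited pause angle
    (counterclockwise positive); its sign must agree with
    ``direction_sign`` (-1 clockwise / synthesis, +1 counterclockwise /
    hydrolysis).
    """

    protocol_kind: str = "stall_and_release"  # or 'full_rotation'
    direction_sign: int = -1
    target_angle: float = -200.0  # deg relative to the pause angle
    ramp_rate: float = 0.5  # revolutions per second
    stall_duration: float = 2.0  # s

    def __post_init__(self) -> None:
        if self.protocol_kind not in ("full_rotation", "stall_and_release"):
            raise ValueError("protocol_kind must be full_rotation or stall_and_release")
        if self.direction_sign not in (+1, -1):
            raise ValueError("direction_sign must be +1 or -1")
        if self.ramp_rate <= 0:
            raise ValueError("ramp_rate must be positive")
        if self.target_angle != 0 and int(np.sign(self.target_angle)) != self.direction_sign:
            raise ValueError(
                "angle-convention mismatch: sign of target_angle disagrees with direction_sign"
            )
        if self.protocol_kind == "full_rotation" and abs(self.target_angle) != 360.0:
            raise ValueError("full_rotation requires |target_angle| = 360")
        if self.stall_duration < 0:
            raise ValueError("stall_duration must be non-negative")


# --------------------------------------------------------------------------
# single-molecule trajectory
# --------------------------------------------------------------------------

def _sample_adp_pause(motor: MotorConfig, rng: np.random.Generator) -> float:
    w = np.asarray(motor.adp_exit_weights, dtype=float)
    w = w / w.sum()
    i = int(rng.choice(len(w), p=w))
    return float(rng.exponential(motor.adp_exit_taus[i]))


def simulate_trajectory(motor: MotorConfig, obs: ObservationConfig) -> AngleTrace:
    """Simulate one bead-rotation record.

    Returns an :class:`AngleTrace` sampled on the camera grid, with the
    ground-truth latent dwell sequence attached as ``trace.segments``
    (classes ``binding``, ``catalytic``, ``adp``, ``if1``).
    """
    rng = np.random.default_rng(obs.seed)
    sign = motor.rotation_direction_sign
    k_bind = motor.binding_rate
    k_cat = motor.catalytic_rate
    r_if1 = motor.if1_entry_rate
    p_adp = motor.adp_entry_prob_per_dwell

    segments: list[TraceSegment] = []
    t = 0.0
    base = motor.binding_angles[0] % 360.0
    step_index = 0  # number of completed 120-deg steps
    duration = obs.duration
    terminal_if1 = False

    def bind_angle() -> float:
        return base + sign * 120.0 * step_index

    while t < duration and not terminal_if1:
        theta_b = bind_angle()
        # ATP-binding dwell
        d = rng.exponential(1.0 / k_bind)
        segments.append(TraceSegment(t, t + d, "binding", theta_b))
        t += d
        if t >= duration:
            break
        theta_c = theta_b + sign * motor.catalytic_offset
        # catalytic dwell with competing inhibitor entry
        in_cat = True
        while in_cat and t < duration:
            t_exit = rng.exponential(1.0 / k_cat)
            t_if1 = rng.exponential(1.0 / r_if1) if r_if1 > 0 else math.inf
            if t_if1 < t_exit:
                segments.append(TraceSegment(t, t + t_if1, "catalytic", theta_c))
                t += t_if1
                pause = (
                    rng.exponential(motor.if1_pause_tau)
                    if math.isfinite(motor.if1_pause_tau)
                    else math.inf
                )
                if math.isinf(pause) or t + pause >= duration:
                    segments.append(
                        TraceSegment(t, duration, "if1", theta_c)
                    )
                    terminal_if1 = True
                    in_cat = False
                else:
                    segments.append(TraceSegment(t, t + pause, "if1", theta_c))
                    t += pause
                    # memoryless: still in the catalytic dwell after release
            else:
                segments.append(TraceSegment(t, t + t_exit, "catalytic", theta_c))
                t += t_exit
                in_cat = False
        if terminal_if1 or t >= duration:
            break
        # ADP-inhibited pause at the catalytic angle, per-dwell Bernoulli
        if p_adp > 0 and rng.random() < p_adp:
            d_adp = _sample_adp_pause(motor, rng)
            if motor.allow_if1_during_adp and r_if1 > 0:
                t_if1 = rng.exponential(1.0 / r_if1)
                if t_if1 < d_adp:
                    segments.append(TraceSegment(t, t + t_if1, "adp", theta_c))
                    t += t_if1
                    pause = (
                        rng.exponential(motor.if1_pause_tau)
                        if math.isfinite(motor.if1_pause_tau)
                        else math.inf
                    )
                    end = duration if math.isinf(pause) else min(t + pause, duration)
                    segments.append(TraceSegment(t, end, "if1", theta_c))
                    if math.isinf(pause) or t + pause >= duration:
                        terminal_if1 = True
                    t = end
                    if terminal_if1:
                        break
                    step_index += 1
                    continue
            segments.append(TraceSegment(t, min(t + d_adp, duration), "adp", theta_c))
            t += d_adp
        step_index += 1

    # clip segments to the record and drop empty ones
    clipped = [
        TraceSegment(s.start, min(s.end, duration), s.kind, s.latent_angle)
        for s in segments
        if s.start < duration and min(s.end, duration) > s.start
    ]

    n_frames = int(round(duration * obs.fps))
    times = np.arange(n_frames) / obs.fps
    starts = np.array([s.start for s in clipped])
    latents = np.array([s.latent_angle for s in clipped])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(clipped) - 1)
    latent = latents[idx]
    noise = (
        rng.normal(0.0, obs.angle_noise_sd, n_frames)
        if obs.angle_noise_sd > 0
        else np.zeros(n_frames)
    )
    return AngleTrace(
        time=times,
        angle=latent + noise,
        fps=obs.fps,
        annotations={"seed": obs.seed, "terminal_if1": terminal_if1},
        segments=clipped,
    )


def ground_truth_pauses(trace: AngleTrace, min_duration: float = 1.0) -> list[TraceSegment]:
    """Merge contiguous ground-truth segments sharing a latent angle and
    return those lasting at least ``min_duration`` seconds.

    A catalytic dwell followed by an ADP or inhibitor pause at the same
    angle is one observable pause; this helper gives the observable
    ground truth that pause detection should recover.
    """
    if trace.segments is None:
        raise ValueError("trace carries no ground-truth segments")
    merged: list[list] = []
    for s in trace.segments:
        if merged and abs(merged[-1][2] - s.latent_angle) < 1e-9:
            merged[-1][1] = s.end
            merged[-1][3].append(s.kind)
        else:
            merged.append([s.start, s.end, s.latent_angle, [s.kind]])
    out = []
    for start, end, ang, kinds in merged:
        if end - start >= min_duration:
            kind = "if1" if "if1" in kinds else ("adp" if "adp" in kinds else kinds[0])
            out.append(TraceSegment(start, end, kind, ang))
    return out


def expected_rotating_time(motor: MotorConfig) -> float:
    """Exact mean time from rotation start to inhibitor arrest (ADP off).

    Each catalytic visit ends in arrest with probability
    q = r/(r + k_cat); the expected number of visits is 1/q and each visit
    costs one binding dwell plus one competing-exponential wait.
    """
    r = motor.if1_entry_rate
    if r <= 0:
        return math.inf
    q = r / (r + motor.catalytic_rate)
    per_visit = 1.0 / motor.binding_rate + 1.0 / (r + motor.catalytic_rate)
    return per_visit / q


# --------------------------------------------------------------------------
# ensemble three-state scheme
# --------------------------------------------------------------------------

def _scheme_matrix(a: float, k_off: float, k_lock: float) -> np.ndarray:
    """Rate matrix for [free, encounter complex, locked] fractions;
    ``a`` is the pseudo-first-order association rate k_on * [I]."""
    return np.array(
        [
            [-a, k_off, 0.0],
            [a, -(k_off + k_lock), 0.0],
            [0.0, k_lock, 0.0],
        ]
    )


def species_fractions(cfg: EnsembleAssayConfig, t_after: np.ndarray) -> np.ndarray:
    """Species fractions [free, intermediate, locked] at times ``t_after``
    (seconds after inhibitor injection), by eigendecomposition of the
    linear scheme.

    Returns an array of shape (len(t_after), 3).
    """
    t_after = np.atleast_1d(np.asarray(t_after, dtype=float))
    K = _scheme_matrix(cfg.k_on * cfg.if1_conc, cfg.k_off, cfg.k_lock)
    lam, V = np.linalg.eig(K)
    c = np.linalg.solve(V, np.array([1.0, 0.0, 0.0]))
    # p(t) = V @ (c * exp(lam t)); all eigenvalues are real and <= 0 here
    expt = np.exp(np.outer(t_after, lam))
    p = np.real(expt * c @ V.T)
    return np.clip(p, 0.0, 1.0)


def _cumulative_active(cfg: EnsembleAssayConfig, t_after: np.ndarray) -> np.ndarray:
    """Integral over [0, t] of the catalytically active fraction
    (free + intermediate), via the same eigendecomposition."""
    t_after = np.atleast_1d(np.asarray(t_after, dtype=float))
    K = _scheme_matrix(cfg.k_on * cfg.if1_conc, cfg.k_off, cfg.k_lock)
    lam, V = np.linalg.eig(K)
    c = np.linalg.solve(V, np.array([1.0, 0.0, 0.0]))
    u = np.array([1.0, 1.0, 0.0])  # active species indicator
    w = (u @ V) * c  # contribution of each mode to the active fraction
    scale = max(abs(lam).max(), 1.0)
    out = np.zeros_like(t_after)
    for wj, lj in zip(w, lam):
        if abs(lj) < 1e-14 * scale:
            out = out + np.real(wj) * t_after
        else:
            out = out + np.real(wj * (np.exp(lj * t_after) - 1.0) / lj)
    return out


def simulate_ensemble_progress(
    cfg: EnsembleAssayConfig, seed: Optional[int] = None
) -> ProgressCurve:
    """Absorbance-vs-time curve of the coupled assay with inhibitor
    injection at ``cfg.injection_time``.

    Before injection the enzyme turns over at the uninhibited rate and the
    absorbance falls linearly; afterwards the instantaneous rate is
    proportional to the still-active species fraction and the absorbance
    follows the integrated three-state solution. Gaussian observation
    noise of ``cfg.absorbance_noise_sd`` AU is added when a seed is given
    or the sd is positive.
    """
    times = np.arange(0.0, cfg.duration + 0.5 * cfg.sampling_interval, cfg.sampling_interval)
    v_au = (
        cfg.nadh_extinction_coefficient
        * cfg.path_length
        * cfg.initial_rate_per_enzyme
        * cfg.enzyme_conc
    )  # AU/s consumed at full activity
    absorbance = cfg.initial_absorbance - v_au * np.minimum(times, cfg.injection_time)
    post = times > cfg.injection_time
    if post.any():
        c = _cumulative_active(cfg, times[post] - cfg.injection_time)
        absorbance[post] = cfg.initial_absorbance - v_au * (cfg.injection_time + c)
    if cfg.absorbance_noise_sd > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, cfg.absorbance_noise_sd, times.shape)
    return ProgressCurve(time=times, absorbance=absorbance, injection_time=cfg.injection_time)


# --------------------------------------------------------------------------
# manipulation
# --------------------------------------------------------------------------

def apply_manipulation(
    pause_angle: float,
    protocol: ManipulationProtocol,
    model,
    seed: Optional[int] = None,
    molecule_id: str = "sim",
    condition: str = "",
) -> StallTrial:
    """Clamp an inhibited motor along a ramp-stall-ramp path and draw the
    release outcome.

    The angle path is a linear ramp at ``protocol.ramp_rate`` from the
    pause angle to ``pause + target_angle``, a hold of
    ``protocol.stall_duration``, and a symmetric ramp back. The ON
    probability is ``1 - exp(-H)`` where ``H`` integrates the activation
    hazard ``model.k_act(theta)`` plus the spontaneous-release hazard
    ``1/model.tau_spont`` along the whole clamped path.

    ``model`` is a :class:`~if1kinetics.stall_release.ActivationModel`.
    """
    from .stall_release import path_hazard  # local import to avoid cycles

    rng = np.random.default_rng(seed)
    H = path_hazard(
        model,
        stall_angle=protocol.target_angle,
        stall_time=protocol.stall_duration,
        ramp_rate=protocol.ramp_rate,
    )
    p_on = 1.0 - math.exp(-H)
    on = bool(rng.random() < p_on)
    return StallTrial(
        molecule_id=molecule_id,
        stall_angle=protocol.target_angle,
        stall_duration=protocol.stall_duration,
        outcome="ON" if on else "OFF",
        condition=condition,
        release_angle=None if on else pause_angle,
    )


def simulate_release_trace(
    outcome: str,
    pause_angle: float,
    fps: float = 30.0,
    duration: float = 10.0,
    noise_sd: float = 5.0,
    rotation_rate_rps: float = 2.0,
    seed: Optional[int] = None,
) -> AngleTrace:
    """Synthesize the post-release record used to score a trial.

    ON: steady counterclockwise rotation from the pause angle at
    ``rotation_rate_rps``; OFF: the angle stays at the pause angle. Both
    carry Gaussian observation noise.
    """
    if outcome not in ("ON", "OFF"):
        raise ValueError("outcome must be ON or OFF")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fps))
    t = np.arange(n) / fps
    latent = pause_angle + (360.0 * rotation_rate_rps * t if outcome == "ON"
                            else np.zeros(n))
    noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
    return AngleTrace(time=t, angle=latent + noise, fps=fps,
                      annotations={"ground_truth_outcome": outcome})
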