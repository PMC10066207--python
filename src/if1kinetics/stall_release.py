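"""Stall-and-release activation statistics.

A magnetic-tweezers trial clamps an inhibited motor at a signed stall
angle (clockwise/synthesis negative) for a set time and scores whether
rotation resumes on release (ON) or the motor returns to its pause (OFF).
This module estimates P_ON with its binomial SD, models the activation
hazard as a function of angle, fits that angle-time surface to trial
tables by binomial maximum likelihood, and classifies release outcomes
from post-release traces.

The hazard parameterisation is a package construct — the measurements
constrain only sampled (angle, time) points — and reports label it as
such: k_act(theta) = k_max * logistic((threshold - theta) / width), zero
for stalls shallower than the threshold and saturating at k_max beyond,
plus a variant-dependent spontaneous-release hazard 1/tau_spont.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator

from .containers import ActivationEstimate, AngleTrace, StallTrial

__all__ = [
    "ActivationModel",
    "estimate_pon",
    "predict_pon",
    "path_hazard",
    "ActivationSurfaceFitter",
    "fit_activation_surface",
    "classify_release_outcome",
    "trials_to_frame",
]


# --------------------------------------------------------------------------
# P_ON estimation
# --------------------------------------------------------------------------

def trials_to_frame(trials: Sequence[StallTrial]) -> pd.DataFrame:
    """Tabulate trials as a DataFrame (one row per trial)."""
    return pd.DataFrame(
        {
            "molecule_id": [t.molecule_id for t in trials],
            "stall_angle": [t.stall_angle for t in trials],
            "stall_s": [t.stall_duration for t in trials],
            "outcome": [t.outcome for t in trials],
            "condition": [t.condition for t in trials],
            "exclusion_reason": [t.exclusion_reason for t in trials],
        }
    )


def estimate_pon(
    trials: Sequence[StallTrial],
    group_by: Sequence[str] = ("stall_angle", "stall_s"),
    unit: str = "trials",
) -> tuple:
    """Estimate P_ON (percent) per group with the binomial SD
    sqrt(P_ON * (100 - P_ON) / N).

    ``unit`` selects the unit of analysis: ``'trials'`` counts every
    non-excluded trial; ``'molecules'`` counts each molecule once and
    scores it ON if any of its trials is ON. Excluded trials are dropped
    and tallied in the returned report.

    Returns ``(estimates, report)`` where ``estimates`` is a list of
    :class:`ActivationEstimate` and ``report`` summarises exclusions.
    """
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    excluded = df[df["outcome"] == "excluded"]
    kept = df[df["outcome"] != "excluded"]
    report = {
        "n_excluded": int(len(excluded)),
        "exclusion_reasons": excluded["exclusion_reason"].value_counts().to_dict()
        if len(excluded)
        else {},
    }
    group_by = list(group_by)
    estimates = []
    grouped = kept.groupby(group_by) if group_by else [((), kept)]
    for key, g in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        if unit == "molecules":
            per_mol = g.groupby("molecule_id")["outcome"].apply(lambda s: (s == "ON").any())
            n, n_on = int(len(per_mol)), int(per_mol.sum())
        elif unit == "trials":
            n, n_on = int(len(g)), int((g["outcome"] == "ON").sum())
        else:
            raise ValueError("unit must be 'trials' or 'molecules'")
        if n == 0:
            raise ValueError(f"empty group {dict(zip(group_by, key))}")
        p = 100.0 * n_on / n
        sd = math.sqrt(p * (100.0 - p) / n)
        estimates.append(
            ActivationEstimate(p_on=p, sd=sd, n=n, group=dict(zip(group_by, key)))
        )
    return estimates, report


# --------------------------------------------------------------------------
# activation model
# --------------------------------------------------------------------------

@dataclass
class ActivationModel:
    """Angle-dependent activation hazard with a spontaneous baseline.

    Defaults reproduce the wild-type inhibitor phenotype: no activation
    for clockwise stalls shallower than ~180 deg, a saturating hazard of
    ~0.55 /s beyond, and no spontaneous release (tau_spont infinite).
    The logistic form is a fitting construct, not a measured shape.
    """

    threshold_angle: float = -180.0  # deg; clockwise displacement where
    # activation becomes possible (signed, clockwise negative)
    k_max: float = 0.55  # /s, saturating hazard
    width: float = 15.0  # deg, logistic ramp width
    tau_spont: float = math.inf  # s; finite for destabilised variants

    def __post_init__(self) -> None:
        if self.k_max < 0:
            raise ValueError("k_max must be non-negative")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.tau_spont <= 0:
            raise ValueError("tau_spont must be positive (may be inf)")

    def k_act(self, theta) -> np.ndarray:
        """Activation hazard (/s) at signed stall angle ``theta`` deg."""
        theta = np.asarray(theta, dtype=float)
        return self.k_max * expit((self.threshold_angle - theta) / self.width)

    @property
    def spont_rate(self) -> float:
        return 0.0 if math.isinf(self.tau_spont) else 1.0 / self.tau_spont


def path_hazard(
    model: ActivationModel,
    stall_angle: float,
    stall_time: float,
    ramp_rate: Optional[float] = None,
    n_grid: int = 512,
) -> float:
    """Integrated activation hazard along a clamp path.

    With ``ramp_rate`` (revolutions per second) the path is a ramp from 0
    to ``stall_angle``, the hold, and the ramp back; without it only the
    hold contributes. The spontaneous hazard acts for the whole clamped
    time.
    """
    hold = (float(model.k_act(stall_angle)) + model.spont_rate) * stall_time
    if ramp_rate is None or stall_angle == 0.0:
        return hold
    omega = 360.0 * ramp_rate  # deg/s
    phis = np.linspace(0.0, stall_angle, n_grid)
    ramp_act = float(np.trapezoid(model.k_act(phis), phis)) / (np.sign(stall_angle) * omega)
    ramp_time = abs(stall_angle) / omega
    return hold + 2.0 * (abs(ramp_act) + model.spont_rate * ramp_time)


def predict_pon(
    model: ActivationModel,
    stall_angle: float,
    stall_time: float,
    ramp_rate: Optional[float] = None,
) -> float:
    """Predicted P_ON (percent): 100 * (1 - exp(-integrated hazard)).

    By default only the hold contributes, i.e.
    100 * (1 - exp(-(k_act(theta) + 1/tau_spont) * t)); pass ``ramp_rate``
    to include the clamp ramps as in a simulated manipulation.
    """
    H = path_hazard(model, stall_angle, stall_time, ramp_rate=ramp_rate)
    return 100.0 * (1.0 - math.exp(-H))


# --------------------------------------------------------------------------
# surface fitting
# --------------------------------------------------------------------------

class ActivationSurfaceFitter(BaseEstimator):
    """Binomial maximum-likelihood fit of the activation surface.

    ``fit(X, y)`` takes per-trial predictors ``X = [[stall_angle,
    stall_time], ...]`` and binary outcomes ``y`` (1 = ON). The free
    parameters are the threshold angle and the saturating hazard
    ``k_max``; the ramp width and spontaneous time constant are held at
    the values supplied to the constructor (profiling them as well is
    rarely identified by sampled designs). ``ramp_rate`` must match the
    protocol that produced the trials so the likelihood integrates the
    same clamp path.

    Attributes (after ``fit``): ``model_``, ``threshold_ci_`` (95%
    profile-likelihood interval), ``separation_flag_`` (all-ON/all-OFF
    data drive k_max to a bound), ``nll_``.
    """

    def __init__(self, width: float = 15.0, tau_spont: float = math.inf,
                 ramp_rate: Optional[float] = None):
        self.width = width
        self.tau_spont = tau_spont
        self.ramp_rate = ramp_rate

    # internal -------------------------------------------------------------
    def _p_on(self, thr: float, kmax: float, ang: np.ndarray, tt: np.ndarray
              ) -> np.ndarray:
        m = ActivationModel(threshold_angle=thr, k_max=kmax, width=self.width,
                            tau_spont=self.tau_spont)
        H = np.array([path_hazard(m, a, t, ramp_rate=self.ramp_rate, n_grid=128)
                      for a, t in zip(ang, tt)])
        return 1.0 - np.exp(-H)

    def _nll(self, params: np.ndarray, ang, tt, y, counts) -> float:
        thr, log_k = params
        p = np.clip(self._p_on(thr, math.exp(log_k), ang, tt), 1e-12, 1 - 1e-12)
        return -float(np.sum(counts * (y * np.log(p) + (1 - y) * np.log(1 - p))))

    def fit(self, X, y) -> "ActivationSurfaceFitter":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2 or y.shape[0] != X.shape[0]:
            raise ValueError("X must be (n, 2) [stall_angle, stall_time] matching y")
        if np.unique(X[:, 0]).size < 3 or np.unique(X[:, 1]).size < 2:
            raise ValueError("need trials at >= 3 angles and >= 2 stall times")
        # collapse identical cells for speed
        df = pd.DataFrame({"a": X[:, 0], "t": X[:, 1], "y": y})
        cells = df.groupby(["a", "t", "y"]).size().reset_index(name="n")
        ang = cells["a"].to_numpy()
        tt = cells["t"].to_numpy()
        yy = cells["y"].to_numpy()
        counts = cells["n"].to_numpy()

        self.separation_flag_ = bool(y.min() == y.max())
        thr0 = float(np.median(np.unique(ang)))
        best = None
        for thr_init in (thr0, float(ang.min()) * 0.67, -180.0):
            for k_init in (0.1, 0.5, 2.0):
                opt = minimize(
                    self._nll, np.array([thr_init, math.log(k_init)]),
                    args=(ang, tt, yy, counts), method="Nelder-Mead",
                    options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000},
                )
                if best is None or opt.fun < best.fun:
                    best = opt
        thr_hat, log_k_hat = best.x
        k_hat = math.exp(log_k_hat)
        if self.separation_flag_ and y.max() == 0:
            k_hat = 0.0  # all-OFF: hazard pinned at zero
        self.model_ = ActivationModel(threshold_angle=float(thr_hat),
                                      k_max=float(k_hat), width=self.width,
                                      tau_spont=self.tau_spont)
        self.nll_ = float(best.fun)

        # 95% profile-likelihood interval for the threshold
        self.threshold_ci_ = self._profile_threshold(ang, tt, yy, counts,
                                                     thr_hat, log_k_hat)
        return self

    def _profile_threshold(self, ang, tt, yy, counts, thr_hat, log_k_hat,
                           crit: float = 1.92) -> tuple:
        """95% profile-likelihood interval: walk outward from the MLE in
        steps of width/10 until the profiled deviance exceeds ``crit``
        (chi2_1 / 2), interpolating the crossing linearly."""
        step = max(self.width / 10.0, 0.5)
        span = max(float(np.ptp(ang)), 120.0)

        def profile_nll(thr: float) -> float:
            opt = minimize(lambda lk: self._nll(np.array([thr, lk[0]]),
                                                ang, tt, yy, counts),
                           np.array([log_k_hat]), method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-8})
            return float(opt.fun)

        def walk(direction: int) -> float:
            prev_thr, prev_d = thr_hat, 0.0
            for i in range(1, int(span / step) + 1):
                thr = thr_hat + direction * i * step
                d = profile_nll(thr) - self.nll_
                if d > crit:
                    frac = (crit - prev_d) / (d - prev_d)
                    return prev_thr + frac * (thr - prev_thr)
                prev_thr, prev_d = thr, d
            return direction * math.inf  # flat likelihood out to the span

        return (walk(-1), walk(+1))

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._p_on(self.model_.threshold_angle, self.model_.k_max,
                          X[:, 0], X[:, 1])


def fit_activation_surface(
    trials: Sequence[StallTrial],
    width: float = 15.0,
    tau_spont: float = math.inf,
    ramp_rate: Optional[float] = None,
) -> ActivationSurfaceFitter:
    """Fit the activation surface from a trial table (excluded trials are
    dropped). Returns the fitted :class:`ActivationSurfaceFitter`."""
    kept = [t for t in trials if t.outcome != "excluded"]
    X = np.array([[t.stall_angle, t.stall_duration] for t in kept])
    y = np.array([1.0 if t.outcome == "ON" else 0.0 for t in kept])
    return ActivationSurfaceFitter(width=width, tau_spont=tau_spont,
                                   ramp_rate=ramp_rate).fit(X, y)


# --------------------------------------------------------------------------
# release-outcome classification
# --------------------------------------------------------------------------

def classify_release_outcome(
    trace: AngleTrace,
    pause_angle: float,
    decision_window: float = 10.0,
    pause_window: float = 45.0,
    revolution: float = 360.0,
) -> str:
    """Score a post-release record as ON, OFF, or 'excluded'.

    ON: the (median-smoothed) angle advances at least one revolution past
    the pause angle within the decision window. OFF: it never leaves the
    pause band. Anything in between — partial advance without a full
    revolution — is excluded as ambiguous.
    """
    m = trace.time - trace.time[0] <= decision_window
    y = median_filter(trace.angle[m], size=5, mode="nearest")
    advance = y - pause_angle
    if np.max(advance) >= revolution:
        return "ON"
    if np.max(np.abs(advance)) <= pause_window:
        return "OFF"
    return "excluded"
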