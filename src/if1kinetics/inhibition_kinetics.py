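"""Ensemble slow-binding inhibition analysis.

The two-step scheme F1 + I <-> F1.I -> F1.I(locked) makes the post-injection
progress curve of a coupled assay an exponential-plus-linear function of
time,

    y(t) - y0 = Vinf * t + (V0 - Vinf) / k_app * (1 - exp(-k_app * t)),

with the apparent inactivation rate hyperbolic in inhibitor concentration,

    k_app = k_lock * [I] / (K_M + [I]),      K_M = (k_off + k_lock) / k_on.

This module fits the progress curve, the concentration dependence, and the
residual (plateau) activity, and converts absorbance slopes to turnover.
V0 and Vinf are signed absorbance slopes (negative while NADH is consumed);
ratios of rates use magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lmfit import Model, Parameters
from scipy.stats import linregress
from sklearn.base import BaseEstimator

from .containers import ProgressCurve

__all__ = [
    "SchemeParams",
    "ProgressFit",
    "ProgressCurveFitter",
    "KappConcentrationFitter",
    "fit_progress_curve",
    "fit_kapp_vs_conc",
    "residual_activity",
    "absorbance_slope_to_turnover",
    "kapp_hyperbola",
]


@dataclass(frozen=True)
class SchemeParams:
    """Rate constants of the two-step inhibition scheme.

    ``km`` is derived, never stored independently, so the identity
    K_M = (k_off + k_lock) / k_on holds exactly by construction.
    """

    k_on: float  # /M/s
    k_off: float  # /s
    k_lock: float  # /s

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_lock"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive")

    @property
    def km(self) -> float:
        return (self.k_off + self.k_lock) / self.k_on

    def kapp(self, conc: float) -> float:
        """Apparent inactivation rate at inhibitor concentration ``conc`` (M)."""
        return kapp_hyperbola(conc, self.k_lock, self.km)


def kapp_hyperbola(conc, k_lock: float, km: float):
    """k_app = k_lock * [I] / (K_M + [I]); increasing in [I], bounded by k_lock."""
    conc = np.asarray(conc, dtype=float)
    return k_lock * conc / (km + conc)


# --------------------------------------------------------------------------
# progress-curve fit
# --------------------------------------------------------------------------

@dataclass
class ProgressFit:
    """Exponential-plus-linear fit of a post-injection progress curve."""

    y0: float  # AU at injection
    v0: float  # AU/s, initial slope (signed)
    vinf: float  # AU/s, final slope (signed)
    k_app: float  # /s (NaN when unidentifiable)
    stderr: dict
    fit_start: float  # s, first time point used (absolute)
    k_app_unidentifiable: bool = False

    @property
    def residual_fraction(self) -> float:
        """|Vinf| / |V0|: the fraction of activity surviving at equilibrium."""
        return abs(self.vinf) / abs(self.v0) if self.v0 else float("nan")


def _eq_progress(t, y0, v0, vinf, k_app):
    return y0 + vinf * t + (v0 - vinf) / k_app * (1.0 - np.exp(-k_app * t))


class ProgressCurveFitter(BaseEstimator):
    """Nonlinear least-squares fit of the slow-binding progress equation.

    Parameters
    ----------
    fit_start_offset : float, s
        Data earlier than ``injection_time + fit_start_offset`` are
        excluded (2 s by default, skipping the mixing transient).
    fit_end : float or None, s
        Absolute end of the fit window (defaults to the full record).

    Attributes (after ``fit``): ``result_`` (a :class:`ProgressFit`) plus
    ``k_app_``, ``v0_``, ``vinf_``, ``y0_``.

    The time axis is re-zeroed at the injection so the fitted ``y0``
    estimates the absorbance at the moment of inhibitor addition. When the
    early and late slopes are indistinguishable (a straight line) the
    exponential amplitude vanishes and ``k_app`` is reported as NaN with
    the ``k_app_unidentifiable`` flag set, rather than forcing a fit.
    """

    def __init__(self, fit_start_offset: float = 2.0, fit_end: Optional[float] = None):
        self.fit_start_offset = fit_start_offset
        self.fit_end = fit_end

    def fit(self, curve: ProgressCurve, y=None) -> "ProgressCurveFitter":
        t_abs = curve.time
        mask = t_abs >= curve.injection_time + self.fit_start_offset
        if self.fit_end is not None:
            mask &= t_abs <= self.fit_end
        if mask.sum() < 20:
            raise ValueError("need at least 20 samples in the fit window")
        t = t_abs[mask] - curve.injection_time
        y_ = curve.absorbance[mask]

        # secant-slope initial guesses from the first and last fifths
        k5 = max(mask.sum() // 5, 2)
        s_early = linregress(t[:k5], y_[:k5]).slope
        s_late = linregress(t[-k5:], y_[-k5:]).slope
        span = t[-1] - t[0]
        scale = max(abs(s_early), abs(s_late), 1e-30)
        if abs(s_early - s_late) <= 1e-6 * scale:
            # pure line: the exponential term is absent
            lr = linregress(t, y_)
            res = ProgressFit(
                y0=float(lr.intercept), v0=float(lr.slope), vinf=float(lr.slope),
                k_app=float("nan"),
                stderr={"y0": float(lr.intercept_stderr), "v0": float(lr.stderr),
                        "vinf": float(lr.stderr), "k_app": float("nan")},
                fit_start=float(t_abs[mask][0]), k_app_unidentifiable=True,
            )
            self._finish(res)
            return self

        model = Model(_eq_progress)
        params = Parameters()
        params.add("y0", value=float(y_[0] - s_early * t[0]))
        params.add("v0", value=float(s_early))
        params.add("vinf", value=float(s_late))
        params.add("k_app", value=5.0 / span, min=1e-7, max=1e3)
        out = model.fit(y_, params, t=t)
        if not out.success:
            raise RuntimeError(f"progress-curve fit failed: {out.message}")
        p = out.params
        se = {k: (float(p[k].stderr) if p[k].stderr is not None else float("nan"))
              for k in ("y0", "v0", "vinf", "k_app")}
        kap = float(p["k_app"].value)
        at_bound = kap <= 2e-7 or kap >= 9.9e2
        se_k = se["k_app"]
        unident = at_bound or (math.isfinite(se_k) and se_k > abs(kap)) or not math.isfinite(se_k)
        res = ProgressFit(
            y0=float(p["y0"].value), v0=float(p["v0"].value),
            vinf=float(p["vinf"].value), k_app=kap, stderr=se,
            fit_start=float(t_abs[mask][0]), k_app_unidentifiable=unident,
        )
        self._finish(res)
        return self

    def _finish(self, res: ProgressFit) -> None:
        self.result_ = res
        self.k_app_ = res.k_app
        self.v0_ = res.v0
        self.vinf_ = res.vinf
        self.y0_ = res.y0


def fit_progress_curve(curve: ProgressCurve, fit_start_offset: float = 2.0,
                       fit_end: Optional[float] = None) -> ProgressFit:
    """Functional wrapper over :class:`ProgressCurveFitter`."""
    return ProgressCurveFitter(fit_start_offset=fit_start_offset,
                               fit_end=fit_end).fit(curve).result_


# --------------------------------------------------------------------------
# concentration dependence
# --------------------------------------------------------------------------

class KappConcentrationFitter(BaseEstimator):
    """Hyperbolic fit of k_app versus inhibitor concentration.

    ``fit(conc, kapp, kapp_se=None)`` estimates the plateau ``k_lock_``
    and half-saturation ``km_`` by least squares, weighting by 1/SE^2
    when standard errors are supplied. When every concentration sits far
    below the fitted K_M only the ratio k_lock/K_M (the second-order
    association rate) is identified; ``ratio_only_`` flags this.
    """

    def fit(self, conc: Sequence[float], kapp: Sequence[float],
            kapp_se: Optional[Sequence[float]] = None) -> "KappConcentrationFitter":
        c = np.asarray(conc, dtype=float)
        k = np.asarray(kapp, dtype=float)
        if c.size < 3 or np.unique(c).size < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if np.any(c < 0) or np.any(k < 0):
            raise ValueError("concentrations and rates must be non-negative")
        weights = None
        if kapp_se is not None:
            se = np.asarray(kapp_se, dtype=float)
            weights = 1.0 / np.maximum(se, 1e-30)  # lmfit weights multiply residuals

        model = Model(kapp_hyperbola, independent_vars=["conc"])
        params = Parameters()
        params.add("k_lock", value=float(k.max() or 1e-3), min=1e-12)
        params.add("km", value=float(np.median(c) or 1e-9), min=1e-15)
        out = model.fit(k, params, conc=c, weights=weights)
        if not out.success:
            raise RuntimeError(f"hyperbolic fit failed: {out.message}")
        self.k_lock_ = float(out.params["k_lock"].value)
        self.km_ = float(out.params["km"].value)
        self.stderr_ = {
            "k_lock": (float(out.params["k_lock"].stderr)
                       if out.params["k_lock"].stderr is not None else float("nan")),
            "km": (float(out.params["km"].stderr)
                   if out.params["km"].stderr is not None else float("nan")),
        }
        self.ratio_only_ = bool(c.max() < 0.1 * self.km_)
        return self


def fit_kapp_vs_conc(points: Sequence[tuple],
                     ses: Optional[Sequence[float]] = None) -> tuple:
    """Fit (concentration, k_app) points; returns (k_lock, K_M).

    ``points`` is a sequence of ([I] in M, k_app in /s) pairs.
    """
    c, k = zip(*points)
    f = KappConcentrationFitter().fit(c, k, kapp_se=ses)
    return f.k_lock_, f.km_


# --------------------------------------------------------------------------
# residual activity and unit conversion
# --------------------------------------------------------------------------

def _local_slope(curve: ProgressCurve, center: float, window: float) -> float:
    lo, hi = center - window / 2.0, center + window / 2.0
    if lo < curve.time[0] - 1e-9 or hi > curve.time[-1] + 1e-9:
        raise ValueError("slope window extends outside the record")
    m = (curve.time >= lo) & (curve.time <= hi)
    if m.sum() < 3:
        raise ValueError("too few samples in the slope window")
    return float(linregress(curve.time[m], curve.absorbance[m]).slope)


def residual_activity(curve: ProgressCurve, late_time: float = 350.0,
                      window: float = 30.0, tolerance: float = 0.05) -> float:
    """Surviving ATPase activity: slope at ``injection + late_time`` over
    the slope just before injection, clipped to [0, 1 + tolerance].

    Slopes come from centred linear regressions of ``window`` seconds
    (the pre-injection window ends at the injection).
    """
    before = _local_slope(
        curve, center=curve.injection_time - window / 2.0, window=window
    )
    after = _local_slope(curve, center=curve.injection_time + late_time, window=window)
    if before == 0:
        raise ValueError("zero pre-injection slope: activity undefined")
    return float(np.clip(abs(after) / abs(before), 0.0, 1.0 + tolerance))


def absorbance_slope_to_turnover(slope: float, epsilon: float = 6220.0,
                                 path_length: float = 1.0,
                                 enzyme_conc: float = 1e-9) -> float:
    """Convert an absorbance slope (AU/s) to enzyme turnover (/s):
    |slope| / (epsilon * l * [E])."""
    denom = epsilon * path_length * enzyme_conc
    if denom <= 0 or not math.isfinite(denom):
        raise ValueError("epsilon, path length and enzyme concentration must be positive")
    return abs(slope) / denom
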