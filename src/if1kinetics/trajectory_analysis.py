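"""Single-molecule trace analysis: pause segmentation, dwell angles,
pause classification and exponential dwell-time fitting.

Conventions
-----------
Pauses are maximal intervals (at least ``min_duration`` seconds, 1 s by
default) over which the angle stays within ``angle_window`` of its local
median. Everything between pauses is a rotation episode. Angular distances
of inhibited pauses are reported relative to the ATP-binding dwell
immediately preceding in the hydrolysis direction, i.e. reduced to
[0, 120) deg. Dwell-time fits default to censored maximum likelihood
(terminal pauses are right-censored at the record end); binned
least-squares fitting of the duration histogram is available for literal
reproduction of histogram-based analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit, minimize
from sklearn.base import BaseEstimator

from .containers import AngleTrace, DwellAngleResult, PauseSegment

__all__ = [
    "PauseDetector",
    "ExpFit",
    "ExponentialDwellFitter",
    "RotatingTime",
    "detect_pauses",
    "rotation_episodes",
    "reference_binding_angles",
    "inhibition_angle",
    "classify_pauses",
    "fit_dwell_times",
    "rotating_time_to_inhibition",
    "circular_mean",
    "circular_sd",
]


# --------------------------------------------------------------------------
# circular helpers (degrees)
# --------------------------------------------------------------------------

def circular_mean(angles: Sequence[float], period: float = 360.0,
                  weights: Optional[Sequence[float]] = None) -> float:
    """Circular mean of ``angles`` on a ``period``-degree circle, in [0, period)."""
    a = np.asarray(angles, dtype=float) * (2.0 * np.pi / period)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    m = math.atan2(float(np.sum(w * np.sin(a))), float(np.sum(w * np.cos(a))))
    return (m * period / (2.0 * np.pi)) % period


def circular_sd(angles: Sequence[float], period: float = 360.0,
                center: Optional[float] = None, ddof: int = 1) -> float:
    """Standard deviation of angular deviations from ``center`` (or the
    circular mean), with deviations reduced to (-period/2, period/2]."""
    a = np.asarray(angles, dtype=float)
    if a.size <= ddof:
        return float("nan")
    c = circular_mean(a, period) if center is None else center
    dev = (a - c + period / 2.0) % period - period / 2.0
    return float(np.std(dev, ddof=ddof))


# --------------------------------------------------------------------------
# pause detection
# --------------------------------------------------------------------------

class PauseDetector(BaseEstimator):
    """Segment an angle trace into pauses and rotation episodes.

    Parameters
    ----------
    min_duration : float, s
        Shortest reported pause (1 s by default; must be >= 2 frames).
    angle_window : float, deg
        Half-width of the stationarity band around the local median. The
        default 30 deg is a quarter of the 120-deg step, which separates
        adjacent dwells at realistic noise levels.
    smooth_frames : int
        Width of the median pre-filter that suppresses isolated outlier
        frames (3 frames by default; boundary distortion is < 1 frame).

    Attributes (after ``fit``)
    --------------------------
    segments_ : list of PauseSegment
    noise_sd_ : float — robust frame-to-frame noise estimate, deg.
    """

    def __init__(self, min_duration: float = 1.0, angle_window: float = 30.0,
                 smooth_frames: int = 3):
        self.min_duration = min_duration
        self.angle_window = angle_window
        self.smooth_frames = smooth_frames

    def fit(self, trace: AngleTrace, y=None) -> "PauseDetector":
        self.segments_ = self._detect(trace)
        return self

    def detect(self, trace: AngleTrace) -> list:
        return self.fit(trace).segments_

    # internal -------------------------------------------------------------
    def _detect(self, trace: AngleTrace) -> list:
        fps = trace.fps
        if self.min_duration < 2.0 / fps:
            raise ValueError("min_duration must span at least two frames")
        y_raw = trace.angle
        n = y_raw.size
        L = max(int(round(self.min_duration * fps)), 2)
        if n < L:
            return []
        k = max(1, int(self.smooth_frames))
        y = median_filter(y_raw, size=k, mode="nearest") if k > 1 else y_raw

        # robust frame-to-frame noise; rotation steps are outliers to MAD
        d = np.diff(y_raw)
        noise = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)
        self.noise_sd_ = noise
        if self.angle_window < 3.0 * noise:
            warnings.warn(
                f"angle_window={self.angle_window:.1f} deg is below 3x the "
                f"frame noise SD ({noise:.1f} deg); segmentation may be unreliable",
                stacklevel=2,
            )

        # windows of length L whose angular range fits inside the band
        win = np.lib.stride_tricks.sliding_window_view(y, L)
        flat = (win.max(axis=1) - win.min(axis=1)) <= 2.0 * self.angle_window
        cover = np.zeros(n + 1, dtype=int)
        starts = np.nonzero(flat)[0]
        cover[starts] += 1
        cover[starts + L] -= 1
        covered = np.cumsum(cover[:-1]) > 0

        # runs of covered frames -> candidate pauses; a run may bridge
        # back-to-back dwells at different angles, so split recursively at
        # the largest internal jump until each piece sits within the band
        bounds = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
        raw_runs = list(zip(bounds[0::2], bounds[1::2]))  # [s, e) frame index
        pieces: list[tuple] = []
        for run in raw_runs:
            stack = [run]
            while stack:
                s, e = stack.pop()
                if e - s < 2:
                    continue
                med = float(np.median(y[s:e]))
                if np.max(np.abs(y[s:e] - med)) <= self.angle_window:
                    pieces.append((s, e))
                    continue
                j = int(np.argmax(np.abs(np.diff(y[s:e]))))
                stack.append((s, s + j + 1))
                stack.append((s + j + 1, e))
        pieces.sort()
        # re-join adjacent pieces of the same dwell (splits caused by a
        # noise outlier, not a real step)
        joined: list[list] = []
        for s, e in pieces:
            if joined and s - joined[-1][1] <= 3 and abs(
                float(np.median(y[s:e])) - float(np.median(y[joined[-1][0]:joined[-1][1]]))
            ) <= self.angle_window:
                joined[-1][1] = e
            else:
                joined.append([s, e])
        # boundary refinement against each segment's median, never
        # crossing into the neighbouring segment
        merged: list[list] = []
        for i, (s, e) in enumerate(joined):
            med = float(np.median(y[s:e]))
            floor = joined[i - 1][1] if i > 0 else 0
            ceil = joined[i + 1][0] if i + 1 < len(joined) else n
            while s > floor and abs(y[s - 1] - med) <= self.angle_window:
                s -= 1
            while e < ceil and abs(y[e] - med) <= self.angle_window:
                e += 1
            while s < e and abs(y[s] - med) > self.angle_window:
                s += 1
            while e > s and abs(y[e - 1] - med) > self.angle_window:
                e -= 1
            if merged and s <= merged[-1][1]:
                s = merged[-1][1]
            if e > s:
                merged.append([s, e])

        segs = []
        for s, e in merged:
            if (e - s) / fps < self.min_duration:
                continue
            # interior frames avoid contamination from adjacent rotation
            trim = 2 if e - s > 8 else 0
            core = y_raw[s + trim: e - trim]
            mean_angle = float(np.mean(core))
            sd = circular_sd(core, period=360.0, center=mean_angle % 360.0)
            segs.append(
                PauseSegment(
                    start=float(trace.time[s]),
                    end=float(trace.time[e - 1] + 1.0 / fps),
                    mean_angle=mean_angle,
                    circular_sd=sd,
                    terminal=(e >= n - 1),
                )
            )
        return segs


def detect_pauses(trace: AngleTrace, min_duration: float = 1.0,
                  angle_window: float = 30.0) -> list:
    """Functional wrapper over :class:`PauseDetector`."""
    return PauseDetector(min_duration=min_duration, angle_window=angle_window).detect(trace)


def rotation_episodes(trace: AngleTrace, pauses: Sequence[PauseSegment]) -> list:
    """Complement intervals of the pauses: (start_s, end_s) rotation episodes."""
    t0, t1 = float(trace.time[0]), float(trace.time[-1] + 1.0 / trace.fps)
    out, cursor = [], t0
    for p in sorted(pauses, key=lambda p: p.start):
        if p.start > cursor:
            out.append((cursor, p.start))
        cursor = max(cursor, p.end)
    if cursor < t1:
        out.append((cursor, t1))
    return out


# --------------------------------------------------------------------------
# dwell angles
# --------------------------------------------------------------------------

def reference_binding_angles(
    trace: AngleTrace,
    min_duration: float = 1.0,
    angle_window: float = 30.0,
    pauses: Optional[Sequence[PauseSegment]] = None,
) -> np.ndarray:
    """Estimate the three ATP-binding dwell angles from a binding-limited
    trace (three-dwell regime).

    Pause mean angles are folded on a 120-deg period to find the common
    phase, assigned to the nearest of the three dwell classes, and each
    class is summarised by its duration-weighted circular mean. Returns
    three angles in [0, 360), sorted ascending.
    """
    if pauses is None:
        pauses = detect_pauses(trace, min_duration=min_duration, angle_window=angle_window)
    if len(pauses) < 3:
        raise ValueError("need at least three pauses to locate the binding angles")
    angles = np.array([p.mean_angle for p in pauses])
    weights = np.array([p.duration for p in pauses])
    base = circular_mean(angles, period=120.0, weights=weights)
    cls = np.rint(((angles - base) % 360.0) / 120.0).astype(int) % 3
    out = np.full(3, np.nan)
    for kk in range(3):
        m = cls == kk
        if not m.any():
            raise ValueError("fewer than 3 occupied dwell clusters")
        out[kk] = circular_mean(angles[m], period=360.0, weights=weights[m])
    return np.sort(out % 360.0)


def inhibition_angle(
    pauses: Sequence[PauseSegment],
    reference_angles: Sequence[float],
) -> DwellAngleResult:
    """Angular distance of inhibited pauses from the preceding ATP-binding
    dwell, as a Gaussian (mean, SD) summary of the per-pause distances.

    Each pause contributes ``(mean_angle - reference) mod 120`` in the
    hydrolysis-positive direction; reduction modulo 120 makes the choice
    among the three congruent references immaterial. With a single pause
    the SD is undefined (NaN).
    """
    pauses = list(pauses)
    if not pauses:
        raise ValueError("no pauses supplied")
    refs = np.asarray(reference_angles, dtype=float)
    if refs.size == 0 or not np.all(np.isfinite(refs)):
        raise ValueError("no valid reference angles")
    labelled = [p for p in pauses if getattr(p, "label", "") == "IF1"]
    use = labelled if labelled else pauses
    deltas = np.array([(p.mean_angle - refs[0]) % 120.0 for p in use])
    mean = circular_mean(deltas, period=120.0)
    sd = circular_sd(deltas, period=120.0, center=mean)
    return DwellAngleResult(delta_theta_mean=float(mean), delta_theta_sd=float(sd),
                            n_pauses=len(use))


def classify_pauses(
    pauses: Sequence[PauseSegment],
    adp_tau_range: tuple = (5.0, 100.0),
    if1_min_duration: float = 480.0,
    trace_end: Optional[float] = None,
) -> list:
    """Label pauses as inhibitor arrest, ADP inhibition or unclassified.

    A pause is IF1 when it lasts at least ``if1_min_duration`` seconds or
    runs to the end of the record without recovery; a recovered pause with
    duration inside ``adp_tau_range`` is ADP; anything else stays
    unclassified. Labels are always assigned; the input is not mutated.
    """
    lo, hi = adp_tau_range
    out = []
    for p in pauses:
        terminal = p.terminal or (trace_end is not None and p.end >= trace_end - 1e-9)
        if p.duration >= if1_min_duration or terminal:
            label = "IF1"
        elif lo <= p.duration <= hi:
            label = "ADP"
        else:
            label = "unclassified"
        out.append(PauseSegment(p.start, p.end, p.mean_angle, p.circular_sd,
                                label=label, terminal=terminal))
    return out


# --------------------------------------------------------------------------
# exponential dwell-time fitting
# --------------------------------------------------------------------------

@dataclass
class ExpFit:
    """Result of a single- or double-exponential dwell-time fit.

    ``taus`` is (tau,) for the single model and (tau_sp, tau_lp) with
    tau_sp < tau_lp for the double model. ``amplitudes`` are event counts
    per component. ``loglik`` is the maximised log-likelihood for MLE
    fits and None for histogram least squares (``residual_sum`` is then
    set instead).
    """

    model: str
    method: str
    taus: tuple
    amplitudes: tuple
    stderr_taus: tuple
    loglik: Optional[float]
    n_events: int
    unidentifiable: bool = False
    residual_sum: Optional[float] = None


def _nll_double(params: np.ndarray, t: np.ndarray, cens: np.ndarray) -> float:
    w = 1.0 / (1.0 + np.exp(-params[0]))
    t1, t2 = np.exp(params[1]), np.exp(params[2])
    dens = w / t1 * np.exp(-t / t1) + (1 - w) / t2 * np.exp(-t / t2)
    surv = w * np.exp(-t / t1) + (1 - w) * np.exp(-t / t2)
    ll = np.where(cens, np.log(np.maximum(surv, 1e-300)),
                  np.log(np.maximum(dens, 1e-300)))
    return -float(np.sum(ll))


def _num_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej); fpm = f(x + ei - ej)
            fmp = f(x - ei + ej); fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


class ExponentialDwellFitter(BaseEstimator):
    """Fit exponential (or two-component) dwell-time distributions.

    Parameters
    ----------
    model : 'single' or 'double'
    method : 'mle_censored' or 'histogram_ls'
        Censored MLE treats flagged durations as right-censored (the
        observation ended before the dwell did). Histogram least squares
        bins the durations and fits counts, reproducing histogram-based
        analyses; censored events are excluded from the histogram.
    n_bins : int or None
        Histogram bin count; by default the bin width is tau_hat/5 from a
        preliminary single-component fit.

    Attributes (after ``fit``): ``result_`` (an :class:`ExpFit`), plus
    ``taus_``, ``amplitudes_``, ``stderr_taus_``.
    """

    def __init__(self, model: str = "single", method: str = "mle_censored",
                 n_bins: Optional[int] = None):
        self.model = model
        self.method = method
        self.n_bins = n_bins

    def fit(self, durations: Sequence[float], censored: Optional[Sequence[bool]] = None
            ) -> "ExponentialDwellFitter":
        t = np.asarray(durations, dtype=float)
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ValueError("durations must be finite and non-negative")
        cens = (np.zeros(t.size, dtype=bool) if censored is None
                else np.asarray(censored, dtype=bool))
        if cens.shape != t.shape:
            raise ValueError("censored flags must match durations")
        if self.model not in ("single", "double"):
            raise ValueError("model must be 'single' or 'double'")
        if self.method not in ("mle_censored", "histogram_ls"):
            raise ValueError("method must be 'mle_censored' or 'histogram_ls'")
        n_min = 5 if self.model == "single" else 20
        if t.size < n_min:
            raise ValueError(f"{self.model} fit requires at least {n_min} events")

        if self.method == "mle_censored":
            result = (self._fit_single_mle(t, cens) if self.model == "single"
                      else self._fit_double_mle(t, cens))
        else:
            result = self._fit_histogram(t[~cens])
        self.result_ = result
        self.taus_ = result.taus
        self.amplitudes_ = result.amplitudes
        self.stderr_taus_ = result.stderr_taus
        return self

    # internal -------------------------------------------------------------
    def _fit_single_mle(self, t: np.ndarray, cens: np.ndarray) -> ExpFit:
        n_unc = int((~cens).sum())
        if n_unc == 0:
            raise ValueError("all events censored: tau not identifiable")
        tau = float(t.sum() / n_unc)
        se = tau / math.sqrt(n_unc)
        ll = -n_unc * math.log(tau) - float(t.sum()) / tau
        return ExpFit("single", "mle_censored", (tau,), (len(t),), (se,),
                      ll, len(t))

    def _fit_double_mle(self, t: np.ndarray, cens: np.ndarray) -> ExpFit:
        unc = t[~cens]
        if unc.size < 10:
            raise ValueError("too few uncensored events for a double fit")
        med = np.median(unc)
        lo = max(float(np.mean(unc[unc <= med])), 1e-9)
        hi = max(float(np.mean(unc[unc > med])), lo * 1.5)
        x0 = np.array([0.0, math.log(lo), math.log(hi)])
        opt = minimize(_nll_double, x0, args=(t, cens), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        w = 1.0 / (1.0 + math.exp(-opt.x[0]))
        taus = [math.exp(opt.x[1]), math.exp(opt.x[2])]
        weights = [w, 1.0 - w]
        if taus[0] > taus[1]:  # enforce tau_sp < tau_lp
            taus.reverse(); weights.reverse()

        # standard errors: delta method on (w, tau1, tau2)
        def nll_nat(p):
            w_, t1, t2 = p
            w_ = min(max(w_, 1e-9), 1 - 1e-9)
            x = np.array([math.log(w_ / (1 - w_)), math.log(max(t1, 1e-12)),
                          math.log(max(t2, 1e-12))])
            return _nll_double(x, t, cens)

        nat = np.array([weights[0], taus[0], taus[1]])
        se = (float("nan"), float("nan"))
        try:
            H = _num_hessian(nll_nat, nat)
            cov = np.linalg.inv(H)
            var = np.diag(cov)
            if np.all(var[1:] > 0):
                se = (math.sqrt(var[1]), math.sqrt(var[2]))
        except np.linalg.LinAlgError:
            pass
        n = len(t)
        amps = (weights[0] * n, weights[1] * n)
        ratio = taus[1] / taus[0]
        # close time constants, or a component carrying almost no events,
        # cannot be resolved from each other / from a single exponential
        unident = ratio < 3.0 or min(weights) < 0.05
        return ExpFit("double", "mle_censored", tuple(taus), amps, se,
                      -opt.fun, n, unidentifiable=unident)

    def _fit_histogram(self, t: np.ndarray) -> ExpFit:
        if t.size == 0:
            raise ValueError("no uncensored events to histogram")
        tau0 = float(np.mean(t))
        if self.n_bins is not None:
            bins = int(self.n_bins)
        else:
            bins = max(int(np.ceil(t.max() / (tau0 / 5.0))), 4)
        counts, edges = np.histogram(t, bins=bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        if self.model == "single":
            def f(x, N, tau):
                return N * np.exp(-x / tau)
            p0 = [counts.max() or 1.0, tau0]
            popt, pcov = curve_fit(f, centers, counts, p0=p0, maxfev=20000)
            resid = counts - f(centers, *popt)
            se = math.sqrt(max(pcov[1, 1], 0.0))
            return ExpFit("single", "histogram_ls", (float(popt[1]),),
                          (float(popt[0]),), (se,), None, t.size,
                          residual_sum=float(np.sum(resid ** 2)))
        med = np.median(t)
        lo = max(float(np.mean(t[t <= med])), 1e-9)
        hi = max(float(np.mean(t[t > med])), lo * 2)

        def f2(x, N1, t1, N2, t2):
            return N1 * np.exp(-x / t1) + N2 * np.exp(-x / t2)

        p0 = [counts.max() or 1.0, lo, (counts.max() or 1.0) / 4.0, hi]
        popt, pcov = curve_fit(f2, centers, counts, p0=p0, maxfev=50000)
        order = np.argsort([popt[1], popt[3]])
        taus = tuple(float([popt[1], popt[3]][i]) for i in order)
        amps = tuple(float([popt[0], popt[2]][i]) for i in order)
        ses = tuple(math.sqrt(max([pcov[1, 1], pcov[3, 3]][i], 0.0)) for i in order)
        resid = counts - f2(centers, *popt)
        return ExpFit("double", "histogram_ls", taus, amps, ses, None, t.size,
                      unidentifiable=(taus[1] / taus[0] < 3.0),
                      residual_sum=float(np.sum(resid ** 2)))


def fit_dwell_times(durations: Sequence[float], model: str = "single",
                    method: str = "mle_censored",
                    censored: Optional[Sequence[bool]] = None,
                    n_bins: Optional[int] = None) -> ExpFit:
    """Functional wrapper over :class:`ExponentialDwellFitter`."""
    return ExponentialDwellFitter(model=model, method=method, n_bins=n_bins).fit(
        durations, censored=censored
    ).result_


# --------------------------------------------------------------------------
# rotating time
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RotatingTime:
    """Time rotating before inhibitor arrest; censored if none occurred."""

    duration: float  # s
    censored: bool


def rotating_time_to_inhibition(
    trace: AngleTrace,
    exchange_time: Optional[float] = None,
    pauses: Optional[Sequence[PauseSegment]] = None,
    **classify_kwargs,
) -> RotatingTime:
    """Time from solution exchange to the onset of the first IF1 pause.

    When no labelled pauses are supplied they are detected and classified
    with default settings. With no IF1 pause the rotating time is censored
    at the record end.
    """
    if exchange_time is None:
        exchange_time = float(trace.annotations.get("exchange_time", trace.time[0]))
    if pauses is None:
        raw = detect_pauses(trace)
        end = float(trace.time[-1] + 1.0 / trace.fps)
        pauses = classify_pauses(raw, trace_end=end, **classify_kwargs)
    onsets = [p.start for p in pauses if p.label == "IF1" and p.start >= exchange_time]
    if not onsets:
        end = float(trace.time[-1] + 1.0 / trace.fps)
        return RotatingTime(duration=end - exchange_time, censored=True)
    return RotatingTime(duration=min(onsets) - exchange_time, censored=False)
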