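"""Shared data containers for rotary-motor traces, pauses, assay curves and trials.

Angles are in degrees throughout, on the unwrapped scale (a trace may pass
through many revolutions; clockwise manipulation can make it decrease).
Counterclockwise — the ATP-hydrolysis direction of the gamma subunit viewed
from the membrane side — is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "AngleTrace",
    "TraceSegment",
    "PauseSegment",
    "DwellAngleResult",
    "ProgressCurve",
    "StallTrial",
    "ActivationEstimate",
]


@dataclass(frozen=True)
class TraceSegment:
    """Ground-truth latent dwell interval of a simulated trace."""

    start: float  # s
    end: float  # s
    kind: str  # 'binding' | 'catalytic' | 'adp' | 'if1'
    latent_angle: float  # deg, unwrapped

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class AngleTrace:
    """A sampled rotary-angle time series.

    Parameters
    ----------
    time : array, s — uniform grid.
    angle : array, deg — unwrapped observed angle.
    fps : float — acquisition rate, frames per second.
    annotations : dict — free-form metadata; recognised keys include
        ``exchange_time`` (s, completion of solution exchange).
    segments : list of TraceSegment or None — ground-truth latent dwells,
        available for simulated traces only.
    """

    time: np.ndarray
    angle: np.ndarray
    fps: float
    annotations: dict = field(default_factory=dict)
    segments: Optional[list] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.time.ndim != 1 or self.angle.shape != self.time.shape:
            raise ValueError("time and angle must be 1-D arrays of equal length")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            mean_dt = dt.mean()
            if np.any(np.abs(dt - mean_dt) > 1e-6 * mean_dt + 1e-12):
                raise ValueError("time grid must be uniform to within 1 ppm")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.angle))):
            raise ValueError("trace contains non-finite values")
        if not np.isfinite(self.fps) or self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0

    def __len__(self) -> int:
        return self.time.size


@dataclass
class PauseSegment:
    """A detected pause: an interval over which the angle stays put."""

    start: float  # s
    end: float  # s
    mean_angle: float  # deg, unwrapped
    circular_sd: float  # deg
    label: str = "unclassified"  # 'unclassified' | 'ADP' | 'IF1' | 'short'
    terminal: bool = False  # pause runs to the end of the record (censored)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class DwellAngleResult:
    """Angular distance of inhibited pauses from the ATP-binding dwell.

    ``delta_theta_mean``/``sd`` summarise a Gaussian fit of the per-pause
    angular distances, reduced to [0, 120) deg.
    """

    delta_theta_mean: float
    delta_theta_sd: float  # NaN when n_pauses < 2
    n_pauses: int


@dataclass
class ProgressCurve:
    """An ensemble NADH-coupled ATPase assay record (absorbance vs time)."""

    time: np.ndarray  # s
    absorbance: np.ndarray  # AU
    injection_time: float  # s, inhibitor added
    temperature: float = 25.0  # degC, metadata only

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.ndim != 1 or self.absorbance.shape != self.time.shape:
            raise ValueError("time and absorbance must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (self.time[0] <= self.injection_time <= self.time[-1]):
            raise ValueError("injection_time must lie within the time range")


@dataclass
class StallTrial:
    """One stall-and-release (or full-rotation) manipulation outcome.

    ``stall_angle`` is signed: counterclockwise (hydrolysis) positive,
    clockwise (synthesis) negative, relative to the inhibited pause angle.
    """

    molecule_id: str
    stall_angle: float  # deg, signed
    stall_duration: float  # s
    outcome: str  # 'ON' | 'OFF' | 'excluded'
    condition: str = ""
    exclusion_reason: str = ""
    release_angle: Optional[float] = None  # deg; equals pause angle when OFF

    def __post_init__(self) -> None:
        if self.outcome not in ("ON", "OFF", "excluded"):
            raise ValueError(f"invalid outcome {self.outcome!r}")
        if self.outcome == "excluded" and not self.exclusion_reason:
            raise ValueError("excluded trials must carry an exclusion_reason")


@dataclass(frozen=True)
class ActivationEstimate:
    """P_ON (percent) with its binomial standard deviation.

    sd = sqrt(p_on * (100 - p_on) / n), the convention used for
    reactivation probabilities in single-molecule manipulation assays.
    """

    p_on: float  # percent
    sd: float  # percent
    n: int
    group: dict = field(default_factory=dict)
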