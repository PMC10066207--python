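"""Plain-text readers and writers for traces, pause tables, curves and trials.

Formats: trace CSV (``time_s,angle_deg``) with an optional sidecar JSON of
ground-truth segments; pause table TSV; progress-curve CSV with a metadata
JSON; trial table TSV; YAML configuration files mirroring the simulator
dataclasses.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import AngleTrace, PauseSegment, ProgressCurve, StallTrial, TraceSegment
from .rotary_sim import (
    EnsembleAssayConfig,
    ManipulationProtocol,
    MotorConfig,
    ObservationConfig,
)

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_pause_table",
    "read_pause_table",
    "write_progress_csv",
    "read_progress_csv",
    "write_trial_table",
    "read_trial_table",
    "load_config",
]


def write_trace_csv(trace: AngleTrace, path, sidecar: bool = True) -> None:
    """Write ``time_s,angle_deg`` CSV; ground-truth segments (if any) go to
    a ``<path>.segments.json`` sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "angle_deg": trace.angle}).to_csv(
        path, index=False, float_format="%.9f"
    )
    if sidecar and trace.segments is not None:
        side = {
            "fps": trace.fps,
            "annotations": {k: v for k, v in trace.annotations.items()
                            if isinstance(v, (int, float, str, bool))},
            "segments": [
                {"start_s": s.start, "end_s": s.end, "class": s.kind,
                 "latent_angle_deg": s.latent_angle}
                for s in trace.segments
            ],
        }
        Path(str(path) + ".segments.json").write_text(json.dumps(side, indent=1))


def read_trace_csv(path, fps: Optional[float] = None) -> AngleTrace:
    path = Path(path)
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if fps is None:
        fps = 1.0 / float(np.median(np.diff(t)))
    segments = None
    annotations: dict = {}
    side = Path(str(path) + ".segments.json")
    if side.exists():
        meta = json.loads(side.read_text())
        fps = meta.get("fps", fps)
        annotations = meta.get("annotations", {})
        segments = [
            TraceSegment(s["start_s"], s["end_s"], s["class"], s["latent_angle_deg"])
            for s in meta.get("segments", [])
        ]
    return AngleTrace(time=t, angle=df["angle_deg"].to_numpy(), fps=fps,
                      annotations=annotations, segments=segments)


def write_pause_table(pauses: Sequence[PauseSegment], path) -> None:
    pd.DataFrame(
        {
            "start_s": [p.start for p in pauses],
            "end_s": [p.end for p in pauses],
            "mean_angle_deg": [p.mean_angle for p in pauses],
            "circular_sd_deg": [p.circular_sd for p in pauses],
            "label": [p.label for p in pauses],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_pause_table(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        PauseSegment(r.start_s, r.end_s, r.mean_angle_deg, r.circular_sd_deg,
                     label=r.label)
        for r in df.itertuples()
    ]


def write_progress_csv(curve: ProgressCurve, path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": curve.time, "absorbance_au": curve.absorbance}).to_csv(
        path, index=False, float_format="%.6f"
    )
    Path(str(path) + ".meta.json").write_text(
        json.dumps({"injection_time_s": curve.injection_time,
                    "temperature_c": curve.temperature})
    )


def read_progress_csv(path, injection_time: Optional[float] = None) -> ProgressCurve:
    path = Path(path)
    df = pd.read_csv(path)
    meta = Path(str(path) + ".meta.json")
    temperature = 25.0
    if meta.exists():
        m = json.loads(meta.read_text())
        injection_time = m.get("injection_time_s", injection_time)
        temperature = m.get("temperature_c", temperature)
    if injection_time is None:
        raise ValueError("injection_time required (no metadata sidecar found)")
    return ProgressCurve(time=df["time_s"].to_numpy(),
                         absorbance=df["absorbance_au"].to_numpy(),
                         injection_time=injection_time, temperature=temperature)


def write_trial_table(trials: Sequence[StallTrial], path) -> None:
    pd.DataFrame(
        {
            "molecule_id": [t.molecule_id for t in trials],
            "stall_angle_deg": [t.stall_angle for t in trials],
            "stall_s": [t.stall_duration for t in trials],
            "outcome": [t.outcome for t in trials],
            "condition": [t.condition for t in trials],
            "exclusion_reason": [t.exclusion_reason for t in trials],
        }
    ).to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> list:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        StallTrial(
            molecule_id=str(r.molecule_id), stall_angle=float(r.stall_angle_deg),
            stall_duration=float(r.stall_s), outcome=r.outcome,
            condition=str(getattr(r, "condition", "")),
            exclusion_reason=str(getattr(r, "exclusion_reason", "")),
        )
        for r in df.itertuples()
    ]


_CONFIG_TYPES = {
    "motor": MotorConfig,
    "observation": ObservationConfig,
    "ensemble": EnsembleAssayConfig,
    "protocol": ManipulationProtocol,
}


def load_config(path) -> dict:
    """Load a YAML config with any of the sections ``motor``,
    ``observation``, ``ensemble``, ``protocol``; each becomes the matching
    dataclass. List values are converted to tuples so defaults compare
    cleanly."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for key, cls in _CONFIG_TYPES.items():
        if key in raw:
            kwargs = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in (raw[key] or {}).items()
            }
            valid = {f.name for f in dataclasses.fields(cls)}
            unknown = set(kwargs) - valid
            if unknown:
                raise ValueError(f"unknown fields for {key}: {sorted(unknown)}")
            out[key] = cls(**kwargs)
    return out
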