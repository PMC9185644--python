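"""Reading, writing and validating trial recordings and annotations.

Trial files are plain CSV with one header line and the 17 fixed columns
of :data:`propgest.schema.CHANNELS`.  Accelerations are in m/s^2 (gravity
offset +9.81 on the vertical axes), angular rates in deg/s, time in
integer milliseconds from trial start.  Annotations travel in a JSON
sidecar, one object per gesture with label, onset, duration and whether
the palm force sensor was active (i.e. whether it was a true propulsion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import CHANNELS, SIDES

__all__ = [
    "TrialRecording",
    "GestureAnnotation",
    "SchemaError",
    "ValidationError",
    "read_trial",
    "write_trial",
    "read_annotations",
    "write_annotations",
    "fsr_boundaries",
]


class SchemaError(ValueError):
    """Trial file does not match the 17-column layout."""


class ValidationError(ValueError):
    """Trial content violates an invariant (e.g. non-monotone time)."""


@dataclass
class GestureAnnotation:
    """Ground-truth (or FSR-derived) gesture interval.

    ``source`` records provenance: ``fsr`` (hand-rim contact boundaries),
    ``manual``, or ``synthetic`` (simulator ground truth).
    """

    label: str
    onset_ms: int
    duration_ms: int
    source: str = "synthetic"
    fsr_active: bool = True

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValidationError(f"duration_ms must be > 0, got {self.duration_ms}")
        if self.onset_ms < 0:
            raise ValidationError(f"onset_ms must be >= 0, got {self.onset_ms}")

    @property
    def offset_ms(self) -> int:
        return self.onset_ms + self.duration_ms


@dataclass
class TrialRecording:
    """A 17-channel trial at a nominal sampling rate ``fs_hz``.

    ``data`` holds one column per channel in canonical order; ``t_ms`` is
    integer milliseconds from trial start, strictly increasing.
    """

    data: pd.DataFrame
    fs_hz: float = 30.0
    annotations: list[GestureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_frame(self.data)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def t_ms(self) -> np.ndarray:
        return self.data["t_ms"].to_numpy()

    @property
    def duration_ms(self) -> int:
        step = round(1000.0 / self.fs_hz)
        return int(self.t_ms[-1]) + step if self.n_samples else 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialRecording):
            return NotImplemented
        return (
            self.data.equals(other.data)
            and self.fs_hz == other.fs_hz
            and self.annotations == other.annotations
        )


def validate_frame(df: pd.DataFrame) -> None:
    missing = [c for c in CHANNELS if c not in df.columns]
    extra = [c for c in df.columns if c not in CHANNELS]
    if missing or extra:
        raise SchemaError(
            f"trial schema mismatch: missing columns {missing}, extra columns {extra}"
        )
    t = df["t_ms"].to_numpy()
    if len(t) and np.any(np.diff(t) <= 0):
        raise ValidationError("t_ms must be strictly increasing")


def infer_fs_hz(t_ms: np.ndarray) -> float:
    """Nominal sampling rate from the mean timestamp step.

    Timestamps are integer milliseconds, so at 30 Hz the per-step
    differences alternate 33/34 ms and their median is biased; the mean
    over the trial recovers the rate exactly.
    """
    if len(t_ms) < 2:
        raise ValidationError("need >= 2 samples to infer the sampling rate")
    return 1000.0 / float(np.mean(np.diff(t_ms)))


def read_trial(path: str | Path) -> TrialRecording:
    """Read a CSV trial file, validating the 17-column schema.

    The sampling rate is inferred from the median timestamp step.
    """
    df = pd.read_csv(path)
    df = df[[c for c in CHANNELS if c in df.columns] + [c for c in df.columns if c not in CHANNELS]]
    validate_frame(df)
    fs = infer_fs_hz(df["t_ms"].to_numpy())
    rec = TrialRecording(df.reset_index(drop=True), fs_hz=fs)
    sidecar = Path(path).with_suffix(".annotations.json")
    if sidecar.exists():
        rec.annotations = read_annotations(sidecar)
    return rec


def write_trial(rec: TrialRecording, path: str | Path, with_annotations: bool = True) -> Path:
    """Write a trial to CSV (+ JSON annotation sidecar if present)."""
    path = Path(path)
    rec.data[list(CHANNELS)].to_csv(path, index=False)
    if with_annotations and rec.annotations:
        write_annotations(rec.annotations, path.with_suffix(".annotations.json"))
    return path


def read_annotations(path: str | Path) -> list[GestureAnnotation]:
    with open(path) as fh:
        raw = json.load(fh)
    return [GestureAnnotation(**item) for item in raw]


def write_annotations(annotations: list[GestureAnnotation], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {
            "label": a.label,
            "onset_ms": a.onset_ms,
            "duration_ms": a.duration_ms,
            "source": a.source,
            "fsr_active": a.fsr_active,
        }
        for a in annotations
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def fsr_boundaries(
    rec: TrialRecording, side: str, threshold: float = 0.5
) -> list[tuple[int, int]]:
    """Hand--rim contact intervals from the palm force sensor.

    Returns maximal runs where the side's FSR exceeds *threshold*, as
    half-open ``[onset_ms, offset_ms)`` intervals.  The offset of a run is
    the timestamp of the first sample after it (trial end + one nominal
    step for a run reaching the last sample).
    """
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    fsr = rec.data[f"{side[0]}_fsr"].to_numpy()
    active = fsr > threshold
    if not active.any():
        return []
    padded = np.concatenate(([False], active, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    t = rec.t_ms
    step = round(1000.0 / rec.fs_hz)
    out = []
    for s, e in zip(starts, ends):
        off = int(t[e]) if e < len(t) else int(t[-1]) + step
        out.append((int(t[s]), off))
    return out
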