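"""Sliding-window segmentation, window labeling and dataset assembly.

A trial of n samples is cut into m = floor((n - w)/s) + 1 half-open
windows of w samples advanced by s; trailing samples that do not fill a
window are dropped.  Each window gets one 3-class label per side --
*forward*, *backward* or *dance* -- by its geometry against the side's
propulsion intervals:

1. the window fully contains the gesture, or
2. the gesture fully contains the window, or
3. their overlap is at least 70% of the window size (inclusive);

otherwise it is dance.  Fake propulsions are never side propulsion
intervals, so their windows label as dance by construction.

Per-side datasets pool windows over trials and rebalance by randomly
undersampling the dance class down to max(#forward, #backward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .io import GestureAnnotation, TrialRecording

__all__ = [
    "WindowParams",
    "Window",
    "LabeledDataset",
    "EmptyTrialError",
    "LabelingConflictError",
    "DegenerateDatasetError",
    "count_windows",
    "slide",
    "side_intervals",
    "label_window",
    "build_dataset",
]

#: Minimum fraction of the window a propulsion must cover (case 3).
OVERLAP_FRACTION = 0.7


class EmptyTrialError(ValueError):
    """Trial shorter than one window."""


class LabelingConflictError(ValueError):
    """Two contradictory propulsions both claim one window."""


class DegenerateDatasetError(ValueError):
    """A class has zero windows; the dataset cannot be balanced."""


@dataclass(frozen=True)
class WindowParams:
    w: int  # window size, samples
    s: int  # step, samples

    def __post_init__(self) -> None:
        if not 1 <= self.s <= self.w:
            raise ValueError(f"need 1 <= s <= w, got w={self.w}, s={self.s}")


@dataclass(frozen=True)
class Window:
    """Half-open slice [start_sample, end_sample) of a recording."""

    k: int
    start_sample: int
    end_sample: int
    start_ms: int
    end_ms: int
    rec: TrialRecording = field(repr=False, compare=False)

    @property
    def w(self) -> int:
        return self.end_sample - self.start_sample

    @property
    def data(self) -> pd.DataFrame:
        return self.rec.data.iloc[self.start_sample : self.end_sample]


def count_windows(n: int, params: WindowParams) -> int:
    """Number of full windows in n samples: floor((n - w)/s) + 1."""
    if n < params.w:
        raise EmptyTrialError(f"trial of {n} samples is shorter than w={params.w}")
    return (n - params.w) // params.s + 1


def slide(rec: TrialRecording, params: WindowParams) -> list[Window]:
    """All full windows of a recording; window k covers [k*s, k*s + w)."""
    n = rec.n_samples
    m = count_windows(n, params)
    step_ms = 1000.0 / rec.fs_hz
    out = []
    for k in range(m):
        a = k * params.s
        b = a + params.w
        out.append(
            Window(
                k=k,
                start_sample=a,
                end_sample=b,
                start_ms=int(round(a * step_ms)),
                end_ms=int(round(b * step_ms)),
                rec=rec,
            )
        )
    return out


def side_intervals(
    annotations: list[GestureAnnotation], side: str, fs_hz: float
) -> list[tuple[str, int, int]]:
    """Per-side propulsion intervals as (stroke, start_sample, end_sample).

    Only true propulsions (fsr_active) where *side* performs a stroke
    qualify; fake propulsions and the other arm's solo strokes do not.
    """
    out = []
    for a in annotations:
        if schema.is_fpg(a.label) or not a.fsr_active:
            continue
        if a.label == schema.DANCE:
            continue
        stroke = schema.stroke_for_side(a.label, side)
        if stroke is None:
            continue
        i0 = int(round(a.onset_ms * fs_hz / 1000.0))
        i1 = int(round(a.offset_ms * fs_hz / 1000.0))
        out.append((stroke, i0, i1))
    return out


def label_window(
    win: Window,
    intervals: list[tuple[str, int, int]],
    overlap_fraction: float = OVERLAP_FRACTION,
) -> str:
    """3-class label of one window against side propulsion intervals.

    *intervals* come from :func:`side_intervals` (or FSR boundaries with a
    known stroke direction).  Raises :class:`LabelingConflictError` if two
    intervals with different strokes both qualify.
    """
    w = win.w
    hits = set()
    for stroke, i0, i1 in sorted(intervals, key=lambda iv: (iv[1], iv[2], iv[0])):
        contains_gesture = win.start_sample <= i0 and i1 <= win.end_sample
        contained_by_gesture = i0 <= win.start_sample and win.end_sample <= i1
        overlap = max(0, min(win.end_sample, i1) - max(win.start_sample, i0))
        if contains_gesture or contained_by_gesture or overlap >= overlap_fraction * w:
            hits.add(stroke)
    if len(hits) > 1:
        raise LabelingConflictError(
            f"window {win.k} [{win.start_sample},{win.end_sample}) claimed by {sorted(hits)}"
        )
    return hits.pop() if hits else schema.DANCE


@dataclass
class LabeledDataset:
    """Feature-ready, balanced per-side window dataset.

    X rows align with y (labels) and groups (trial indices).  counts
    holds the pre- and post-balancing class sizes.
    """

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray
    side: str
    mode: str
    params: WindowParams
    seed: int
    counts: dict[str, dict[str, int]]

    def __len__(self) -> int:
        return len(self.y)


def labeled_windows(
    rec: TrialRecording, side: str, params: WindowParams
) -> list[tuple[Window, str]]:
    """Slide over a trial and label every window for one side."""
    intervals = side_intervals(rec.annotations, side, rec.fs_hz)
    return [(win, label_window(win, intervals)) for win in slide(rec, params)]


def build_dataset(
    trials: list[TrialRecording],
    side: str,
    mode: str,
    params: WindowParams,
    seed: int = 0,
    filt: "FilterSpec | None" = None,
) -> LabeledDataset:
    """Pool labeled windows over trials into a balanced feature table.

    Dance windows are randomly undersampled (seeded) to
    max(#forward, #backward).  Raises :class:`DegenerateDatasetError`
    if any of the three classes is empty before balancing.
    """
    from .features import FilterSpec, featurize_windows

    if not trials:
        raise ValueError("need at least one trial")
    filt = filt or FilterSpec(fs_hz=trials[0].fs_hz)

    frames, labels, groups = [], [], []
    for ti, rec in enumerate(trials):
        wins_labels = labeled_windows(rec, side, params)
        wins = [w for w, _ in wins_labels]
        frames.append(featurize_windows(wins, side, mode, filt))
        labels.extend(lab for _, lab in wins_labels)
        groups.extend([ti] * len(wins))

    X = pd.concat(frames, ignore_index=True)
    y = np.asarray(labels)
    g = np.asarray(groups)

    raw = {lab: int((y == lab).sum()) for lab in schema.SIDE_LABELS}
    empty = [lab for lab, c in raw.items() if c == 0]
    if empty:
        raise DegenerateDatasetError(f"classes with zero windows: {empty}")

    n_keep = max(raw[schema.FORWARD], raw[schema.BACKWARD])
    rng = np.random.default_rng(seed)
    dance_idx = np.flatnonzero(y == schema.DANCE)
    keep_dance = np.sort(rng.choice(dance_idx, size=min(n_keep, len(dance_idx)), replace=False))
    keep = np.sort(np.concatenate([np.flatnonzero(y != schema.DANCE), keep_dance]))

    balanced = {lab: int((y[keep] == lab).sum()) for lab in schema.SIDE_LABELS}
    return LabeledDataset(
        X=X.iloc[keep].reset_index(drop=True),
        y=y[keep],
        groups=g[keep],
        side=side,
        mode=mode,
        params=params,
        seed=seed,
        counts={"raw": raw, "balanced": balanced},
    )
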