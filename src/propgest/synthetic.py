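"""Synthetic wheelchair-dance choreographies and trial signals.

Real recordings of wheelchair dancers are not redistributable, so the
training and evaluation corpus is emulated.  A choreography strings the
eight propulsion gestures (PGs) plus one fake propulsion (FPG) in random
order, separated by free-dance filler whose duration runs up to three
times the neighbouring propulsion time.  Propulsion durations are drawn
uniformly from 600-1500 ms.

Signal model
------------
Each stroke is a deterministic kinematic template on the active hand's
channels plus white Gaussian noise:

* a half-sine angular-velocity pulse on the hand gyroscope Y axis (the
  axis aligned with wheel rotation while gripping the rim), positive for
  a forward stroke and negative for a backward one, with cross-talk onto
  the other gyro axes;
* a correlated full-sine acceleration pulse on the hand X axis
  (push then brake), with gravity (+9.81 m/s^2) resting on the Z axis;
* for *true* propulsions only, a short contact jerk on the accelerometer
  at stroke onset and release, where the palm grabs and leaves the rim.

Fake propulsions reuse the same template at reduced amplitude and
without the contact jerk: kinematically similar, but learnable.  Dance
filler is an Ornstein-Uhlenbeck (smoothed, nonstationary) process with
occasional low-frequency arm-wave bursts -- propulsion-free by
construction.  Palm force channels are 1 during true hand-rim contact
and exactly 0 during FPGs and dance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .io import GestureAnnotation, TrialRecording, write_trial

__all__ = [
    "GestureSpec",
    "ChoreographyPlan",
    "SimulatorConfig",
    "make_choreography",
    "synthesize_trial",
    "make_corpus",
]

#: Propulsion duration bounds (ms).
DURATION_RANGE_MS = (600, 1500)


@dataclass(frozen=True)
class GestureSpec:
    """One planned gesture: label, duration, template scale, active arms."""

    label: str
    duration_ms: int
    amplitude: float = 1.0
    sides_active: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.label != schema.DANCE:
            lo, hi = DURATION_RANGE_MS
            if not lo <= self.duration_ms <= hi:
                raise ValueError(
                    f"propulsion-like duration must lie in {DURATION_RANGE_MS} ms, "
                    f"got {self.duration_ms}"
                )
            expected = schema.sides_active(self.label)
            if self.sides_active != expected:
                raise ValueError(
                    f"{self.label}: sides_active {set(self.sides_active)} != {set(expected)}"
                )

    @property
    def is_fpg(self) -> bool:
        return schema.is_fpg(self.label)


@dataclass(frozen=True)
class ChoreographyPlan:
    """Ordered propulsion-like events on a dance background."""

    events: tuple[tuple[GestureSpec, int], ...]  # (spec, onset_ms)
    trial_length_ms: int
    seed: int

    def __post_init__(self) -> None:
        last_end = 0
        for spec, onset in self.events:
            if onset < last_end:
                raise ValueError("planned events overlap")
            last_end = onset + spec.duration_ms


@dataclass(frozen=True)
class SimulatorConfig:
    """Signal-model parameters.

    noise_sd scales the white noise added on top of propulsion templates
    (in channel units: m/s^2 for accelerometers; gyroscope noise is
    ``10 * noise_sd`` deg/s).  dance_gap_range gives the filler
    duration as a multiple of the neighbouring propulsion time.
    """

    fs_hz: float = 30.0
    noise_sd: float = 0.35
    dance_gap_range: tuple[float, float] = (1.0, 3.0)
    gyro_amplitude: float = 150.0  # deg/s, half-sine peak
    acc_amplitude: float = 3.0  # m/s^2, full-sine peak
    contact_jerk: float = 4.0  # m/s^2, grab/release transient (true PGs)
    contact_vibration: float = 1.5  # m/s^2, rim-reaction vibration (true PGs)
    vibration_hz: float = 7.0  # above the 4 Hz feature filter, below Nyquist
    fpg_attenuation: float = 0.65  # unloaded mimed stroke: gentler than a true push
    dance_gyro_sd: float = 25.0  # deg/s, OU stationary sd
    dance_acc_sd: float = 0.8  # m/s^2
    dance_tau_s: float = 0.3  # OU relaxation time
    burst_rate_hz: float = 0.15  # arm-wave bursts per second of dance
    fsr_level: float = 1.0  # contact channel amplitude (binary by default)
    gravity: float = 9.81

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_choreography(
    seed: int,
    include_fpg: bool = True,
    config: SimulatorConfig | None = None,
) -> ChoreographyPlan:
    """Plan one trial: the 8 PGs (plus 1 FPG) in random order with dance gaps.

    Deterministic for a fixed seed.  Gap durations are drawn uniformly
    from ``dance_gap_range`` times the duration of the propulsion that
    follows (the preceding one for the closing gap).
    """
    cfg = config or SimulatorConfig()
    rng = np.random.default_rng(seed)
    names = list(schema.GESTURES)
    order = [names[i] for i in rng.permutation(len(names))]
    if include_fpg:
        fpg_base = names[rng.integers(len(names))]
        order.insert(int(rng.integers(len(order) + 1)), schema.FPG_PREFIX + fpg_base)

    lo, hi = DURATION_RANGE_MS
    specs = [
        GestureSpec(
            label=label,
            duration_ms=int(rng.integers(lo, hi + 1)),
            amplitude=float(rng.uniform(0.85, 1.15)),
            sides_active=schema.sides_active(label),
        )
        for label in order
    ]

    events: list[tuple[GestureSpec, int]] = []
    cursor = 0
    g_lo, g_hi = cfg.dance_gap_range
    for spec in specs:
        gap = int(rng.uniform(g_lo, g_hi) * spec.duration_ms)
        cursor += gap
        events.append((spec, cursor))
        cursor += spec.duration_ms
    closing = int(rng.uniform(g_lo, g_hi) * specs[-1].duration_ms)
    return ChoreographyPlan(tuple(events), trial_length_ms=cursor + closing, seed=int(seed))


def _ou_process(rng: np.random.Generator, n: int, sd: float, a: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path, AR(1) with coefficient a."""
    eps = rng.standard_normal(n) * sd * np.sqrt(max(1.0 - a * a, 1e-12))
    x = np.empty(n)
    x[0] = rng.standard_normal() * sd
    for i in range(1, n):
        x[i] = a * x[i - 1] + eps[i]
    return x


def _dance_channel(
    rng: np.random.Generator, n: int, sd: float, cfg: SimulatorConfig
) -> np.ndarray:
    """OU background plus sparse smooth arm-wave bursts."""
    a = float(np.exp(-1.0 / (cfg.dance_tau_s * cfg.fs_hz)))
    x = _ou_process(rng, n, sd, a)
    n_bursts = rng.poisson(cfg.burst_rate_hz * n / cfg.fs_hz)
    for _ in range(n_bursts):
        dur = int(rng.uniform(0.5, 1.5) * cfg.fs_hz)
        start = int(rng.integers(0, max(n - dur, 1)))
        f = rng.uniform(0.5, 2.0)
        tt = np.arange(min(dur, n - start)) / cfg.fs_hz
        envelope = np.sin(np.pi * tt / (dur / cfg.fs_hz)) ** 2
        # burst vigour spans gentle sways up to free arm swings in the
        # same rate band as mimed (contact-free) strokes, well below a
        # loaded push
        amp = rng.uniform(0.5, 3.0) * sd
        x[start : start + len(tt)] += amp * envelope * np.sin(
            2 * np.pi * f * tt + rng.uniform(0, 2 * np.pi)
        )
    return x


def _stroke_templates(
    spec: GestureSpec, side: str, n_g: int, cfg: SimulatorConfig
) -> dict[str, np.ndarray] | None:
    """Deterministic per-channel templates of a stroke, or None if arm free."""
    stroke = schema.stroke_for_side(spec.label, side)
    if stroke is None:
        return None
    sign = 1.0 if stroke == schema.FORWARD else -1.0
    scale = spec.amplitude * (cfg.fpg_attenuation if spec.is_fpg else 1.0)
    phase = np.arange(n_g) / max(n_g - 1, 1)  # 0..1 across the stroke
    # front-loaded half-sine: the push phase carries the angular-velocity
    # peak early, the follow-through decays -- a stroke is not symmetric
    warped = phase ** 0.6
    gyro_pulse = sign * scale * cfg.gyro_amplitude * np.sin(np.pi * warped)
    acc_pulse = sign * scale * cfg.acc_amplitude * np.sin(2 * np.pi * warped)
    if spec.is_fpg:
        # without the rim constraining the grip, the mimed stroke is not
        # aligned with the wheel plane: the angular-velocity pulse spreads
        # off the primary axis even though the overall arm motion looks
        # the same
        tpl = {
            "gyro_y": 0.5 * gyro_pulse,
            "gyro_x": 0.75 * gyro_pulse,
            "gyro_z": -0.5 * gyro_pulse,
            "acc_x": 0.6 * acc_pulse,
            "acc_y": 0.6 * acc_pulse,
            "acc_z": 0.4 * np.abs(acc_pulse),
        }
    else:
        tpl = {
            "gyro_y": gyro_pulse,
            "gyro_x": 0.3 * gyro_pulse,
            "gyro_z": -0.2 * gyro_pulse,
            "acc_x": acc_pulse,
            "acc_y": 0.25 * acc_pulse,
            "acc_z": 0.4 * np.abs(acc_pulse),
        }
    if not spec.is_fpg:
        # rim contact: grab/release jerk plus sustained reaction vibration
        # (the loaded rim pushes back; a free-air fake stroke has neither)
        k = max(int(round(0.05 * cfg.fs_hz)), 1)  # ~50 ms transient
        jerk = np.zeros(n_g)
        jerk[:k] = cfg.contact_jerk
        jerk[-k:] -= cfg.contact_jerk
        t = np.arange(n_g) / cfg.fs_hz
        vib = cfg.contact_vibration * np.sin(2 * np.pi * cfg.vibration_hz * t)
        tpl["acc_x"] = tpl["acc_x"] + jerk + vib
        tpl["acc_z"] = tpl["acc_z"] + 0.5 * np.abs(jerk) + 0.6 * vib
        tpl["gyro_y"] = tpl["gyro_y"] + 6.0 * vib
    return tpl


def synthesize_trial(
    plan: ChoreographyPlan, config: SimulatorConfig | None = None
) -> TrialRecording:
    """Render a plan into a 17-channel recording with ground-truth annotations.

    Hand channels of an active arm are template + N(0, noise_sd) inside a
    propulsion-like span and dance process outside; the inactive arm keeps
    dancing throughout.  FSR channels are ``fsr_level`` inside true PG
    spans of the corresponding hand and exactly 0 elsewhere.
    """
    cfg = config or SimulatorConfig()
    rng = np.random.default_rng(plan.seed + 0x5EED)
    if plan.events and plan.events[-1][0].duration_ms + plan.events[-1][1] > plan.trial_length_ms:
        raise ValueError("planned events exceed trial_length_ms")

    n = int(round(plan.trial_length_ms * cfg.fs_hz / 1000.0))
    t_ms = np.round(1000.0 * np.arange(n) / cfg.fs_hz).astype(np.int64)

    cols: dict[str, np.ndarray] = {}
    cols["trunk_acc_z"] = cfg.gravity + _dance_channel(rng, n, 0.4 * cfg.dance_acc_sd, cfg)
    cols["trunk_gyro"] = _dance_channel(rng, n, 0.4 * cfg.dance_gyro_sd, cfg)
    for side in schema.SIDES:
        p = side[0]
        for ax in "xyz":
            base = cfg.gravity if ax == "z" else 0.0
            cols[f"{p}_acc_{ax}"] = base + _dance_channel(rng, n, cfg.dance_acc_sd, cfg)
            cols[f"{p}_gyro_{ax}"] = _dance_channel(rng, n, cfg.dance_gyro_sd, cfg)
        cols[f"{p}_fsr"] = np.zeros(n)

    annotations: list[GestureAnnotation] = []
    for spec, onset_ms in plan.events:
        i0 = int(round(onset_ms * cfg.fs_hz / 1000.0))
        i1 = int(round((onset_ms + spec.duration_ms) * cfg.fs_hz / 1000.0))
        i1 = min(i1, n)
        n_g = i1 - i0
        if n_g <= 0:
            continue
        for side in spec.sides_active:
            p = side[0]
            tpl = _stroke_templates(spec, side, n_g, cfg)
            assert tpl is not None
            noise = lambda sd: rng.standard_normal(n_g) * sd
            gyro_sd = 10.0 * cfg.noise_sd
            cols[f"{p}_gyro_x"][i0:i1] = tpl["gyro_x"] + noise(gyro_sd)
            cols[f"{p}_gyro_y"][i0:i1] = tpl["gyro_y"] + noise(gyro_sd)
            cols[f"{p}_gyro_z"][i0:i1] = tpl["gyro_z"] + noise(gyro_sd)
            cols[f"{p}_acc_x"][i0:i1] = tpl["acc_x"] + noise(cfg.noise_sd)
            cols[f"{p}_acc_y"][i0:i1] = tpl["acc_y"] + noise(cfg.noise_sd)
            cols[f"{p}_acc_z"][i0:i1] = cfg.gravity + tpl["acc_z"] + noise(cfg.noise_sd)
            if not spec.is_fpg:
                cols[f"{p}_fsr"][i0:i1] = cfg.fsr_level
        annotations.append(
            GestureAnnotation(
                label=spec.label,
                onset_ms=int(onset_ms),
                duration_ms=int(spec.duration_ms),
                source="synthetic",
                fsr_active=not spec.is_fpg,
            )
        )

    cols["t_ms"] = t_ms
    df = pd.DataFrame({c: cols[c] for c in schema.CHANNELS})
    return TrialRecording(df, fs_hz=cfg.fs_hz, annotations=annotations)


def make_corpus(
    seed: int,
    n_subjects: int = 8,
    n_trials: int = 10,
    config: SimulatorConfig | None = None,
) -> list[TrialRecording]:
    """Simulate a study corpus: per subject, repeated runs of one choreography.

    Subject s, trial t gets plan seed ``seed + 1000*s`` (one choreography
    per subject, as in a study protocol) and an independent render seed,
    so repeats share structure but not noise.
    """
    cfg = config or SimulatorConfig()
    trials = []
    for s in range(n_subjects):
        plan = make_choreography(seed + 1000 * s, config=cfg)
        for t in range(n_trials):
            render = ChoreographyPlan(plan.events, plan.trial_length_ms, seed=plan.seed + t)
            trials.append(synthesize_trial(render, cfg))
    return trials


def write_corpus(trials: list[TrialRecording], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rec in enumerate(trials):
        paths.append(write_trial(rec, out_dir / f"trial_{i:03d}.csv"))
    return paths
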