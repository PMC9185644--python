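"""Channel and gesture vocabulary shared across the pipeline.

A trial recording carries 17 variables sampled at a nominal 30 Hz: one
trunk accelerometer axis (Z) and one trunk gyroscope axis, a 3-axis
accelerometer and 3-axis gyroscope on the back of each hand, the sampling
time, and one palm force sensor (FSR) per hand.  The FSR channels flag
hand--rim contact and are used only to delimit true propulsions for
labeling; they are never fed to the classifiers.

Eight specific propulsion gestures (PGs) are recognized.  Each is a
bilateral combination of two basic per-arm strokes, *forward* and
*backward*; everything else -- including fake propulsions (FPGs), arm
movements that mimic a stroke without touching the rim -- is *dance*.
"""

from __future__ import annotations

# Column order of a trial file.  Fixed; validated on read.
CHANNELS: tuple[str, ...] = (
    "trunk_acc_z",
    "trunk_gyro",
    "l_acc_x",
    "l_acc_y",
    "l_acc_z",
    "l_gyro_x",
    "l_gyro_y",
    "l_gyro_z",
    "r_acc_x",
    "r_acc_y",
    "r_acc_z",
    "r_gyro_x",
    "r_gyro_y",
    "r_gyro_z",
    "t_ms",
    "l_fsr",
    "r_fsr",
)

N_CHANNELS = len(CHANNELS)  # 17

SIDES = ("left", "right")
MODES = ("two-sensor", "three-sensor")

#: Window labels emitted by each side classifier.
FORWARD = "forward"
BACKWARD = "backward"
DANCE = "dance"
SIDE_LABELS = (FORWARD, BACKWARD, DANCE)

#: The eight propulsion gestures, keyed by name, with the basic stroke
#: each arm performs: ``(left stroke, right stroke)``; ``None`` = arm free.
#: Numbering follows the fusion lookup (1-8; 9 is dance).
GESTURES: dict[str, tuple[str | None, str | None]] = {
    "left-forward": (FORWARD, None),
    "left-backward": (BACKWARD, None),
    "right-forward": (None, FORWARD),
    "right-backward": (None, BACKWARD),
    "forward": (FORWARD, FORWARD),
    "backward": (BACKWARD, BACKWARD),
    "clockwise": (FORWARD, BACKWARD),
    "anticlockwise": (BACKWARD, FORWARD),
}

GESTURE_IDS: dict[str, int] = {
    "left-forward": 1,
    "left-backward": 2,
    "right-forward": 3,
    "right-backward": 4,
    "forward": 5,
    "backward": 6,
    "clockwise": 7,
    "anticlockwise": 8,
    DANCE: 9,
}

ID_TO_GESTURE: dict[int, str] = {v: k for k, v in GESTURE_IDS.items()}

FPG_PREFIX = "fpg-"


def is_fpg(label: str) -> bool:
    """True for fake-propulsion labels (``fpg-<gesture>``)."""
    return label.startswith(FPG_PREFIX)


def base_gesture(label: str) -> str:
    """Strip the fake-propulsion prefix, if any."""
    return label[len(FPG_PREFIX):] if is_fpg(label) else label


def sides_active(label: str) -> frozenset[str]:
    """Which arms perform a stroke during *label*.

    Works for PGs and FPGs; raises ``KeyError`` for unknown gestures
    (``dance`` has no stroke and is rejected too).
    """
    left, right = GESTURES[base_gesture(label)]
    active = set()
    if left is not None:
        active.add("left")
    if right is not None:
        active.add("right")
    return frozenset(active)


def stroke_for_side(label: str, side: str) -> str | None:
    """The basic stroke *side* performs during *label* (None if free)."""
    left, right = GESTURES[base_gesture(label)]
    return left if side == "left" else right


def hand_prefix(side: str) -> str:
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}; expected one of {SIDES}")
    return side[0]
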