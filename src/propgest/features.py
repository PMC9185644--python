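"""Per-window signal selection and the 19 time/frequency features.

Each side classifier sees the 3 accelerometer axes, the 3 gyroscope axes
and the per-sample Euclidean norms |a| and |w| of its own hand
(two-sensor mode, N = 8 signals); three-sensor mode adds the trunk
accelerometer Z axis and the trunk gyroscope channel (N = 10).  Every
signal contributes 13 time-domain and 6 frequency-domain features
(Nf = 19), giving 152 features in two-sensor mode and 190 in
three-sensor mode.

Time features are computed on the raw window.  Frequency features are
computed on a causally low-pass-filtered copy (2nd-order Butterworth,
4 Hz cutoff, filter state initialised from the window's first sample and
reset per window -- no future samples are ever used), mean-removed, via
a one-sided periodogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import schema
from .io import SchemaError
from .windowing import Window

__all__ = [
    "FilterSpec",
    "SignalMatrix",
    "signal_names",
    "select_signals",
    "time_features",
    "freq_features",
    "featurize",
    "featurize_windows",
    "feature_names",
    "TIME_FEATURES",
    "FREQ_FEATURES",
]

TIME_FEATURES = (
    "mean",
    "rms",
    "variance",
    "std",
    "median",
    "max",
    "min",
    "zero_crossings",
    "n_peaks",
    "p25",
    "p75",
    "kurtosis",
    "skew",
)
FREQ_FEATURES = (
    "psd_n_peaks",
    "psd_mean",
    "psd_rms",
    "psd_median",
    "psd_std",
    "psd_entropy",
)
NF = len(TIME_FEATURES) + len(FREQ_FEATURES)  # 19


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth used before the frequency features."""

    order: int = 2
    cutoff_hz: float = 4.0
    fs_hz: float = 30.0

    def __post_init__(self) -> None:
        if not self.cutoff_hz < self.fs_hz / 2:
            raise ValueError("cutoff_hz must be below the Nyquist frequency")

    def ba(self) -> tuple[np.ndarray, np.ndarray]:
        return sps.butter(self.order, self.cutoff_hz, btype="low", fs=self.fs_hz)


@dataclass
class SignalMatrix:
    """Named per-window signals for one (side, mode) classifier input."""

    signals: pd.DataFrame  # w rows x N named columns
    side: str
    mode: str

    @property
    def N(self) -> int:
        return self.signals.shape[1]


def signal_names(side: str, mode: str) -> list[str]:
    """Canonical input-signal order for a (side, mode) classifier."""
    if side not in schema.SIDES:
        raise ValueError(f"unknown side {side!r}")
    if mode not in schema.MODES:
        raise ValueError(f"unknown mode {mode!r}")
    p = side[0]
    names = []
    if mode == "three-sensor":
        names += ["trunk_acc_z", "trunk_gyro"]
    names += [f"{p}_acc_{ax}" for ax in "xyz"]
    names += [f"{p}_gyro_{ax}" for ax in "xyz"]
    names += [f"{p}_acc_norm", f"{p}_gyro_norm"]
    return names


def _signal_frame(data: pd.DataFrame, side: str, mode: str) -> pd.DataFrame:
    p = side[0]
    required = [c for c in signal_names(side, mode) if not c.endswith("_norm")]
    missing = [c for c in required + [f"{p}_acc_x"] if c not in data.columns]
    if missing:
        raise SchemaError(f"window is missing channels {sorted(set(missing))}")
    out = {}
    for name in signal_names(side, mode):
        if name.endswith("_norm"):
            kind = "acc" if "acc" in name else "gyro"
            axes = data[[f"{p}_{kind}_{ax}" for ax in "xyz"]].to_numpy()
            out[name] = np.linalg.norm(axes, axis=1)
        else:
            out[name] = data[name].to_numpy()
    return pd.DataFrame(out)


def select_signals(win: Window, side: str, mode: str) -> SignalMatrix:
    """Table-driven signal selection (8 or 10 signals, incl. |a| and |w|)."""
    return SignalMatrix(_signal_frame(win.data, side, mode), side=side, mode=mode)


# ---------------------------------------------------------------------------
# feature kernels (vectorized along the last axis)

def _moments_features(X: np.ndarray) -> dict[str, np.ndarray]:
    mean = X.mean(axis=-1)
    var = X.var(axis=-1)
    std = np.sqrt(var)
    centered = X - mean[..., None]
    m3 = (centered**3).mean(axis=-1)
    m4 = (centered**4).mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(var > 0, m3 / np.where(var > 0, var, 1) ** 1.5, 0.0)
        kurt = np.where(var > 0, m4 / np.where(var > 0, var, 1) ** 2 - 3.0, 0.0)
    return {"mean": mean, "variance": var, "std": std, "skew": skew, "kurtosis": kurt}


def _count_peaks(X: np.ndarray) -> np.ndarray:
    """Strict local maxima: x[i-1] < x[i] > x[i+1]."""
    if X.shape[-1] < 3:
        return np.zeros(X.shape[:-1])
    mid = X[..., 1:-1]
    return ((mid > X[..., :-2]) & (mid > X[..., 2:])).sum(axis=-1).astype(float)


def _zero_crossings(X: np.ndarray) -> np.ndarray:
    """Strict sign changes of the mean-centered series.

    Raw accelerometer channels carry the gravity offset; centering makes
    the count reflect oscillation rather than bias.
    """
    c = X - X.mean(axis=-1, keepdims=True)
    return (c[..., :-1] * c[..., 1:] < 0).sum(axis=-1).astype(float)


def _time_feature_block(X: np.ndarray) -> np.ndarray:
    """13 time features along the last axis; output (..., 13)."""
    mom = _moments_features(X)
    feats = [
        mom["mean"],
        np.sqrt((X**2).mean(axis=-1)),  # rms
        mom["variance"],
        mom["std"],
        np.median(X, axis=-1),
        X.max(axis=-1),
        X.min(axis=-1),
        _zero_crossings(X),
        _count_peaks(X),
        np.percentile(X, 25, axis=-1),
        np.percentile(X, 75, axis=-1),
        mom["kurtosis"],
        mom["skew"],
    ]
    return np.stack(feats, axis=-1)


def _causal_filter(X: np.ndarray, filt: FilterSpec) -> np.ndarray:
    """Forward-only Butterworth, state initialised at the first sample."""
    b, a = filt.ba()
    zi = sps.lfilter_zi(b, a)
    zi_full = X[..., :1] * zi.reshape((1,) * (X.ndim - 1) + (-1,))
    y, _ = sps.lfilter(b, a, X, axis=-1, zi=zi_full)
    return y


def _freq_feature_block(X: np.ndarray, filt: FilterSpec) -> np.ndarray:
    """6 PSD features along the last axis; output (..., 6).

    PSD = one-sided periodogram of the filtered, mean-removed window.
    Spectral entropy uses the non-DC bins normalised to sum 1 (natural
    log); an all-zero spectrum scores 0 everywhere.
    """
    xf = _causal_filter(X, filt)
    xf = xf - xf.mean(axis=-1, keepdims=True)
    _, psd = sps.periodogram(xf, fs=filt.fs_hz, axis=-1)
    power = psd[..., 1:]  # non-DC bins
    total = power.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = power / np.where(total > 0, total, 1.0)[..., None]
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    entropy = np.where(total > 0, -plogp.sum(axis=-1), 0.0)
    feats = [
        _count_peaks(psd),
        psd.mean(axis=-1),
        np.sqrt((psd**2).mean(axis=-1)),
        np.median(psd, axis=-1),
        psd.std(axis=-1),
        entropy,
    ]
    return np.stack(feats, axis=-1)


def time_features(x: np.ndarray) -> np.ndarray:
    """13 time-domain features of one series (order = TIME_FEATURES)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("time_features expects a 1-D series of length >= 2")
    return _time_feature_block(x)


def freq_features(x: np.ndarray, filt: FilterSpec | None = None) -> np.ndarray:
    """6 frequency-domain features of one series (order = FREQ_FEATURES)."""
    filt = filt or FilterSpec()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("freq_features expects a 1-D series of length >= 8")
    return _freq_feature_block(x, filt)


def feature_names(side: str, mode: str) -> list[str]:
    """Deterministic ``signal__feature`` naming, N x 19 entries."""
    return [
        f"{sig}__{feat}"
        for sig in signal_names(side, mode)
        for feat in TIME_FEATURES + FREQ_FEATURES
    ]


def featurize(win: Window, side: str, mode: str, filt: FilterSpec | None = None) -> pd.Series:
    """Full feature vector of one window: N x 19 named values."""
    filt = filt or FilterSpec(fs_hz=win.rec.fs_hz)
    frame = featurize_windows([win], side, mode, filt)
    return frame.iloc[0]


def featurize_windows(
    windows: list[Window], side: str, mode: str, filt: FilterSpec | None = None
) -> pd.DataFrame:
    """Feature table for many equally-sized windows (vectorized)."""
    if not windows:
        return pd.DataFrame(columns=feature_names(side, mode))
    filt = filt or FilterSpec(fs_hz=windows[0].rec.fs_hz)

    # signal matrices are built once per recording, then sliced per window
    cache: dict[int, np.ndarray] = {}

    def full_matrix(rec) -> np.ndarray:
        key = id(rec)
        if key not in cache:
            cache[key] = _signal_frame(rec.data, side, mode).to_numpy().T  # (N, n)
        return cache[key]

    w = windows[0].w
    n_sig = full_matrix(windows[0].rec).shape[0]
    X = np.empty((len(windows), n_sig, w))
    for i, win in enumerate(windows):
        if win.w != w:
            raise ValueError("all windows must share one size")
        X[i] = full_matrix(win.rec)[:, win.start_sample : win.end_sample]
    tf = _time_feature_block(X)  # (n_windows, N, 13)
    ff = _freq_feature_block(X, filt)  # (n_windows, N, 6)
    all_feats = np.concatenate([tf, ff], axis=-1)  # (n_windows, N, 19)
    flat = all_feats.reshape(len(windows), -1)
    return pd.DataFrame(flat, columns=feature_names(side, mode))
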