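"""Time-domain sEMG features and the feature-major window descriptor.

Seven features are computed per channel of a window — mean absolute value
(MAV), root mean square (RMS), variance (VAR), simple square integral (SSI),
zero crossings (ZC), waveform length (WL) and slope sign changes (SSC) — and
assembled feature-major: for 8 channels, positions 1-8 are MAV of channels
1-8, 9-16 RMS, and so on, 56 values in all.

Magnitude features (MAV/RMS/VAR/SSI/WL) are invariant to full-wave
rectification by construction; ZC and SSC are computed on the un-rectified
signal, where they are informative (a rectified signal has essentially no
zero crossings).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import Window

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "FeatureVector",
    "mav",
    "rms",
    "var",
    "ssi",
    "zc",
    "wl",
    "ssc",
    "extract_features",
    "extract_matrix",
    "feature_names",
    "write_features",
    "read_features",
]

#: fixed feature order of the descriptor (feature-major layout)
FEATURE_NAMES: tuple[str, ...] = ("mav", "rms", "var", "ssi", "zc", "wl", "ssc")


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds and conventions for the count-type features.

    ``zc_threshold`` is an amplitude deadzone (normalized units) on the jump
    across a sign change; ``ssc_threshold`` a deadzone on the slope product at
    a local extremum.  Both suppress noise-floor counts and default to small
    nonzero values.  ``var_convention`` selects the zero-mean EMG variance
    (default) or the mean-centered sample variance.
    """

    zc_threshold: float = 0.01
    ssc_threshold: float = 1e-4
    var_convention: str = "zero-mean"  # or "centered"

    def __post_init__(self) -> None:
        if self.zc_threshold < 0 or self.ssc_threshold < 0:
            raise ValueError("feature thresholds must be >= 0")
        if self.var_convention not in ("zero-mean", "centered"):
            raise ValueError(f"unknown var_convention {self.var_convention!r}")


@dataclass
class FeatureVector:
    """The feature-major descriptor of one window (56 values for 8 channels)."""

    values: np.ndarray
    channel_count: int = 8
    window_ref: Window | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(FEATURE_NAMES) * self.channel_count,):
            raise ValueError(
                f"feature vector must have {len(FEATURE_NAMES)} x {self.channel_count} values"
            )


def _as_1d(x, min_len: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} expects a 1-D sample sequence")
    if x.size < min_len:
        raise ValueError(f"{name} needs at least {min_len} samples; got {x.size}")
    return x


def mav(x) -> float:
    """Mean absolute value: (1/N) sum |x_i|."""
    x = _as_1d(x, 1, "mav")
    return float(np.mean(np.abs(x)))


def rms(x) -> float:
    """Root mean square: sqrt((1/N) sum x_i^2)."""
    x = _as_1d(x, 1, "rms")
    return float(np.sqrt(np.mean(x * x)))


def var(x, config: FeatureConfig = FeatureConfig()) -> float:
    """Variance of the window.

    Zero-mean EMG convention (default): (1/(N-1)) sum x_i^2 — sEMG is
    zero-mean, so no mean is subtracted.  The "centered" convention subtracts
    the sample mean first.
    """
    x = _as_1d(x, 2, "var")
    if config.var_convention == "centered":
        x = x - x.mean()
    return float(np.sum(x * x) / (x.size - 1))


def ssi(x) -> float:
    """Simple square integral (signal strength): sum x_i^2 (= N * rms^2)."""
    x = _as_1d(x, 1, "ssi")
    return float(np.sum(x * x))


def zc(x, config: FeatureConfig = FeatureConfig()) -> int:
    """Zero crossings: sign changes between consecutive samples whose jump
    exceeds the amplitude deadzone."""
    x = _as_1d(x, 2, "zc")
    sign_change = np.sign(x[:-1]) != np.sign(x[1:])
    big_enough = np.abs(x[:-1] - x[1:]) >= config.zc_threshold
    return int(np.count_nonzero(sign_change & big_enough))


def wl(x) -> float:
    """Waveform length: cumulative absolute first difference sum |x_{i+1} - x_i|."""
    x = _as_1d(x, 2, "wl")
    return float(np.sum(np.abs(np.diff(x))))


def ssc(x, config: FeatureConfig = FeatureConfig()) -> int:
    """Slope sign changes: interior local extrema whose slope product clears
    the deadzone: count of i with (x_i - x_{i-1})(x_i - x_{i+1}) >= threshold."""
    x = _as_1d(x, 3, "ssc")
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    return int(np.count_nonzero(left * right >= config.ssc_threshold))


_FEATURE_FUNCS = {
    "mav": lambda x, cfg: mav(x),
    "rms": lambda x, cfg: rms(x),
    "var": lambda x, cfg: var(x, cfg),
    "ssi": lambda x, cfg: ssi(x),
    "zc": lambda x, cfg: zc(x, cfg),
    "wl": lambda x, cfg: wl(x),
    "ssc": lambda x, cfg: ssc(x, cfg),
}


def extract_features(
    window: Window, config: FeatureConfig = FeatureConfig(), channel_count: int | None = None
) -> FeatureVector:
    """Compute the feature-major descriptor of one window.

    The layout generalises to any channel count K (length 7*K), so 16-channel
    dual-armband data are handled without modification.
    """
    if channel_count is not None and window.channel_count != channel_count:
        raise ValueError(
            f"window has {window.channel_count} channels; expected {channel_count}"
        )
    if window.n_samples < 3:
        raise ValueError("window must have at least 3 samples per channel")
    k = window.channel_count
    values = np.empty(len(FEATURE_NAMES) * k)
    for fi, name in enumerate(FEATURE_NAMES):
        func = _FEATURE_FUNCS[name]
        for ch in range(k):
            values[fi * k + ch] = func(window.data[ch], config)
    return FeatureVector(values=values, channel_count=k, window_ref=window)


def extract_matrix(windows, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Feature matrix for a sequence of windows: one row per window."""
    return np.array([extract_features(w, config).values for w in windows])


def feature_names(channel_count: int = 8) -> list[str]:
    """Column names in layout order: ``mav_ch1 .. ssc_chK``."""
    return [f"{f}_ch{c + 1}" for f in FEATURE_NAMES for c in range(channel_count)]


def write_features(
    path: str | Path, features: np.ndarray, labels=None, channel_count: int = 8
) -> None:
    """Persist a feature matrix as CSV (one row per window, named columns)."""
    frame = pd.DataFrame(np.asarray(features, dtype=float), columns=feature_names(channel_count))
    if labels is not None:
        frame["label"] = [int(l) for l in labels]
    frame.to_csv(path, index=False, float_format="%.12g")


def read_features(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Load a feature CSV; returns ``(features, labels-or-None)``."""
    frame = pd.read_csv(path)
    labels = None
    if "label" in frame.columns:
        labels = frame.pop("label").to_numpy(dtype=int)
    return frame.to_numpy(dtype=float), labels
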