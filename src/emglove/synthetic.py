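"""Synthetic sEMG generator for hardware-free training and evaluation.

Real multi-channel sEMG at desk scale is well approximated, as far as
time-domain features are concerned, by band-limited zero-mean Gaussian noise
whose per-channel standard deviation encodes muscle activation: each gesture
is a distinct 8-channel activation pattern riding on a common noise floor.
The generator emulates exactly that — the classifier consumes only
second-order window statistics, so no motor-unit action-potential modelling
is attempted.

The six default activation profiles have pairwise-distinct channel supports,
with the pinch ("gripper") and thumb-up profiles deliberately the closest
pair — those two gestures are the ones most easily confused in practice.
A single ``separation`` knob scales every profile's distance from the relax
(noise-floor-only) profile: at 0 all gestures are distributionally identical;
at the default 1 they are cleanly separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .features import FeatureConfig, extract_matrix
from .signal import (
    DEFAULT_CHANNELS,
    DEFAULT_SAMPLE_RATE,
    EmgRecording,
    GestureLabel,
    Window,
    samples_per_window,
)

__all__ = [
    "GestureProfile",
    "SimConfig",
    "DEFAULT_PROFILES",
    "DEMO_SESSION_SCRIPT",
    "generate_window",
    "generate_dataset",
    "generate_session",
]


@dataclass
class GestureProfile:
    """Per-channel activation amplitudes in [0, 1] plus the tremor band that
    band-limits the carrier noise and the activation onset ramp."""

    amplitudes: np.ndarray
    tremor_band: tuple[float, float] = (10.0, 95.0)
    onset_ramp_ms: float = 150.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not np.all(np.isfinite(self.amplitudes)) or (self.amplitudes < 0).any():
            raise ValueError("profile amplitudes must be finite and >= 0")


#: hand-crafted activation patterns; relax is the noise floor, the fist
#: recruits nearly everything, and gripper/thumb-up are the closest pair.
DEFAULT_PROFILES: dict[GestureLabel, GestureProfile] = {
    GestureLabel.RELAX: GestureProfile(np.zeros(8)),
    GestureLabel.GRIPPER: GestureProfile(np.array([0.50, 0.60, 0.20, 0.00, 0.00, 0.10, 0.40, 0.30])),
    GestureLabel.THUMB_UP: GestureProfile(np.array([0.60, 0.50, 0.15, 0.00, 0.00, 0.00, 0.35, 0.40])),
    GestureLabel.GRIP: GestureProfile(np.array([0.40, 0.30, 0.50, 0.60, 0.50, 0.30, 0.20, 0.40])),
    GestureLabel.FIST: GestureProfile(np.array([0.80, 0.70, 0.90, 0.80, 0.70, 0.80, 0.90, 0.70])),
    GestureLabel.OPEN_HAND: GestureProfile(np.array([0.10, 0.20, 0.40, 0.70, 0.80, 0.60, 0.10, 0.00])),
}

#: the 40 s demonstration script: seven gesture blocks totalling exactly 40 s
#: (8000 samples at 200 Hz)
DEMO_SESSION_SCRIPT: list[tuple[GestureLabel, float]] = [
    (GestureLabel.RELAX, 4.50),
    (GestureLabel.FIST, 5.75),
    (GestureLabel.OPEN_HAND, 6.51),
    (GestureLabel.GRIPPER, 3.42),
    (GestureLabel.GRIP, 9.79),
    (GestureLabel.THUMB_UP, 5.49),
    (GestureLabel.RELAX, 4.54),
]


@dataclass
class SimConfig:
    """Study conditions for the generator.

    ``noise_floor`` is the baseline Gaussian sigma present on every channel;
    ``amplitude_gain`` converts a profile amplitude of 1 at ``separation`` 1
    into an activation sigma of 0.3 normalized units, keeping samples
    comfortably inside [-1, 1]; ``separation`` >= 0 scales inter-profile
    distance (0 collapses every gesture onto the relax distribution).
    """

    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    noise_floor: float = 0.02
    separation: float = 1.0
    amplitude_gain: float = 0.3
    sample_rate: float = DEFAULT_SAMPLE_RATE
    channel_count: int = DEFAULT_CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation < 0 or self.noise_floor < 0:
            raise ValueError("separation and noise_floor must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "noise_floor": self.noise_floor,
            "separation": self.separation,
            "amplitude_gain": self.amplitude_gain,
            "sample_rate": self.sample_rate,
            "channel_count": self.channel_count,
            "seed": self.seed,
            "profiles": {
                g.name.lower(): {
                    "amplitudes": [float(a) for a in p.amplitudes],
                    "tremor_band": list(p.tremor_band),
                    "onset_ramp_ms": p.onset_ramp_ms,
                }
                for g, p in self.profiles.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text())
        profiles = {
            GestureLabel[name.upper()]: GestureProfile(
                amplitudes=np.asarray(spec["amplitudes"], dtype=float),
                tremor_band=tuple(spec.get("tremor_band", (10.0, 95.0))),
                onset_ramp_ms=float(spec.get("onset_ramp_ms", 150.0)),
            )
            for name, spec in doc.get("profiles", {}).items()
        } or dict(DEFAULT_PROFILES)
        return cls(
            profiles=profiles,
            noise_floor=float(doc.get("noise_floor", 0.02)),
            separation=float(doc.get("separation", 1.0)),
            amplitude_gain=float(doc.get("amplitude_gain", 0.3)),
            sample_rate=float(doc.get("sample_rate", DEFAULT_SAMPLE_RATE)),
            channel_count=int(doc.get("channel_count", DEFAULT_CHANNELS)),
            seed=int(doc.get("seed", 0)),
        )


def _bandlimited_noise(rng, n_channels: int, n_samples: int,
                       band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-variance white Gaussian noise restricted to ``band`` by FFT masking.

    The output RMS is sqrt(kept-power fraction) — close to sqrt(band width /
    Nyquist) for flat spectra.
    """
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec[:, ~mask] = 0.0
    return np.fft.irfft(spec, n=n_samples, axis=1)


def _channel_sigmas(gesture: GestureLabel, config: SimConfig) -> np.ndarray:
    profile = config.profiles[GestureLabel(gesture)]
    return config.noise_floor + config.amplitude_gain * config.separation * profile.amplitudes


def generate_window(gesture: GestureLabel, config: SimConfig | None = None,
                    seed: int | None = None, window_ms: float = 300.0) -> Window:
    """One labeled-gesture window: per-channel band-limited Gaussian noise at
    the gesture's activation sigma, clipped to [-1, 1].  Same seed, same window."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = samples_per_window(window_ms, config.sample_rate)
    profile = config.profiles[GestureLabel(gesture)]
    noise = _bandlimited_noise(rng, config.channel_count, n,
                               profile.tremor_band, config.sample_rate)
    data = noise * _channel_sigmas(gesture, config)[:, None]
    return Window(data=np.clip(data, -1.0, 1.0), source_offset=0)


def generate_dataset(
    n_per_gesture: int,
    config: SimConfig | None = None,
    feature_config: FeatureConfig | None = None,
    seed: int | None = None,
    window_ms: float = 300.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A balanced featurized dataset: ``n_per_gesture`` windows per class.

    Rows are grouped by gesture in label order (the per-gesture acquisition
    blocks of the protocol); 250 per gesture gives the 1,500-sample database,
    600 per gesture the 3600 x 56 one.  Returns ``(features, labels)``.
    """
    config = config or SimConfig()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    gestures = sorted(config.profiles, key=int)
    children = root.spawn(len(gestures) * n_per_gesture)
    windows, labels = [], []
    i = 0
    for g in gestures:
        for _ in range(n_per_gesture):
            s = int(children[i].generate_state(1)[0] % (2**31))
            windows.append(generate_window(g, config, seed=s, window_ms=window_ms))
            labels.append(int(g))
            i += 1
    X = extract_matrix(windows, feature_config or FeatureConfig())
    return X, np.asarray(labels, dtype=int)


def generate_session(
    script: list[tuple[GestureLabel, float]],
    config: SimConfig | None = None,
    seed: int | None = None,
) -> EmgRecording:
    """A scripted session: concatenated gesture blocks with onset ramps.

    ``script`` is a list of ``(gesture, duration_s)``; the activation
    component of each block ramps up linearly over the profile's onset ramp.
    The returned recording carries a timeline annotation per block.
    """
    if not script:
        raise ValueError("session script is empty")
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.sample_rate
    blocks, timeline = [], []
    t = 0.0
    for gesture, duration in script:
        if duration <= 0:
            raise ValueError("block durations must be positive")
        gesture = GestureLabel(gesture)
        n_b = int(round(duration * fs))
        profile = config.profiles[gesture]
        noise = _bandlimited_noise(rng, config.channel_count, n_b,
                                   profile.tremor_band, fs)
        ramp_n = max(1, int(round(profile.onset_ramp_ms * fs / 1000.0)))
        ramp = np.minimum(np.arange(1, n_b + 1) / ramp_n, 1.0)
        act = config.amplitude_gain * config.separation * profile.amplitudes
        sigma_t = config.noise_floor + act[:, None] * ramp[None, :]
        blocks.append(noise * sigma_t)
        timeline.append((t, t + n_b / fs, gesture))
        t += n_b / fs
    data = np.clip(np.concatenate(blocks, axis=1), -1.0, 1.0)
    return EmgRecording(data=data, sample_rate=fs, timeline=timeline)
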