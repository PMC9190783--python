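"""Data model, I/O, rectification and adjacent windowing for multi-channel sEMG.

Signals are stored amplitude-normalized in [-1, 1] (the convention of consumer
armband SDKs, which deliver filtered, normalized channels); the default stream
is 8 channels at 200 Hz.  Recordings may carry a single gesture label or a
timeline of ``(start_s, end_s, label)`` annotations for scripted sessions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "GestureLabel",
    "N_GESTURES",
    "EmgRecording",
    "Window",
    "samples_per_window",
    "rectify",
    "segment",
    "window_labels",
    "read_session",
    "write_session",
]

DEFAULT_SAMPLE_RATE = 200.0
DEFAULT_CHANNELS = 8
#: tiny slack for float round-off when validating the [-1, 1] amplitude range
_AMPLITUDE_TOL = 1e-9


class GestureLabel(IntEnum):
    """The six hand gestures, with fixed integer codes used for one-hot targets."""

    RELAX = 0
    GRIPPER = 1      # pinch: thumb taps the index finger
    THUMB_UP = 2     # thumb extension
    GRIP = 3         # object-holding posture
    FIST = 4         # closed hand
    OPEN_HAND = 5    # finger extension


N_GESTURES = len(GestureLabel)


class SignalError(ValueError):
    """Raised for invalid sEMG data or malformed session files."""


@dataclass
class EmgRecording:
    """A channel-major block of normalized sEMG samples.

    Parameters
    ----------
    data
        ``(channels, samples)`` float array, all values finite and in [-1, 1].
    sample_rate
        Stream rate in Hz (200 for the armband this models).
    label
        Optional single gesture label for the whole recording.
    timeline
        Optional ordered, non-overlapping ``(start_s, end_s, label)`` list for
        scripted sessions.
    """

    data: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    label: GestureLabel | None = None
    timeline: list[tuple[float, float, GestureLabel]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SignalError(f"data must be 2-D (channels, samples); got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise SignalError("non-finite samples in recording")
        amax = float(np.abs(self.data).max(initial=0.0))
        if amax > 1.0 + _AMPLITUDE_TOL:
            raise SignalError(f"samples exceed normalized range [-1, 1] (max |x| = {amax:g})")
        if self.sample_rate <= 0:
            raise SignalError("sample_rate must be positive")
        if self.timeline is not None:
            prev_end = -np.inf
            for start, end, _lab in self.timeline:
                if end <= start:
                    raise SignalError(f"empty/reversed timeline interval ({start}, {end})")
                if start < prev_end - 1e-12:
                    raise SignalError("timeline intervals overlap or are unordered")
                prev_end = end

    @property
    def channel_count(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class Window:
    """One adjacent-segmentation window: ``(channels, N)`` samples."""

    data: np.ndarray
    source_offset: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SignalError("window data must be 2-D (channels, N)")

    @property
    def channel_count(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def samples_per_window(window_ms: float, sample_rate: float) -> int:
    """Window length in samples: ``round(window_ms * sample_rate / 1000)``.

    300 ms at 200 Hz gives 60 samples.
    """
    n = int(round(window_ms * sample_rate / 1000.0))
    if n < 1:
        raise SignalError(f"window of {window_ms} ms holds no samples at {sample_rate} Hz")
    return n


def rectify(recording: EmgRecording) -> EmgRecording:
    """Full-wave rectification: every sample replaced by its absolute value."""
    return replace(recording, data=np.abs(recording.data))


def segment(recording: EmgRecording, window_ms: float = 300.0) -> list[Window]:
    """Split a recording into adjacent (disjoint, contiguous) fixed-length windows.

    The trailing partial window, if any, is discarded; padding would fabricate
    signal.  Raises :class:`SignalError` if the recording is shorter than one
    window.
    """
    n = samples_per_window(window_ms, recording.sample_rate)
    n_windows = recording.n_samples // n
    if n_windows == 0:
        raise SignalError(
            f"recording of {recording.n_samples} samples is shorter than one "
            f"{window_ms} ms window ({n} samples)"
        )
    return [
        Window(data=recording.data[:, i * n : (i + 1) * n], source_offset=i * n)
        for i in range(n_windows)
    ]


def window_labels(
    recording: EmgRecording, windows: Sequence[Window]
) -> tuple[list[GestureLabel], np.ndarray]:
    """Label each window from the recording's timeline by majority vote.

    A window straddling a gesture boundary carries the label covering most of
    its samples (ties resolved in favour of the earlier gesture); such windows
    are flagged in the returned boolean mask so callers may exclude them.
    """
    if recording.timeline is None:
        if recording.label is None:
            raise SignalError("recording has neither a timeline nor a label")
        labels = [recording.label] * len(windows)
        return labels, np.zeros(len(windows), dtype=bool)

    fs = recording.sample_rate
    labels: list[GestureLabel] = []
    boundary = np.zeros(len(windows), dtype=bool)
    for k, w in enumerate(windows):
        t0 = w.source_offset / fs
        t1 = (w.source_offset + w.n_samples) / fs
        overlaps: list[tuple[float, GestureLabel]] = []
        for start, end, lab in recording.timeline:
            ov = min(t1, end) - max(t0, start)
            if ov > 1e-12:
                overlaps.append((ov, GestureLabel(lab)))
        if not overlaps:
            raise SignalError(f"window at {t0:.3f}s not covered by the timeline")
        best = max(range(len(overlaps)), key=lambda i: overlaps[i][0])
        labels.append(overlaps[best][1])
        boundary[k] = len(overlaps) > 1
    return labels, boundary


# ---------------------------------------------------------------------------
# Session I/O.  Text dialect: CSV with a `# sample_rate: <Hz>` comment line,
# then a mandatory header `ch1..chK[,label]`, one row per sample.  Binary
# dialect: HDF5 with dataset `emg` (float64, channels x samples), attributes
# `sample_rate`/`channels`, optional `timeline` dataset.
# ---------------------------------------------------------------------------


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise SignalError(f"cannot infer session format from suffix {suffix!r}; pass format=")


def _sample_labels(recording: EmgRecording) -> np.ndarray | None:
    """Per-sample integer labels from the timeline or the scalar label."""
    if recording.timeline is not None:
        out = np.full(recording.n_samples, -1, dtype=int)
        fs = recording.sample_rate
        for start, end, lab in recording.timeline:
            i0 = int(round(start * fs))
            i1 = int(round(end * fs))
            out[i0:i1] = int(lab)
        return out
    if recording.label is not None:
        return np.full(recording.n_samples, int(recording.label), dtype=int)
    return None


def _timeline_from_sample_labels(labels: np.ndarray, fs: float):
    """Reconstruct scalar label / timeline from a per-sample label column."""
    runs: list[tuple[float, float, GestureLabel]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start / fs, i / fs, GestureLabel(int(labels[start]))))
            start = i
    if len(runs) == 1:
        return runs[0][2], None
    return None, runs


def write_session(recording: EmgRecording, path: str | Path, format: str | None = None) -> None:
    """Write a recording to disk in the CSV or HDF5 session dialect."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        cols = {f"ch{i + 1}": recording.data[i] for i in range(recording.channel_count)}
        frame = pd.DataFrame(cols)
        labels = _sample_labels(recording)
        if labels is not None:
            frame["label"] = labels
        buf = io.StringIO()
        buf.write(f"# sample_rate: {recording.sample_rate:g}\n")
        frame.to_csv(buf, index=False, float_format="%.12g")
        path.write_text(buf.getvalue())
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("emg", data=recording.data.astype(np.float64))
            dset.attrs["sample_rate"] = recording.sample_rate
            dset.attrs["channels"] = recording.channel_count
            if recording.label is not None:
                dset.attrs["label"] = int(recording.label)
            if recording.timeline is not None:
                tl = np.array(
                    [(s, e, int(l)) for s, e, l in recording.timeline], dtype=np.float64
                )
                f.create_dataset("timeline", data=tl)
    else:
        raise SignalError(f"unknown session format {fmt!r}")


def read_session(
    path: str | Path, format: str | None = None, channel_count: int | None = None
) -> EmgRecording:
    """Read a session written by :func:`write_session`.

    ``channel_count``, if given, is enforced against the file's channel count.
    Malformed headers, channel mismatches and out-of-range amplitudes raise
    :class:`SignalError`.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path) as f:
            first = f.readline().strip()
            if not first.startswith("# sample_rate:"):
                raise SignalError(
                    f"{path}: missing '# sample_rate:' header line (no format sniffing)"
                )
            try:
                sample_rate = float(first.split(":", 1)[1])
            except ValueError as exc:
                raise SignalError(f"{path}: unparseable sample rate in {first!r}") from exc
            frame = pd.read_csv(f)
        ch_cols = [c for c in frame.columns if c.startswith("ch")]
        expected = [f"ch{i + 1}" for i in range(len(ch_cols))]
        if ch_cols != expected:
            raise SignalError(f"{path}: channel columns {ch_cols} are not contiguous ch1..chK")
        data = frame[ch_cols].to_numpy(dtype=float).T
        label = timeline = None
        if "label" in frame.columns:
            label, timeline = _timeline_from_sample_labels(
                frame["label"].to_numpy(dtype=int), sample_rate
            )
    elif fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "emg" not in f:
                raise SignalError(f"{path}: missing 'emg' dataset")
            dset = f["emg"]
            if "sample_rate" not in dset.attrs or "channels" not in dset.attrs:
                raise SignalError(f"{path}: missing sample_rate/channels attributes")
            data = dset[...]
            sample_rate = float(dset.attrs["sample_rate"])
            if int(dset.attrs["channels"]) != data.shape[0]:
                raise SignalError(f"{path}: channels attribute disagrees with data shape")
            label = GestureLabel(int(dset.attrs["label"])) if "label" in dset.attrs else None
            timeline = None
            if "timeline" in f:
                timeline = [
                    (float(s), float(e), GestureLabel(int(l))) for s, e, l in f["timeline"][...]
                ]
    else:
        raise SignalError(f"unknown session format {fmt!r}")

    if channel_count is not None and data.shape[0] != channel_count:
        raise SignalError(
            f"{path}: expected {channel_count} channels, file has {data.shape[0]}"
        )
    return EmgRecording(data=data, sample_rate=sample_rate, label=label, timeline=timeline)
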