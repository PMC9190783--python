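"""Shared classifier types."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..signal import GestureLabel, N_GESTURES

__all__ = ["ClassScores", "one_hot", "argmax_label"]


@dataclass
class ClassScores:
    """A 6-element score vector over the gesture classes, indexed by label code."""

    scores: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be a 1-D vector")
        if self.normalized:
            if (self.scores < -1e-9).any() or (self.scores > 1 + 1e-9).any():
                raise ValueError("normalized scores must lie in [0, 1]")
            if abs(float(self.scores.sum()) - 1.0) > 1e-9:
                raise ValueError("normalized scores must sum to 1")

    @property
    def label(self) -> GestureLabel:
        return argmax_label(self.scores)


def argmax_label(scores: np.ndarray) -> GestureLabel:
    """Argmax with the lowest-index tie-break (np.argmax's convention)."""
    return GestureLabel(int(np.argmax(scores)))


def one_hot(labels, n_classes: int = N_GESTURES) -> np.ndarray:
    """Targets as arrays of zeros with a 1 at the class index."""
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out
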