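"""Reference generation for the tendon-driven rehabilitation glove.

The recognized gesture maps to six per-actuator target displacements in mm
(actuator order: thumb flexion, thumb opposition, index, middle, ring,
pinky).  That instantaneous "reference intention" is not what the actuators
receive; a ramped reference approaches it with one of two adjustable
increments — a coarse step while the reference is far from the measured
actuator position, a fine step near it, so the reference stays followable —
and never overshoots.  For the antagonistic tendon pairs, extension
references are the stroke-complement of the flexion references.

A first-order lag plant with asymmetric time constants (fast contraction,
slow relaxation — thermally driven actuators must cool to extend) is bundled
as a test double for closed-loop simulation; it is not an actuator model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .classifiers import ClassScores, EnsembleModel, argmax_label, predict_ensemble
from .features import extract_features
from .signal import EmgRecording, GestureLabel, segment

__all__ = [
    "ACTUATOR_NAMES",
    "GestureTargetMap",
    "ReferenceState",
    "FirstOrderPlant",
    "gesture_targets",
    "step_reference",
    "antagonistic_duplicate",
    "run_session",
]

ACTUATOR_NAMES = ("thumb_flexion", "thumb_opposition", "index", "middle", "ring", "pinky")
DEFAULT_STROKE_MM = 60.0


def _default_targets() -> dict:
    s = DEFAULT_STROKE_MM
    return {
        GestureLabel.RELAX: np.zeros(6),
        GestureLabel.OPEN_HAND: np.zeros(6),
        GestureLabel.FIST: np.full(6, s),
        GestureLabel.GRIP: np.full(6, 40.0),
        GestureLabel.GRIPPER: np.array([40.0, 40.0, 40.0, 40.0, s, s]),
        GestureLabel.THUMB_UP: np.array([0.0, 0.0, s, s, s, s]),
    }


@dataclass
class GestureTargetMap:
    """Gesture -> 6-vector of flexion displacement targets (mm).

    Defaults: fist flexes every finger to the full 60 mm stroke; grip holds
    all actuators at 40 mm; the pinch ("gripper") holds thumb/index/middle at
    40 mm with ring and pinky fully flexed; thumb-up releases both thumb
    actuators and flexes the rest; open hand and relax release everything.
    """

    targets: dict = field(default_factory=_default_targets)
    stroke: float = DEFAULT_STROKE_MM

    def __post_init__(self) -> None:
        for g, t in self.targets.items():
            t = np.asarray(t, dtype=float)
            if t.shape != (6,):
                raise ValueError(f"target for {g} must be a 6-vector")
            if (t < 0).any() or (t > self.stroke).any():
                raise ValueError(f"target for {g} outside [0, {self.stroke}] mm")
            self.targets[g] = t


@dataclass
class ReferenceState:
    """The six ramped actuator references plus the measured positions.

    ``coarse_increment`` and ``fine_increment`` are mm per update step (one
    update every 50 ms by default in :func:`run_session`); the fine step is
    used whenever the reference is within ``near_threshold`` of the measured
    position.
    """

    reference: np.ndarray = field(default_factory=lambda: np.zeros(6))
    position: np.ndarray = field(default_factory=lambda: np.zeros(6))
    coarse_increment: float = 2.0
    fine_increment: float = 0.5
    near_threshold: float = 5.0
    stroke: float = DEFAULT_STROKE_MM

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.reference.shape != (6,) or self.position.shape != (6,):
            raise ValueError("reference and position must be 6-vectors")
        for name in ("reference", "position"):
            v = getattr(self, name)
            if (v < -1e-9).any() or (v > self.stroke + 1e-9).any():
                raise ValueError(f"{name} outside [0, {self.stroke}] mm")
        if not (0 < self.fine_increment <= self.coarse_increment):
            raise ValueError("need 0 < fine_increment <= coarse_increment")


def gesture_targets(gesture: GestureLabel, target_map: GestureTargetMap | None = None) -> np.ndarray:
    """The 6-vector of flexion targets (mm) mapped to a gesture."""
    target_map = target_map or GestureTargetMap()
    gesture = GestureLabel(gesture)
    if gesture not in target_map.targets:
        raise KeyError(f"no target mapped for gesture {gesture!r}")
    return target_map.targets[gesture].copy()


def step_reference(
    state: ReferenceState,
    scores: ClassScores | np.ndarray,
    target_map: GestureTargetMap | None = None,
) -> ReferenceState:
    """Advance the six references one update toward the recognized gesture's
    targets.

    Per actuator the increment is coarse while |reference - position| exceeds
    the near threshold, fine otherwise; the move is clamped at the target, so
    the approach is monotone and the reference stays in [0, stroke].  Returns
    a new state (position unchanged).
    """
    raw = getattr(scores, "scores", scores)
    gesture = argmax_label(np.asarray(raw, dtype=float))
    target = gesture_targets(gesture, target_map)
    inc = np.where(
        np.abs(state.reference - state.position) > state.near_threshold,
        state.coarse_increment,
        state.fine_increment,
    )
    delta = np.clip(target - state.reference, -inc, inc)
    new_ref = np.clip(state.reference + delta, 0.0, state.stroke)
    return replace(state, reference=new_ref)


def antagonistic_duplicate(reference: np.ndarray, stroke: float = DEFAULT_STROKE_MM) -> np.ndarray:
    """Extend the 6 flexion references with their 6 extension complements:
    ``extension_i = stroke - flexion_i`` (flexion first, then extension)."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (6,):
        raise ValueError("expected a 6-vector of flexion references")
    return np.concatenate([reference, stroke - reference])


@dataclass
class FirstOrderPlant:
    """First-order lag follower with asymmetric time constants (s).

    Contraction (position rising toward the reference) is fast; relaxation is
    slow, mimicking actuators that must shed heat to extend.  A closed-loop
    test double only.
    """

    tau_contract: float = 0.8
    tau_relax: float = 2.0
    stroke: float = DEFAULT_STROKE_MM

    def step(self, position: np.ndarray, reference: np.ndarray, dt: float) -> np.ndarray:
        position = np.asarray(position, dtype=float)
        reference = np.asarray(reference, dtype=float)
        tau = np.where(reference >= position, self.tau_contract, self.tau_relax)
        alpha = 1.0 - np.exp(-dt / tau)
        return np.clip(position + alpha * (reference - position), 0.0, self.stroke)


def run_session(
    model: EnsembleModel,
    recording: EmgRecording,
    state: ReferenceState | None = None,
    target_map: GestureTargetMap | None = None,
    plant: FirstOrderPlant | Callable | None = None,
    window_ms: float = 300.0,
    update_ms: float = 50.0,
    smoothing: int = 0,
) -> pd.DataFrame:
    """Closed-loop run: classify each window, ramp the references, advance the
    plant, log the trace.

    Each window drives ``window_ms / update_ms`` reference sub-steps (6 at
    the defaults).  ``smoothing`` > 1 replaces the instantaneous gesture with
    a majority vote over the last ``smoothing`` windows (earliest-gesture
    tie-break), damping transition misclassifications; default off.
    Returns a DataFrame with time_s, gesture, ref_1..6 and pos_1..6 columns,
    one row per sub-step.
    """
    state = state or ReferenceState()
    target_map = target_map or GestureTargetMap()
    plant = plant or FirstOrderPlant(stroke=state.stroke)
    substeps = max(1, int(round(window_ms / update_ms)))
    dt = update_ms / 1000.0

    model.reset_state()
    windows = segment(recording, window_ms)
    rows = []
    recent: list[int] = []
    for w in windows:
        fv = extract_features(w, model.feature_config)
        label, _scores = predict_ensemble(model, fv)
        recent.append(int(label))
        if smoothing > 1:
            tail = recent[-smoothing:]
            label = GestureLabel(int(np.bincount(tail).argmax()))
        vote = np.zeros(len(GestureLabel))
        vote[int(label)] = 1.0
        for k in range(substeps):
            state = step_reference(state, vote, target_map)
            new_pos = plant.step(state.position, state.reference, dt)
            new_pos = np.asarray(new_pos, dtype=float)
            if (new_pos < -1e-9).any() or (new_pos > state.stroke + 1e-9).any():
                import warnings

                warnings.warn("plant returned out-of-range positions; clamped", stacklevel=2)
                new_pos = np.clip(new_pos, 0.0, state.stroke)
            state = replace(state, position=new_pos)
            t = (w.source_offset / recording.sample_rate) + (k + 1) * dt
            row = {"time_s": t, "gesture": int(label)}
            row.update({f"ref_{i + 1}": state.reference[i] for i in range(6)})
            row.update({f"pos_{i + 1}": state.position[i] for i in range(6)})
            rows.append(row)
    return pd.DataFrame(rows)
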