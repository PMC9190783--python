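"""Closed-loop demo: classify a 40 s scripted session and ramp the glove
references.

Trains a small ensemble, generates the seven-block demonstration session
(relax, fist, open hand, gripper, grip, thumb up, relax), then per 300 ms
window classifies the gesture and advances the six actuator references with
the coarse/fine increment policy against a first-order plant.  Prints, per
block, the recognized plateau and the mapped target displacement.
"""

import warnings

import numpy as np

from emglove import generate_dataset, generate_session, run_session, train_ensemble
from emglove.reference import ACTUATOR_NAMES, gesture_targets
from emglove.synthetic import DEMO_SESSION_SCRIPT

warnings.filterwarnings("ignore")

X, y = generate_dataset(60, seed=11)
model = train_ensemble(X, y, seed=11)

recording = generate_session(DEMO_SESSION_SCRIPT, seed=42)
trace = run_session(model, recording)
ref_cols = [f"ref_{i}" for i in range(1, 7)]

print(f"session: {recording.duration_s:.0f} s, {recording.n_samples} samples, "
      f"{len(trace)} reference updates\n")
print(f"{'block':>10s} {'interval':>16s}   final reference (mm)          target")
for t0, t1, gesture in recording.timeline:
    tail = trace[(trace.time_s > t1 - 0.8) & (trace.time_s <= t1 - 0.3 + 1e-9)]
    final = tail[ref_cols].to_numpy()[-1]
    target = gesture_targets(gesture)
    print(f"{gesture.name.lower():>10s} {t0:6.2f}-{t1:6.2f} s   "
          + " ".join(f"{v:4.0f}" for v in final)
          + "   " + " ".join(f"{v:4.0f}" for v in target))

refs = trace[ref_cols].to_numpy()
print(f"\nreference bounds: [{refs.min():.1f}, {refs.max():.1f}] mm "
      f"(actuator order: {', '.join(ACTUATOR_NAMES)})")
print("Each reference ramps to its target with a 2 mm step while far from the\n"
      "measured position and a 0.5 mm step near it, and never overshoots.")
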