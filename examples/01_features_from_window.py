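"""Extract the 56-value time-domain descriptor from one 300 ms sEMG window.

Generates a synthetic fist-gesture window (8 channels, 200 Hz, 60 samples),
computes the seven per-channel features and prints the feature-major layout:
positions 1-8 hold MAV per channel, 9-16 RMS, and so on through SSC.
"""

import numpy as np

from emglove import GestureLabel, extract_features, generate_window
from emglove.features import FEATURE_NAMES

window = generate_window(GestureLabel.FIST, seed=1)
fv = extract_features(window)

print(f"window shape: {window.data.shape} (channels x samples)")
print(f"feature vector length: {fv.values.size}\n")
for fi, name in enumerate(FEATURE_NAMES):
    block = fv.values[fi * 8 : (fi + 1) * 8]
    print(f"{name:>4s} (positions {fi * 8 + 1:2d}-{fi * 8 + 8:2d}): "
          + " ".join(f"{v:8.4f}" for v in block))
print(
    "\nMagnitude features (mav/rms/var/ssi/wl) scale with muscle activation;\n"
    "zc/ssc count sign changes and local extrema of the raw oscillation."
)
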