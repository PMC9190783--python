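# emglove

Surface-EMG hand-gesture recognition and reference-trajectory generation for
a tendon-driven hand-rehabilitation glove — a complete, hardware-free
re-implementation of the classification and high-level control stack, with a
synthetic signal generator standing in for the armband.

## The problem

Myoelectric control of rehabilitation devices needs two things: a classifier
that recognizes the wearer's movement intention from forearm sEMG in real
time, and a rule that converts the recognized gesture into setpoints the
device's actuators can follow. This package implements both for six hand
gestures (relax, gripper/pinch, thumb up, grip, fist, open hand) recorded
from an 8-channel, 200 Hz armband whose SDK delivers filtered signals
normalized to [-1, 1].

## The method

**Windowing and features.** The stream is cut into adjacent (non-overlapping)
300 ms windows — 60 samples per channel. Seven time-domain features are
computed per channel: mean absolute value (MAV), root mean square (RMS),
variance (VAR, zero-mean convention), simple square integral (SSI), zero
crossings (ZC), waveform length (WL) and slope sign changes (SSC). The 56
values are laid out feature-major: positions 1–8 are MAV of channels 1–8,
9–16 RMS, … 49–56 SSC.

**Ensemble classifier.** Two sub-classifiers run in parallel on the feature
vector x ∈ ℝ⁵⁶:

- *Kernel naive Bayes*: P(c | x) ∝ P(c) ∏₍f₎ p̂₍c,f₎(x_f), where each
  p̂₍c,f₎ is a one-dimensional Gaussian kernel density estimate
  (normal-reference bandwidth, floored) fitted per class and feature — sEMG
  feature distributions are not Gaussian, so a parametric likelihood is
  avoided. Trained with stratified 5-fold cross-validation.
- *Feedforward pattern-recognition net*: 56 → 8 (tanh) → 6 (softmax), trained
  full-batch with scaled conjugate gradient on cross-entropy against one-hot
  targets, with a stratified 70/15/15 train/validation/test split and
  validation early stopping.

Their two 6-element posteriors are concatenated into a 12-vector that feeds a
*layer-recurrent network* (12 → 10 → 6) whose hidden layer receives its own
delay-1 activations, giving one-step memory across consecutive windows —
consecutive gestures are strongly autocorrelated and the recurrence exploits
that. It is trained on the unrolled sequence with Levenberg–Marquardt on the
mean-squared error to one-hot targets. The ensemble's argmax is the final
gesture.

**Reference generation.** Each gesture maps to six actuator displacement
targets in mm (actuator order: thumb flexion, thumb opposition, index,
middle, ring, pinky; stroke 60 mm): fist → all 60, grip → all 40, gripper →
(40, 40, 40, 40, 60, 60), thumb up → (0, 0, 60, 60, 60, 60), open hand and
relax → all 0. A ramped reference approaches the target with a coarse 2 mm
step while far (> 5 mm) from the measured actuator position and a fine
0.5 mm step near it, never overshooting; extension-actuator references are
the 60 mm complement of the flexion references (antagonistic tendon pairs).

**Synthetic signals.** Each gesture is an 8-channel activation-amplitude
profile modulating band-limited (10–95 Hz) zero-mean Gaussian noise over a
common noise floor; a `separation` knob scales class separability from 0
(all gestures identical) upward. See `docs/methods.md` for what this does
and does not emulate.

## Worked example

`python examples/02_train_and_evaluate.py` trains on 60 synthetic windows per
gesture and evaluates on a fresh set of 60 per gesture:

```
trained on 360 windows (kernel-NB 5-fold CV accuracy 1.000)

confusion matrix (rows = predicted, columns = true):
                 relax    gripper   thumb_up       grip       fist  open_hand
      relax         60          0          0          0          0          0
    gripper          0         60          0          0          0          0
   ...
accuracy: 1.0000
macro: precision 1.0000 recall 1.0000 f1 1.0000

kernel-NB alone : 1.000
feedforward net : 0.989
ensemble (LRN)  : 1.000
```

The numbers are held-out classification rates per stage; the fusion net must
match or beat the better sub-classifier. `examples/01_features_from_window.py`
prints the 56-value feature layout for one window, and
`examples/03_closed_loop_session.py` runs a scripted 40 s session through
classify → reference → plant and prints, per gesture block, the plateau the
six references reach against the mapped targets.

The same workflow is scriptable from a shell:

```sh
emglove acquire --seed 5 --n-per-gesture 100 --out train.csv
emglove train   --features train.csv --seed 5 --out model.h5
emglove eval    --model model.h5 --features eval.csv
emglove run     --model model.h5 --out trace.csv
```

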