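# Methods

This note documents the models, the synthetic study conditions, the numerical
choices, and the limits of what the test suite demonstrates.

## Signal model and windowing

Recordings are channel-major float arrays, amplitude-normalized to [-1, 1]
(the armband SDK's convention; importers of integer formats must rescale,
e.g. signed 8-bit by 1/128). The stream rate is 200 Hz and the default
channel count 8, but nothing in the feature or classifier code assumes 8 —
a 16-channel (dual-armband) window yields a 112-value descriptor unchanged.

Segmentation is adjacent: disjoint, contiguous 300 ms windows
(`round(300 · 200 / 1000)` = 60 samples); the trailing partial window is
dropped rather than padded, because padding would fabricate signal. Windows
straddling a gesture boundary in scripted sessions take the majority label
(ties to the earlier gesture) and are flagged so callers can exclude them.

Full-wave rectification is exposed as an operation but is *not* applied
before feature extraction: the five magnitude features are invariant to it
by construction, while ZC and SSC are degenerate on a rectified signal
(essentially zero crossings remain). The counts are therefore computed on
the raw window — the only reading under which they carry information.

## Features

Per channel: MAV = (1/N)Σ|xᵢ|; RMS = √((1/N)Σxᵢ²); VAR = (1/(N−1))Σxᵢ²
under the zero-mean EMG convention (sEMG has no DC component; a
mean-centered variant is available via `FeatureConfig`); SSI = Σxᵢ²;
WL = Σ|xᵢ₊₁−xᵢ|; ZC counts sign changes whose amplitude jump clears a
deadzone (default 0.01 normalized units); SSC counts interior points with
(xᵢ−xᵢ₋₁)(xᵢ−xᵢ₊₁) ≥ a slope-product deadzone (default 1e−4). The deadzones
suppress noise-floor counts and are configurable; both default values are
conventional small thresholds, not fitted quantities. WL and SSC follow the
standard time-domain feature-set definitions (waveform length, slope sign
changes) that the abbreviations denote in the EMG literature.

## Classifiers

**Kernel naive Bayes.** Per class c and feature f, a 1-D Gaussian KDE over
the training values with normal-reference bandwidth
h = σ̂ (4/(3n))^{1/5}, σ̂ = min(std, IQR/1.349), floored at 1e−4 (a
zero-variance feature triggers the floor and a warning). Posteriors are
computed in log space; each per-feature density is floored at 1e−300 before
the log so an outlying feature cannot produce −∞. Fitting is
order-independent; prediction matches a brute-force density-product oracle
to 1e−10 (tested). Training reports stratified 5-fold cross-validation
accuracy; the returned model is refit on all data.

**Feedforward net (56→8→6).** Hidden tanh, softmax output, cross-entropy
loss, full-batch scaled conjugate gradient (Møller's algorithm, implemented
in-package), at most 1000 iterations with validation patience 6. Inputs are
z-scored using the training split's statistics (the 56 features span four
orders of magnitude; the net does not train unscaled) and the
standardization is stored in the model. Splits are stratified 70/15/15 with
per-class flooring: train = ⌊0.70 n_c⌋, validation = ⌊0.15 n_c⌋, test the
remainder — one undivided group of 250 therefore splits 175/37/38.
Weight initialization is Glorot-uniform from the run's seed; a zero
initialization is available and yields the uniform 1/6 output of a
symmetric untrained net.

**Layer-recurrent fusion net (12→10→6).** h_t = tanh(W_x u_t + W_h h_{t−1}
+ b_h), y_t = softmax(W_o h_t + b_o), where u_t is the concatenation of the
two sub-classifier posteriors. Training minimizes the squared error of y_t
against one-hot targets over the unrolled training sequence with
Levenberg–Marquardt (MINPACK), using the exact Jacobian propagated forward
through the recurrence (real-time recurrent learning). Two numerical
safeguards matter in practice:

- a ridge term √λ·θ (λ = 1e−3) is appended to the residuals. Without it the
  near-separable training inputs let LM drive the weights to saturation
  (training MSE ~1e−150), and the resulting extreme recurrent dynamics lock
  into attractors on unseen sequences — whole gesture blocks misclassified;
- LM occasionally stalls immediately (spurious `xtol` termination from a
  rank-deficient raw Jacobian at a poor initialization). Training restarts
  from the next seed-derived initialization, up to four times, keeping the
  best fit; a fit is accepted when the residual MSE drops below 5e−3.

The training sequence is ordered as a simulated session: 10-window (3 s)
holds of each gesture, class order reshuffled every cycle, so the recurrence
learns both within-gesture persistence and transitions between every class
pair. Each sequence splits contiguously 70/15/15 along time. At inference
the hidden state persists across consecutive windows — that memory is the
point of the architecture — and `reset_state` marks session boundaries.
Argmax ties resolve to the lowest class index, for determinism.

All randomness (splits, initializations, restarts, the session ordering)
derives from a single seed via spawned seed sequences.

## Evaluation conventions

Confusion matrices are oriented rows = predicted, columns = true — the
transpose of several common conventions; every report labels its axes.
Precision of class c is the diagonal over the row sum, recall over the
column sum; a zero denominator defines the metric as 0 with a warning.
Summary averages are macro (unweighted), appropriate to the balanced
per-gesture design.

## Synthetic study conditions

Each gesture is an 8-channel activation profile in [0, 1]; a window is
white Gaussian noise band-limited to 10–95 Hz by FFT masking, with
per-channel σ = noise_floor + gain · separation · amplitude, clipped to
[-1, 1]. Defaults: noise floor σ = 0.02, gain 0.3, separation 1. Relax is
the bare noise floor; fist recruits nearly all channels; gripper (pinch)
and thumb-up are deliberately the closest pair, because those two are the
gestures most easily confused in practice. At separation 0 every gesture
collapses onto the relax distribution (verified by a two-sample KS test);
classification accuracy is non-decreasing in separation.

Sessions concatenate gesture blocks with a 150 ms linear onset ramp on the
activation component and carry timeline annotations. The bundled 40 s
demonstration script holds seven blocks (relax, fist, open hand, gripper,
grip, thumb up, relax) totalling exactly 8000 samples.

What the generator does *not* emulate: motor-unit action-potential trains,
electrode shift, inter-session placement variability, fatigue drift,
cross-talk structure between channels, or movement artifacts. The generator
matches real sEMG only at the level of second-order window statistics —
sufficient for exercising a time-domain-feature classifier, but a perfect
score here does not predict the accuracy attainable on real recordings; it
shows the pipeline is correct and that the fusion does not harm a solvable
problem.

## Reference generation

The recognized gesture selects a 6-vector of flexion targets (mm); defaults
are fist 60 everywhere, grip 40 everywhere, gripper (40, 40, 40, 40, 60, 60),
thumb-up (0, 0, 60, 60, 60, 60), open hand/relax 0 — all overridable, since
appropriate displacements scale with hand size. The instantaneous target
("reference intention") is distinct from the ramped reference actually sent
to the actuators: per 50 ms update (6 per window) each reference moves
toward its target by the coarse increment (2 mm) while |reference −
position| > 5 mm and by the fine increment (0.5 mm) otherwise, clamped at
the target — monotone approach, no overshoot, always within [0, 60] mm.
Extension references are the stroke complement of flexion references.

The bundled plant is a first-order lag with asymmetric time constants
(0.8 s contracting, 2.0 s relaxing — thermally driven actuators must shed
heat to extend). It is a closed-loop test double, not an actuator model;
its constants were chosen so the two-increment policy produces the intended
fast-far/smooth-near ramps, reaching a 60 mm target in roughly 2 s.
Optional majority-vote smoothing over the last k windows (default off)
damps transition misclassifications.

## Problem sizes

The default test and acceptance runs train on 100 windows per gesture and
evaluate on a fresh 100 per gesture; the separation-monotonicity sweep uses
50 per gesture per level; the examples use 60. These sizes put every
quantity in a regime where the expected results (perfect or near-perfect
separation at the default conditions) are stable across seeds while the
whole suite runs in a few minutes on one CPU.

## Known limitations

- The LRN benefits from temporally coherent evaluation sequences; on
  randomly shuffled windows its memory is useless (though, trained as
  described, not harmful).
- Kernel-NB prediction is O(training points) per window; at the intended
  scale (hundreds of windows per gesture) this is negligible, but it grows
  linearly with the database.
- The CSV session dialect stores per-sample labels; a reconstructed timeline
  is quantized to the sample grid.
- No frequency-domain features, no overlapping segmentation, no live
  acquisition.
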