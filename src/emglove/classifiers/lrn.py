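"""Layer-recurrent network fusing the two sub-classifiers' score vectors.

The hidden layer (10 tanh units) receives the current 12-element input — the
kernel-NB posterior concatenated with the feedforward net's posterior — plus
its own activations from the previous step (delay-1 feedback), giving the
classifier one-step memory over consecutive windows: consecutive hand
gestures are strongly autocorrelated, and the recurrence exploits that.
Output is a softmax over the six gestures; training minimizes the mean
squared error to one-hot targets over the unrolled training sequence with the
Levenberg-Marquardt algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from ..signal import N_GESTURES
from .common import ClassScores, one_hot

__all__ = ["LrnModel", "train_lrn", "lrn_step", "reset_state", "lrn_forward_sequence"]


@dataclass
class LrnModel:
    wx: np.ndarray  # (hidden, n_in)   input weights
    wh: np.ndarray  # (hidden, hidden) delay-1 recurrent weights
    bh: np.ndarray  # (hidden,)
    wo: np.ndarray  # (n_out, hidden)
    bo: np.ndarray  # (n_out,)
    hidden_state: np.ndarray = field(default=None)  # mutable inference state
    training_report: dict | None = None

    def __post_init__(self) -> None:
        if self.hidden_state is None:
            self.hidden_state = np.zeros(self.wx.shape[0])

    @property
    def n_in(self) -> int:
        return self.wx.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.wx.shape[0]

    @property
    def n_out(self) -> int:
        return self.wo.shape[0]


def reset_state(model: LrnModel) -> None:
    """Zero the hidden state — marks a session boundary."""
    model.hidden_state = np.zeros(model.n_hidden)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _pack(m: LrnModel) -> np.ndarray:
    return np.concatenate([m.wx.ravel(), m.wh.ravel(), m.bh, m.wo.ravel(), m.bo])


def _unpack(theta: np.ndarray, n_in: int, n_hidden: int, n_out: int):
    i = 0
    wx = theta[i : i + n_hidden * n_in].reshape(n_hidden, n_in); i += n_hidden * n_in
    wh = theta[i : i + n_hidden * n_hidden].reshape(n_hidden, n_hidden); i += n_hidden * n_hidden
    bh = theta[i : i + n_hidden]; i += n_hidden
    wo = theta[i : i + n_out * n_hidden].reshape(n_out, n_hidden); i += n_out * n_hidden
    bo = theta[i : i + n_out]
    return wx, wh, bh, wo, bo


def _forward(theta, U, h0, dims):
    """Run the recurrence over a (T, n_in) input sequence; returns (probs, h_T)."""
    n_in, n_hidden, n_out = dims
    wx, wh, bh, wo, bo = _unpack(theta, n_in, n_hidden, n_out)
    ux = U @ wx.T + bh  # (T, hidden), input drive precomputed
    h = h0
    H = np.empty((U.shape[0], n_hidden))
    for t in range(U.shape[0]):
        h = np.tanh(ux[t] + wh @ h)
        H[t] = h
    return _softmax(H @ wo.T + bo), h


def _forward_with_jacobian(theta, U, h0, dims):
    """Forward pass plus the exact residual Jacobian d softmax_t / d theta.

    Hidden-state sensitivities are propagated forward through the recurrence
    (real-time recurrent learning): S_t = D_t (C_t + Wh S_{t-1}) with
    D_t = diag(1 - h_t^2) and C_t the direct dependence of the pre-activation
    on the hidden parameters.  Returns ``(probs (T, out), J (T*out, P))``.
    """
    n_in, n_hidden, n_out = dims
    wx, wh, bh, wo, bo = _unpack(theta, n_in, n_hidden, n_out)
    n_hid_params = n_hidden * n_in + n_hidden * n_hidden + n_hidden
    P = theta.size
    o_wh = n_hidden * n_in
    o_bh = o_wh + n_hidden * n_hidden
    o_wo = n_hid_params
    o_bo = o_wo + n_out * n_hidden

    rh = np.arange(n_hidden)
    ro = np.arange(n_out)
    wx_cols = (rh[:, None] * n_in) + np.arange(n_in)[None, :]
    wh_cols = o_wh + (rh[:, None] * n_hidden) + rh[None, :]
    wo_cols = o_wo + (ro[:, None] * n_hidden) + np.arange(n_hidden)[None, :]

    T = U.shape[0]
    ux = U @ wx.T + bh
    h = h0
    S = np.zeros((n_hidden, n_hid_params))
    probs = np.empty((T, n_out))
    J = np.empty((T * n_out, P))
    for t in range(T):
        M = wh @ S
        M[rh[:, None], wx_cols] += U[t]
        M[rh[:, None], wh_cols] += h
        M[rh, o_bh + rh] += 1.0
        h = np.tanh(ux[t] + wh @ h)
        S = (1.0 - h * h)[:, None] * M
        z = wo @ h + bo
        z -= z.max()
        e = np.exp(z)
        y = e / e.sum()
        probs[t] = y
        G = np.zeros((n_out, P))
        G[:, :n_hid_params] = wo @ S
        G[ro[:, None], wo_cols] = h
        G[ro, o_bo + ro] = 1.0
        J[t * n_out : (t + 1) * n_out] = (np.diag(y) - np.outer(y, y)) @ G
    return probs, J


def lrn_forward_sequence(model: LrnModel, U: np.ndarray, h0: np.ndarray | None = None):
    """Stateless sequence forward pass; returns ``(probs (T, 6), final_hidden)``."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if h0 is None:
        h0 = np.zeros(model.n_hidden)
    return _forward(_pack(model), U, np.asarray(h0, dtype=float),
                    (model.n_in, model.n_hidden, model.n_out))


def lrn_step(model: LrnModel, u: np.ndarray) -> ClassScores:
    """One stateful inference step: advances the hidden state, returns scores."""
    u = np.asarray(u, dtype=float)
    if u.shape != (model.n_in,):
        raise ValueError(f"expected a {model.n_in}-element input, got shape {u.shape}")
    if model.hidden_state is None:
        reset_state(model)
    probs, h = _forward(_pack(model), u[None, :], model.hidden_state,
                        (model.n_in, model.n_hidden, model.n_out))
    model.hidden_state = h
    return ClassScores(scores=probs[0], normalized=True)


def _as_sequences(x) -> list[np.ndarray]:
    if isinstance(x, (list, tuple)):
        return [np.asarray(s, dtype=float) for s in x]
    return [np.asarray(x, dtype=float)]


def train_lrn(
    knb_scores_seq,
    ann_scores_seq,
    labels_seq,
    split: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    n_hidden: int = 10,
    max_nfev: int | None = None,
    l2: float = 1e-3,
) -> LrnModel:
    """Fit the recurrent fusion net on aligned sub-classifier score sequences.

    Inputs may be single ``(T, 6)`` arrays or lists of such arrays (one per
    session); the hidden state is carried across consecutive samples within a
    sequence and reset between sequences.  Each sequence is split
    contiguously — the leading 70% of steps are the training portion,
    the next 15% validation, the rest test — so temporal order is preserved.
    Residuals (softmax output minus one-hot target over every training step,
    plus a small ridge penalty ``sqrt(l2) * theta`` that keeps the recurrent
    dynamics from saturating) are minimized with MINPACK's
    Levenberg-Marquardt, using the exact forward-propagated Jacobian.
    """
    knb_seqs = _as_sequences(knb_scores_seq)
    ann_seqs = _as_sequences(ann_scores_seq)
    lab_seqs = [np.asarray(s, dtype=int) for s in _as_sequences(labels_seq)]
    if not (len(knb_seqs) == len(ann_seqs) == len(lab_seqs)):
        raise ValueError("sequence lists must have equal length")
    U_seqs, Y_seqs = [], []
    n_out = N_GESTURES
    for kq, aq, lq in zip(knb_seqs, ann_seqs, lab_seqs):
        if not (kq.shape[0] == aq.shape[0] == lq.shape[0]):
            raise ValueError("aligned sequences required")
        if lq.shape[0] < 2:
            raise ValueError("each sequence needs at least 2 samples")
        U_seqs.append(np.hstack([kq, aq]))
        Y_seqs.append(one_hot(lq, n_out))
    n_in = U_seqs[0].shape[1]
    dims = (n_in, n_hidden, n_out)

    bounds = []
    for Y in Y_seqs:
        T = Y.shape[0]
        n_tr = int(np.floor(split[0] * T))
        n_va = int(np.floor(split[1] * T))
        bounds.append((max(n_tr, 1), n_va))

    rng = np.random.default_rng(seed)
    theta0 = rng.normal(scale=0.1, size=(n_hidden * n_in + n_hidden * n_hidden
                                         + n_hidden + n_out * n_hidden + n_out))

    sqrt_l2 = np.sqrt(l2)

    def residuals(theta):
        res = []
        for (n_tr, _), U, Y in zip(bounds, U_seqs, Y_seqs):
            probs, _ = _forward(theta, U[:n_tr], np.zeros(n_hidden), dims)
            res.append((probs - Y[:n_tr]).ravel())
        res.append(sqrt_l2 * theta)
        return np.concatenate(res)

    def jacobian(theta):
        jac = []
        for (n_tr, _), U, _Y in zip(bounds, U_seqs, Y_seqs):
            _probs, J = _forward_with_jacobian(theta, U[:n_tr], np.zeros(n_hidden), dims)
            jac.append(J)
        jac.append(sqrt_l2 * np.eye(theta.size))
        return np.vstack(jac)

    if max_nfev is None:
        max_nfev = 150
    # LM occasionally stalls straight from a bad initialization (the raw
    # sequence Jacobian is rank-deficient); restart deterministically from the
    # next derived init and keep the best fit.
    n_res = sum(n_out * n_tr for n_tr, _ in bounds)
    sol = None
    n_restarts = 0
    for attempt in range(4):
        theta_init = theta0 if attempt == 0 else rng.normal(scale=0.1, size=theta0.size)
        s = least_squares(residuals, theta_init, jac=jacobian, method="lm",
                          max_nfev=max_nfev, xtol=1e-8, ftol=1e-8)
        if sol is None or s.cost < sol.cost:
            sol = s
        if 2.0 * sol.cost / n_res < 5e-3:  # residual MSE of a genuine fit
            break
        n_restarts = attempt + 1

    wx, wh, bh, wo, bo = _unpack(sol.x, *dims)
    model = LrnModel(wx=wx, wh=wh, bh=bh, wo=wo, bo=bo)

    report = {"train_mse": None, "val_mse": None, "test_mse": None,
              "nfev": int(sol.nfev), "cost": float(sol.cost),
              "restarts": n_restarts}
    sums = {"train": [0.0, 0], "val": [0.0, 0], "test": [0.0, 0]}
    correct = {"train": 0, "val": 0, "test": 0}
    for (n_tr, n_va), U, Y in zip(bounds, U_seqs, Y_seqs):
        probs, _ = _forward(sol.x, U, np.zeros(n_hidden), dims)
        parts = {"train": slice(0, n_tr), "val": slice(n_tr, n_tr + n_va),
                 "test": slice(n_tr + n_va, U.shape[0])}
        for name, sl in parts.items():
            if Y[sl].size:
                sums[name][0] += float(np.sum((probs[sl] - Y[sl]) ** 2))
                sums[name][1] += Y[sl].size
                correct[name] += int(np.sum(np.argmax(probs[sl], axis=1)
                                            == np.argmax(Y[sl], axis=1)))
    for name in sums:
        if sums[name][1]:
            report[f"{name}_mse"] = sums[name][0] / sums[name][1]
            report[f"{name}_accuracy"] = correct[name] / (sums[name][1] / n_out)
    model.training_report = report
    return model
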