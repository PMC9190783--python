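"""Shallow feedforward pattern-recognition network: 56 -> 8 (tanh) -> 6 (softmax).

Trained full-batch with scaled conjugate gradient on cross-entropy against
one-hot targets, with a stratified 70/15/15 train/validation/test split and
validation-loss early stopping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..evaluation import confusion, stratified_split
from ..signal import N_GESTURES
from ._scg import scg_minimize
from .common import ClassScores, one_hot

__all__ = ["AnnModel", "train_ann", "predict_ann", "predict_ann_matrix", "init_ann"]


@dataclass
class AnnModel:
    w1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (n_out, hidden)
    b2: np.ndarray  # (n_out,)
    # input standardization (fitted on the training split); identity by default
    in_mean: np.ndarray | None = None
    in_scale: np.ndarray | None = None
    training_report: dict | None = None

    @property
    def n_in(self) -> int:
        return self.w1.shape[1]

    @property
    def n_out(self) -> int:
        return self.w2.shape[0]


def init_ann(n_in: int = 56, n_hidden: int = 8, n_out: int = N_GESTURES, rng=None) -> AnnModel:
    """Glorot-uniform initialization (all-zero if rng is None: a symmetric net
    whose output is uniform 1/6 before training)."""
    if rng is None:
        return AnnModel(
            w1=np.zeros((n_hidden, n_in)),
            b1=np.zeros(n_hidden),
            w2=np.zeros((n_out, n_hidden)),
            b2=np.zeros(n_out),
        )
    lim1 = np.sqrt(6.0 / (n_in + n_hidden))
    lim2 = np.sqrt(6.0 / (n_hidden + n_out))
    return AnnModel(
        w1=rng.uniform(-lim1, lim1, (n_hidden, n_in)),
        b1=np.zeros(n_hidden),
        w2=rng.uniform(-lim2, lim2, (n_out, n_hidden)),
        b2=np.zeros(n_out),
    )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _pack(m: AnnModel) -> np.ndarray:
    return np.concatenate([m.w1.ravel(), m.b1, m.w2.ravel(), m.b2])


def _unpack(theta: np.ndarray, n_in: int, n_hidden: int, n_out: int):
    i = 0
    w1 = theta[i : i + n_hidden * n_in].reshape(n_hidden, n_in); i += n_hidden * n_in
    b1 = theta[i : i + n_hidden]; i += n_hidden
    w2 = theta[i : i + n_out * n_hidden].reshape(n_out, n_hidden); i += n_out * n_hidden
    b2 = theta[i : i + n_out]
    return w1, b1, w2, b2


def _forward(theta, X, n_in, n_hidden, n_out):
    w1, b1, w2, b2 = _unpack(theta, n_in, n_hidden, n_out)
    z1 = np.tanh(X @ w1.T + b1)
    return _softmax(z1 @ w2.T + b2), z1


def _cross_entropy(theta, X, Y, dims) -> float:
    p, _ = _forward(theta, X, *dims)
    return float(-np.mean(np.sum(Y * np.log(np.maximum(p, 1e-300)), axis=1)))


def _grad(theta, X, Y, dims) -> np.ndarray:
    n_in, n_hidden, n_out = dims
    w1, b1, w2, b2 = _unpack(theta, n_in, n_hidden, n_out)
    z1 = np.tanh(X @ w1.T + b1)
    p = _softmax(z1 @ w2.T + b2)
    dlogits = (p - Y) / X.shape[0]          # (n, out)
    gw2 = dlogits.T @ z1
    gb2 = dlogits.sum(axis=0)
    dz1 = (dlogits @ w2) * (1.0 - z1 * z1)  # (n, hidden)
    gw1 = dz1.T @ X
    gb1 = dz1.sum(axis=0)
    return np.concatenate([gw1.ravel(), gb1, gw2.ravel(), gb2])


def predict_ann_matrix(model: AnnModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.in_mean is not None:
        X = (X - model.in_mean) / model.in_scale
    theta = _pack(model)
    p, _ = _forward(theta, X, model.n_in, model.w1.shape[0], model.n_out)
    return p


def predict_ann(model: AnnModel, fv) -> ClassScores:
    values = getattr(fv, "values", fv)
    return ClassScores(scores=predict_ann_matrix(model, np.asarray(values))[0], normalized=True)


def train_ann(
    features,
    labels,
    split: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    n_hidden: int = 8,
    max_epochs: int = 1000,
    patience: int = 6,
) -> AnnModel:
    """Train the pattern-recognition net; the report holds the loss curves,
    split indices and the train/validation/test confusion matrices."""
    X_raw = np.asarray(features, dtype=float)
    X = X_raw
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 10:
        raise ValueError("need at least 10 samples per class to split 70/15/15")
    n_out = int(classes.max()) + 1
    dims = (X.shape[1], n_hidden, n_out)
    tr, va, te = stratified_split(y, split, seed=seed)
    # z-score the inputs on the training split: the 56 features span several
    # orders of magnitude and the net does not train well unscaled
    in_mean = X[tr].mean(axis=0)
    in_scale = np.maximum(X[tr].std(axis=0), 1e-8)
    X = (X - in_mean) / in_scale
    Xtr, Ytr = X[tr], one_hot(y[tr], n_out)
    Xva, Yva = X[va], one_hot(y[va], n_out)

    rng = np.random.default_rng(seed)
    theta0 = _pack(init_ann(dims[0], n_hidden, n_out, rng))

    state = {"best": theta0.copy(), "best_val": np.inf, "bad": 0,
             "loss": [], "val_loss": []}

    def callback(theta, k):
        loss = _cross_entropy(theta, Xtr, Ytr, dims)
        val = _cross_entropy(theta, Xva, Yva, dims)
        state["loss"].append(loss)
        state["val_loss"].append(val)
        if val < state["best_val"] - 1e-12:
            state["best_val"] = val
            state["best"] = theta.copy()
            state["bad"] = 0
        else:
            state["bad"] += 1
        return state["bad"] > patience

    scg_minimize(
        lambda t: _cross_entropy(t, Xtr, Ytr, dims),
        lambda t: _grad(t, Xtr, Ytr, dims),
        theta0,
        max_iter=max_epochs,
        callback=callback,
    )
    theta = state["best"]
    if state["bad"] <= patience and len(state["loss"]) >= max_epochs:
        warnings.warn("ANN training hit the epoch limit; returning best-so-far", stacklevel=2)

    w1, b1, w2, b2 = _unpack(theta, *dims)
    model = AnnModel(w1=w1, b1=b1, w2=w2, b2=b2, in_mean=in_mean, in_scale=in_scale)
    report = {
        "loss": np.array(state["loss"]),
        "val_loss": np.array(state["val_loss"]),
        "split_indices": {"train": tr, "val": va, "test": te},
        "epochs": len(state["loss"]),
    }
    for name, idx in (("train", tr), ("val", va), ("test", te)):
        pred = np.argmax(predict_ann_matrix(model, X_raw[idx]), axis=1)
        cm = confusion(pred, y[idx], n_classes=n_out)
        report[f"{name}_confusion"] = cm
        report[f"{name}_accuracy"] = cm.accuracy
    model.training_report = report
    return model
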