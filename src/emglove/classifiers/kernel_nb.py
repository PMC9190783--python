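"""Kernel naive Bayes: per-class, per-feature 1-D Gaussian KDE likelihoods.

The naive Bayes assumption treats the 56 features as independent within each
class; instead of a parametric (Gaussian) class-conditional, each feature's
likelihood is a kernel density estimate over the training points — sEMG
feature distributions are routinely non-Gaussian, which is why the kernel
variant is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from ..evaluation import kfold
from .common import ClassScores

__all__ = ["KernelNBModel", "train_knb", "predict_knb", "predict_knb_matrix"]

#: floor applied to each per-feature density before taking the log
DENSITY_FLOOR = 1e-300
#: minimum kernel bandwidth (normalized feature units)
MIN_BANDWIDTH = 1e-4

_LOG_FLOOR = np.log(DENSITY_FLOOR)
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class KernelNBModel:
    classes: np.ndarray        # (C,) class codes in score order
    priors: np.ndarray         # (C,) empirical class priors, sum 1
    train_points: list         # per class: (n_c, F) training feature rows
    bandwidths: np.ndarray     # (C, F) positive kernel bandwidths

    @property
    def n_features(self) -> int:
        return self.bandwidths.shape[1]


def _silverman_bandwidths(points: np.ndarray) -> np.ndarray:
    """Normal-reference rule per feature, with an IQR guard and a hard floor."""
    n = points.shape[0]
    std = points.std(axis=0, ddof=1) if n > 1 else np.zeros(points.shape[1])
    iqr = np.subtract(*np.percentile(points, [75, 25], axis=0)) / 1.349
    sigma = np.where(iqr > 0, np.minimum(std, iqr), std)
    h = sigma * (4.0 / (3.0 * max(n, 2))) ** 0.2
    if np.any(h < MIN_BANDWIDTH):
        warnings.warn(
            "degenerate (near zero-variance) feature: bandwidth floored", stacklevel=3
        )
    return np.maximum(h, MIN_BANDWIDTH)


def _fit(features: np.ndarray, labels: np.ndarray, classes: np.ndarray) -> KernelNBModel:
    priors = np.array([(labels == c).mean() for c in classes])
    train_points = [features[labels == c] for c in classes]
    bandwidths = np.vstack([_silverman_bandwidths(p) for p in train_points])
    return KernelNBModel(
        classes=classes, priors=priors, train_points=train_points, bandwidths=bandwidths
    )


def _log_likelihoods(model: KernelNBModel, X: np.ndarray) -> np.ndarray:
    """(n, C) matrix of log prior + sum of per-feature floored log KDE densities."""
    n = X.shape[0]
    out = np.empty((n, len(model.classes)))
    # evaluate in row blocks to bound the (block, F, m) temporaries
    block = max(1, int(2e6 // max(1, model.n_features * max(p.shape[0] for p in model.train_points))))
    for ci in range(len(model.classes)):
        pts = model.train_points[ci]          # (m, F)
        h = model.bandwidths[ci]              # (F,)
        log_norm = np.log(pts.shape[0]) + np.log(h) + _LOG_SQRT_2PI  # (F,)
        for i0 in range(0, n, block):
            xb = X[i0 : i0 + block]
            # z: (b, F, m) standardized distances to every training point
            z = (xb[:, :, None] - pts.T[None, :, :]) / h[None, :, None]
            logd = logsumexp(-0.5 * z * z, axis=2) - log_norm[None, :]  # (b, F)
            logd = np.maximum(logd, _LOG_FLOOR)
            out[i0 : i0 + block, ci] = np.log(model.priors[ci]) + logd.sum(axis=1)
    return out


def predict_knb_matrix(model: KernelNBModel, X: np.ndarray) -> np.ndarray:
    """Posterior matrix (n, C): softmax-normalized log posteriors, rows sum to 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    logp = _log_likelihoods(model, X)
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def predict_knb(model: KernelNBModel, fv) -> ClassScores:
    """Posterior class scores for one feature vector."""
    values = getattr(fv, "values", fv)
    return ClassScores(scores=predict_knb_matrix(model, np.asarray(values))[0], normalized=True)


def train_knb(
    features, labels, folds: int = 5, seed: int = 0
) -> tuple[KernelNBModel, dict]:
    """Fit the kernel-NB model with a stratified k-fold cross-validation report.

    Each fold trains on the other k-1 folds and scores the held-out fold; the
    returned model is refit on all data.  Fitting is order-independent: the
    model depends on the training set, not on row order.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    counts = np.array([(labels == c).sum() for c in classes])
    if np.any(counts < folds):
        raise ValueError(f"need at least {folds} samples per class for {folds}-fold CV")
    assignment = kfold(labels.size, k=folds, seed=seed, labels=labels)
    fold_acc = []
    for f in range(folds):
        tr = assignment != f
        va = ~tr
        m = _fit(features[tr], labels[tr], classes)
        pred = classes[np.argmax(predict_knb_matrix(m, features[va]), axis=1)]
        fold_acc.append(float(np.mean(pred == labels[va])))
    model = _fit(features, labels, classes)
    report = {"fold_accuracy": fold_acc, "cv_accuracy": float(np.mean(fold_acc))}
    return model, report
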