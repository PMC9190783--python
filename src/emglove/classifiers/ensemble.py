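"""The three-classifier ensemble: kernel-NB and the feedforward net in
parallel, their two 6-element posteriors concatenated into a 12-element input
for the layer-recurrent net, whose output is the final gesture decision."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from ..features import FeatureConfig
from ..signal import GestureLabel, N_GESTURES
from .ann import AnnModel, predict_ann_matrix, train_ann
from .common import ClassScores, argmax_label
from .kernel_nb import KernelNBModel, predict_knb_matrix, train_knb
from .lrn import LrnModel, lrn_step, reset_state, train_lrn

__all__ = ["EnsembleModel", "train_ensemble", "predict_ensemble",
           "predict_sequence", "save_model", "load_model", "ARCHIVE_VERSION"]

ARCHIVE_VERSION = "emglove-model-1"


@dataclass
class EnsembleModel:
    knb: KernelNBModel
    ann: AnnModel
    lrn: LrnModel
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    class_order: tuple = tuple(GestureLabel)
    reports: dict = field(default_factory=dict)

    def reset_state(self) -> None:
        reset_state(self.lrn)


def config_hash(feature_config: FeatureConfig) -> str:
    payload = yaml.safe_dump(
        {"zc_threshold": feature_config.zc_threshold,
         "ssc_threshold": feature_config.ssc_threshold,
         "var_convention": feature_config.var_convention},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _session_order(y: np.ndarray, chunk: int = 10, seed: int = 0) -> np.ndarray:
    """Row order emulating a session of held gestures: cycle through the
    classes taking ``chunk`` consecutive samples per visit (10 windows = 3 s
    holds), shuffling the class order every cycle so the recurrent net trains
    on within-gesture runs *and* on transitions between every class pair."""
    rng = np.random.default_rng(seed)
    pools = {c: list(np.flatnonzero(y == c)) for c in np.unique(y)}
    order: list[int] = []
    while any(pools.values()):
        for c in rng.permutation(sorted(pools)):
            take, pools[c] = pools[c][:chunk], pools[c][chunk:]
            order.extend(take)
    return np.asarray(order, dtype=int)


def train_ensemble(
    features,
    labels,
    seed: int = 0,
    folds: int = 5,
    split: tuple[float, float, float] = (0.70, 0.15, 0.15),
    feature_config: FeatureConfig = FeatureConfig(),
) -> EnsembleModel:
    """Train all three sub-models on one labeled feature matrix.

    The kernel-NB is fit with stratified k-fold cross-validation; the
    feedforward net with a stratified 70/15/15 split; the recurrent fusion
    net is then trained on the two sub-models' posteriors over the same data,
    ordered as a session of 3 s gesture holds cycling through the classes so
    that the recurrence learns both within-gesture runs and transitions.
    All randomness derives from ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    root = np.random.SeedSequence(seed)
    seed_knb, seed_ann, seed_lrn = (int(s.generate_state(1)[0] % (2**31))
                                    for s in root.spawn(3))

    knb, cv_report = train_knb(X, y, folds=folds, seed=seed_knb)
    ann = train_ann(X, y, split=split, seed=seed_ann)

    knb_scores = predict_knb_matrix(knb, X)
    ann_scores = predict_ann_matrix(ann, X)
    order = _session_order(y, chunk=10, seed=seed_lrn)
    lrn = train_lrn(knb_scores[order], ann_scores[order], y[order],
                    split=split, seed=seed_lrn)

    return EnsembleModel(
        knb=knb, ann=ann, lrn=lrn, feature_config=feature_config,
        reports={"knb_cv": cv_report,
                 "ann": {k: v for k, v in (ann.training_report or {}).items()
                         if k.endswith("accuracy")},
                 "lrn": lrn.training_report},
    )


def predict_ensemble(model: EnsembleModel, fv) -> tuple[GestureLabel, ClassScores]:
    """Classify one window: KNB and ANN posteriors (6 + 6) feed one stateful
    LRN step; the label is the argmax of the LRN output (lowest-index ties)."""
    values = np.asarray(getattr(fv, "values", fv), dtype=float)
    knb_p = predict_knb_matrix(model.knb, values[None, :])[0]
    ann_p = predict_ann_matrix(model.ann, values[None, :])[0]
    scores = lrn_step(model.lrn, np.concatenate([knb_p, ann_p]))
    return argmax_label(scores.scores), scores


def predict_sequence(model: EnsembleModel, X, reset: bool = True):
    """Classify a feature matrix as one ordered sequence.

    Returns ``(labels, lrn_scores, knb_scores, ann_scores)``; the recurrent
    state is carried across rows, reset first unless ``reset=False``.
    """
    X = np.asarray(X, dtype=float)
    if reset:
        model.reset_state()
    knb_p = predict_knb_matrix(model.knb, X)
    ann_p = predict_ann_matrix(model.ann, X)
    labels = np.empty(X.shape[0], dtype=int)
    scores = np.empty((X.shape[0], N_GESTURES))
    for t in range(X.shape[0]):
        s = lrn_step(model.lrn, np.concatenate([knb_p[t], ann_p[t]]))
        scores[t] = s.scores
        labels[t] = int(argmax_label(s.scores))
    return labels, scores, knb_p, ann_p


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Write the full ensemble (all parameters, KDE training points and
    bandwidths, class order, config hash, version tag) to one HDF5 archive."""
    with h5py.File(Path(path), "w") as f:
        f.attrs["version"] = ARCHIVE_VERSION
        f.attrs["config_hash"] = config_hash(model.feature_config)
        f.attrs["class_order"] = [int(c) for c in model.class_order]
        cfg = f.create_group("feature_config")
        cfg.attrs["zc_threshold"] = model.feature_config.zc_threshold
        cfg.attrs["ssc_threshold"] = model.feature_config.ssc_threshold
        cfg.attrs["var_convention"] = model.feature_config.var_convention
        g = f.create_group("knb")
        g.create_dataset("classes", data=model.knb.classes)
        g.create_dataset("priors", data=model.knb.priors)
        g.create_dataset("bandwidths", data=model.knb.bandwidths)
        for i, pts in enumerate(model.knb.train_points):
            g.create_dataset(f"train_points_{i}", data=pts)
        g = f.create_group("ann")
        for name in ("w1", "b1", "w2", "b2"):
            g.create_dataset(name, data=getattr(model.ann, name))
        if model.ann.in_mean is not None:
            g.create_dataset("in_mean", data=model.ann.in_mean)
            g.create_dataset("in_scale", data=model.ann.in_scale)
        g = f.create_group("lrn")
        for name in ("wx", "wh", "bh", "wo", "bo"):
            g.create_dataset(name, data=getattr(model.lrn, name))


def load_model(path: str | Path) -> EnsembleModel:
    """Load an archive written by :func:`save_model`; predictions round-trip
    bit-identically."""
    with h5py.File(Path(path), "r") as f:
        if f.attrs.get("version") != ARCHIVE_VERSION:
            raise ValueError(f"{path}: not an {ARCHIVE_VERSION} archive")
        cfg = f["feature_config"].attrs
        feature_config = FeatureConfig(
            zc_threshold=float(cfg["zc_threshold"]),
            ssc_threshold=float(cfg["ssc_threshold"]),
            var_convention=str(cfg["var_convention"]),
        )
        g = f["knb"]
        classes = g["classes"][...]
        knb = KernelNBModel(
            classes=classes,
            priors=g["priors"][...],
            train_points=[g[f"train_points_{i}"][...] for i in range(len(classes))],
            bandwidths=g["bandwidths"][...],
        )
        g = f["ann"]
        ann = AnnModel(
            w1=g["w1"][...], b1=g["b1"][...], w2=g["w2"][...], b2=g["b2"][...],
            in_mean=g["in_mean"][...] if "in_mean" in g else None,
            in_scale=g["in_scale"][...] if "in_scale" in g else None,
        )
        g = f["lrn"]
        lrn = LrnModel(wx=g["wx"][...], wh=g["wh"][...], bh=g["bh"][...],
                       wo=g["wo"][...], bo=g["bo"][...])
        class_order = tuple(GestureLabel(int(c)) for c in f.attrs["class_order"])
    return EnsembleModel(knb=knb, ann=ann, lrn=lrn,
                         feature_config=feature_config, class_order=class_order)
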