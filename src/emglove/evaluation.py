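"""Confusion matrices, classification metrics, and split machinery.

Confusion matrices here follow the rows = predicted class, columns = true
class orientation (note: the transpose of several common conventions); every
report labels its axes explicitly.  With that orientation, precision of class
c is the diagonal over the row sum and recall the diagonal over the column
sum.  Summary averages are macro (unweighted) — appropriate for the balanced
per-gesture acquisition protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signal import N_GESTURES

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "accuracy",
    "stratified_split",
    "kfold",
    "report_text",
]


@dataclass
class ConfusionMatrix:
    """Integer count matrix; ``counts[p, t]`` = windows of true class t predicted p."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be >= 0")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.n) if self.n else 0.0

    def row_normalized(self) -> np.ndarray:
        """Each row (predicted class) normalized to sum 1 — per-class precision view."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / sums, 0.0)
        return out

    def col_normalized(self) -> np.ndarray:
        """Each column (true class) normalized to sum 1 — per-class recall view."""
        sums = self.counts.sum(axis=0, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / sums, 0.0)
        return out


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray   # per class
    recall: np.ndarray      # per class
    f1: np.ndarray          # per class
    macro_precision: float
    macro_recall: float
    macro_f1: float


def confusion(predictions, truths, n_classes: int = N_GESTURES) -> ConfusionMatrix:
    """Build the (predicted x true) confusion matrix from label pairs."""
    predictions = np.asarray(predictions, dtype=int)
    truths = np.asarray(truths, dtype=int)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths differ in length")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (predictions, truths), 1)
    return ConfusionMatrix(counts=counts)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, metric defined as 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy and per-class / macro precision, recall, F1 from a confusion matrix."""
    k = cm.counts.shape[0]
    precision = np.zeros(k)
    recall = np.zeros(k)
    f1 = np.zeros(k)
    for c in range(k):
        tp = cm.counts[c, c]
        precision[c] = _safe_div(tp, cm.counts[c, :].sum(), f"precision[{c}]")
        recall[c] = _safe_div(tp, cm.counts[:, c].sum(), f"recall[{c}]")
        f1[c] = _safe_div(2 * precision[c] * recall[c], precision[c] + recall[c], f"f1[{c}]")
    return MetricsReport(
        accuracy=cm.accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
    )


def accuracy(predictions, truths) -> float:
    predictions = np.asarray(predictions, dtype=int)
    truths = np.asarray(truths, dtype=int)
    return float(np.mean(predictions == truths))


def stratified_split(
    labels, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded stratified train/validation/test split.

    Per class: ``floor(f_train * n_c)`` training rows, ``floor(f_val * n_c)``
    validation rows, the remainder test (so 250 samples split 175/37/38 and
    600 balanced samples split 420/90/90).  Disjoint and exhaustive.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be three numbers summing to 1; got {fractions}")
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    train_idx, val_idx, test_idx = [], [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        n_train = int(np.floor(fractions[0] * idx.size))
        n_val = int(np.floor(fractions[1] * idx.size))
        train_idx.append(idx[:n_train])
        val_idx.append(idx[n_train : n_train + n_val])
        test_idx.append(idx[n_train + n_val :])
    return (
        np.concatenate(train_idx),
        np.concatenate(val_idx),
        np.concatenate(test_idx),
    )


def kfold(n: int, k: int = 5, seed: int = 0, labels=None) -> np.ndarray:
    """Seeded fold assignment (values 0..k-1), balanced to within one sample.

    With ``labels`` given, folds are stratified per class — matching the
    protocol of training on four of every five samples and validating on the
    fifth.
    """
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n; got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if labels is None:
        order = rng.permutation(n)
        assignment[order] = np.arange(n) % k
    else:
        labels = np.asarray(labels, dtype=int)
        if labels.size != n:
            raise ValueError("labels length must equal n")
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            idx = idx[rng.permutation(idx.size)]
            assignment[idx] = np.arange(idx.size) % k
    return assignment


def report_text(cm: ConfusionMatrix, class_names=None) -> str:
    """Human-readable confusion matrix (rows = predicted, cols = true) + metrics."""
    rep = metrics(cm)
    k = cm.counts.shape[0]
    if class_names is None:
        class_names = [f"class{c}" for c in range(k)]
    width = max(len(str(n)) for n in class_names) + 2
    lines = ["confusion matrix (rows = predicted, columns = true):"]
    header = " " * width + "".join(f"{n:>{width}}" for n in class_names)
    lines.append(header)
    for p in range(k):
        row = f"{class_names[p]:>{width}}" + "".join(
            f"{cm.counts[p, t]:>{width}d}" for t in range(k)
        )
        lines.append(row)
    lines.append(f"accuracy: {rep.accuracy:.4f}")
    for c in range(k):
        lines.append(
            f"{class_names[c]}: precision {rep.precision[c]:.4f} "
            f"recall {rep.recall[c]:.4f} f1 {rep.f1[c]:.4f}"
        )
    lines.append(
        f"macro: precision {rep.macro_precision:.4f} recall {rep.macro_recall:.4f} "
        f"f1 {rep.macro_f1:.4f}"
    )
    return "\n".join(lines)


def plot_confusion(cm: ConfusionMatrix, class_names=None, path=None):
    """Render the confusion matrix as a heatmap (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = cm.counts.shape[0]
    if class_names is None:
        class_names = [f"class{c}" for c in range(k)]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xlabel("true class")
    ax.set_ylabel("predicted class")
    ax.set_xticks(range(k), class_names, rotation=45, ha="right")
    ax.set_yticks(range(k), class_names)
    for p in range(k):
        for t in range(k):
            ax.text(t, p, str(cm.counts[p, t]), ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
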