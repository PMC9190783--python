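"""Confusion matrices, metrics arithmetic, and split machinery."""

import numpy as np
import pytest

from emglove.evaluation import (
    ConfusionMatrix,
    confusion,
    kfold,
    metrics,
    report_text,
    stratified_split,
)
from emglove.signal import GestureLabel


class TestConfusion:
    def test_perfect_predictions_give_diagonal_matrix(self):
        y = np.repeat(np.arange(6), 10)
        cm = confusion(y, y)
        assert cm.accuracy == 1.0
        np.testing.assert_array_equal(cm.counts, np.diag(np.full(6, 10)))
        rep = metrics(cm)
        assert rep.macro_f1 == 1.0

    def test_single_fist_as_grip_error_hits_grip_precision_only(self):
        # rows = predicted, columns = true: one true fist predicted as grip
        truths = np.repeat(np.arange(6), 10)
        preds = truths.copy()
        fist_idx = np.flatnonzero(truths == int(GestureLabel.FIST))[0]
        preds[fist_idx] = int(GestureLabel.GRIP)
        cm = confusion(preds, truths)
        assert cm.counts[int(GestureLabel.GRIP), int(GestureLabel.FIST)] == 1
        rep = metrics(cm)
        assert rep.precision[int(GestureLabel.FIST)] == 1.0
        assert rep.precision[int(GestureLabel.GRIP)] < 1.0
        assert rep.recall[int(GestureLabel.FIST)] < 1.0

    def test_random_predictions_score_near_chance(self):
        rng = np.random.default_rng(0)
        truths = np.repeat(np.arange(6), 100)
        preds = rng.integers(0, 6, 600)
        acc = confusion(preds, truths).accuracy
        # 1/6 within ~4 binomial standard errors
        assert abs(acc - 1 / 6) < 4 * np.sqrt((1 / 6) * (5 / 6) / 600)

    def test_normalized_summaries_sum_to_one(self):
        rng = np.random.default_rng(1)
        cm = confusion(rng.integers(0, 6, 300), rng.integers(0, 6, 300))
        np.testing.assert_allclose(cm.row_normalized().sum(axis=1), 1.0)
        np.testing.assert_allclose(cm.col_normalized().sum(axis=0), 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(counts=np.array([[1, -1], [0, 2]]))


class TestMetrics:
    def test_two_class_toy_matches_hand_arithmetic(self):
        cm = ConfusionMatrix(counts=np.array([[8, 2], [0, 10]]))
        rep = metrics(cm)
        assert rep.precision[0] == pytest.approx(0.8)
        assert rep.recall[0] == pytest.approx(1.0)
        assert rep.f1[0] == pytest.approx(2 * 0.8 / 1.8)  # ~0.889
        assert rep.accuracy == pytest.approx(18 / 20)

    def test_macro_f1_invariant_under_relabeling(self):
        rng = np.random.default_rng(2)
        preds = rng.integers(0, 6, 400)
        truths = rng.integers(0, 6, 400)
        rep = metrics(confusion(preds, truths))
        perm = rng.permutation(6)
        rep_p = metrics(confusion(perm[preds], perm[truths]))
        assert rep.macro_f1 == pytest.approx(rep_p.macro_f1)
        assert rep.accuracy == pytest.approx(rep_p.accuracy)

    def test_empty_class_warns_and_zeroes_metric(self):
        cm = ConfusionMatrix(counts=np.array([[5, 0], [0, 0]]))
        with pytest.warns(UserWarning, match="zero denominator"):
            rep = metrics(cm)
        assert rep.precision[1] == 0.0

    def test_report_text_mentions_axis_orientation(self):
        cm = confusion([0, 1], [0, 1], n_classes=2)
        assert "rows = predicted" in report_text(cm)


class TestSplits:
    def test_balanced_600_gives_420_90_90(self):
        y = np.repeat(np.arange(6), 100)
        tr, va, te = stratified_split(y, seed=0)
        assert (len(tr), len(va), len(te)) == (420, 90, 90)
        merged = np.sort(np.concatenate([tr, va, te]))
        np.testing.assert_array_equal(merged, np.arange(600))
        # stratification: 70 training rows per class
        assert all((y[tr] == c).sum() == 70 for c in range(6))

    def test_single_group_250_gives_175_37_38(self):
        # train = floor(0.70 n), validation = floor(0.15 n), test = remainder
        tr, va, te = stratified_split(np.zeros(250, dtype=int), seed=1)
        assert (len(tr), len(va), len(te)) == (175, 37, 38)

    def test_bad_fractions_raise(self):
        with pytest.raises(ValueError, match="summing to 1"):
            stratified_split(np.arange(10) % 2, fractions=(0.5, 0.4, 0.2))

    def test_same_seed_same_split(self):
        y = np.repeat(np.arange(3), 30)
        a = stratified_split(y, seed=5)
        b = stratified_split(y, seed=5)
        for ia, ib in zip(a, b):
            np.testing.assert_array_equal(ia, ib)

    def test_kfold_balanced_and_exhaustive(self):
        y = np.repeat(np.arange(6), 25)
        folds = kfold(150, k=5, seed=1, labels=y)
        counts = np.bincount(folds, minlength=5)
        assert counts.tolist() == [30] * 5
        # stratified: each fold has 5 samples of each class
        for f in range(5):
            assert all((y[folds == f] == c).sum() == 5 for c in range(6))

    def test_kfold_bad_k_raises(self):
        with pytest.raises(ValueError):
            kfold(4, k=5)
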