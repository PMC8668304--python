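import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorseg.errors import TumorsegError
from tumorseg.evaluate import (
    ConfusionMatrix,
    confusion,
    dice_from_precision_recall,
    dice_score,
    kfold_record,
    kfold_subject,
    metrics,
    segmentation_confusion,
    split_counts,
    split_dataset,
)


class TestSplitDataset:
    @pytest.mark.parametrize(
        "n,expected",
        [(1425, (998, 142, 285)), (1675, (1173, 167, 335)), (2470, (1729, 247, 494)), (10, (7, 1, 2))],
    )
    def test_counts_follow_half_up_convention(self, n, expected):
        assert split_counts(n) == expected

    def test_split_partitions_indices(self):
        split = split_dataset(53, seed=4)
        all_idx = np.concatenate([split.train_idx, split.val_idx, split.test_idx])
        assert sorted(all_idx) == list(range(53))
        assert split.counts == split_counts(53)

    def test_membership_depends_on_seed_counts_do_not(self):
        a, b = split_dataset(40, seed=1), split_dataset(40, seed=2)
        assert a.counts == b.counts
        assert not np.array_equal(a.train_idx, b.train_idx)

    def test_too_small_n_rejected(self):
        with pytest.raises(TumorsegError):
            split_dataset(9)


class TestConfusion:
    def test_perfect_prediction_has_no_errors(self):
        cm = confusion(["t", "n", "t"], ["t", "n", "t"], positive="t")
        assert cm.FP == 0 and cm.FN == 0 and cm.TP == 2 and cm.TN == 1

    def test_four_case_enumeration(self):
        cm = confusion(["P", "P", "N", "N"], ["P", "N", "P", "N"], positive="P")
        assert (cm.TP, cm.FN, cm.FP, cm.TN) == (1, 1, 1, 1)

    def test_swapping_positive_class_swaps_counts(self):
        y_t, y_p = ["P", "P", "N", "N", "N"], ["P", "N", "P", "N", "N"]
        a = confusion(y_t, y_p, positive="P")
        b = confusion(y_t, y_p, positive="N")
        assert (a.TP, a.TN, a.FP, a.FN) == (b.TN, b.TP, b.FN, b.FP)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(TumorsegError):
            confusion(["a"], ["a", "b"], positive="a")
        with pytest.raises(TumorsegError):
            confusion(["a", "b", "c"], ["a", "b", "c"], positive="a")


class TestMetrics:
    def test_correct_count_accuracy_examples(self):
        # 275 of 285 correct
        cm = ConfusionMatrix(TP=275, FP=4, FN=6, TN=0)
        assert round(metrics(cm).accuracy, 2) == 96.49

    def test_dice_is_harmonic_mean_of_precision_and_recall(self):
        assert round(dice_from_precision_recall(96.74, 97.80), 2) == 97.27

    def test_uniform_matrix_gives_fifty_percent_everywhere(self):
        rep = metrics(ConfusionMatrix(TP=1, FP=1, FN=1, TN=1))
        for value in rep.as_dict().values():
            assert value == pytest.approx(50.0)

    def test_self_comparison_yields_full_accuracy(self):
        labels = ["t", "n", "t", "n", "n"]
        assert metrics(confusion(labels, labels, positive="t")).accuracy == 100.0

    def test_zero_denominator_reports_nan_with_warning(self):
        cm = ConfusionMatrix(TP=0, FP=0, FN=0, TN=5)
        with pytest.warns(UserWarning):
            rep = metrics(cm)
        assert np.isnan(rep.sensitivity)
        assert rep.specificity == 100.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(TumorsegError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_dice_identity_against_direct_overlap_form(self, counts):
        tp, fp, fn, tn = counts
        rep = metrics(ConfusionMatrix(TP=tp, FP=fp, FN=fn, TN=tn))
        direct = 100.0 * 2 * tp / (2 * tp + fp + fn)
        assert rep.dice == pytest.approx(direct)


class TestSegmentationConfusion:
    def test_identical_masks_full_dice(self, rng):
        mask = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        assert dice_score(mask, mask) == 1.0

    def test_disjoint_nonempty_masks_zero_dice(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert dice_score(a, b) == 0.0

    def test_counts_match_per_pixel_enumeration(self, rng):
        pred = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        true = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        cm = segmentation_confusion(pred, true)
        tp = fp = fn = tn = 0
        for i in range(8):
            for j in range(8):
                if pred[i, j] and true[i, j]:
                    tp += 1
                elif pred[i, j]:
                    fp += 1
                elif true[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (cm.TP, cm.FP, cm.FN, cm.TN) == (tp, fp, fn, tn)

    def test_ignore_label_pixels_excluded(self):
        true = np.array([[1, 255], [0, 255]], dtype=np.uint8)
        pred = np.ones((2, 2), dtype=np.uint8)
        cm = segmentation_confusion(pred, true)
        assert cm.total == 2 and cm.TP == 1 and cm.FP == 1


class TestKfold:
    def test_record_folds_are_stratified_within_one(self):
        labels = np.array(["tumor"] * 50 + ["normal"] * 50)
        folds = kfold_record(labels, k=10, seed=3)
        for f in range(10):
            tumor_count = np.sum((folds == f) & (labels == "tumor"))
            assert tumor_count == 5
            assert np.sum(folds == f) == 10

    def test_record_folds_partition_data(self):
        labels = np.array([0] * 33 + [1] * 29)
        folds = kfold_record(labels, k=10, seed=1)
        assert len(folds) == 62
        assert set(folds) == set(range(10))

    def test_record_warns_when_class_smaller_than_k(self):
        labels = np.array([0] * 20 + [1] * 3)
        with pytest.warns(UserWarning):
            kfold_record(labels, k=5, seed=0)

    def test_subject_folds_never_split_a_subject(self):
        subjects = np.repeat([f"s{i}" for i in range(20)], 5)
        folds = kfold_subject(subjects, k=10, seed=2)
        for s in np.unique(subjects):
            assert len(set(folds[subjects == s])) == 1
        # 20 subjects x 5 images, k=10 -> 2 subjects / 10 images per fold
        counts = np.bincount(folds, minlength=10)
        assert (counts == 10).all()

    def test_subject_fold_spread_bounded_by_largest_subject(self):
        sizes = [7, 5, 5, 4, 3, 3, 2, 2, 1, 1, 6, 4]
        subjects = np.concatenate([[f"s{i}"] * n for i, n in enumerate(sizes)])
        folds = kfold_subject(subjects, k=5, seed=0)
        counts = np.bincount(folds, minlength=5)
        assert counts.max() - counts.min() <= max(sizes)

    def test_fewer_subjects_than_folds_rejected(self):
        with pytest.raises(TumorsegError):
            kfold_subject(np.array(["a", "a", "b"]), k=3)
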