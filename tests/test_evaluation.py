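import itertools

import numpy as np
import pytest

from wbcnet.dataset_io import CLASS_NAMES
from wbcnet.evaluation import (ConfusionMatrix, classification_metrics,
                               confusion_matrix, cross_validate, ovr_curves,
                               stratified_kfold)
from wbcnet.models import ArchitectureSpec, LayerSpec
from wbcnet.training import TrainingConfig

from conftest import make_label_dataset

# Published rater-study confusion matrix used as a worked example: rows are
# true classes, columns predictions, 100 items total, 95 on the diagonal.
RATER_MATRIX = np.array([
    [19, 0, 0, 1, 0],
    [0, 19, 0, 0, 1],
    [0, 0, 20, 0, 0],
    [1, 0, 0, 19, 0],
    [2, 0, 0, 0, 18],
])


class TestStratifiedKFold:
    def test_divisible_counts_fill_folds_evenly(self):
        ds = make_label_dataset({"neutrophil": 20, "eosinophil": 10})
        plan = stratified_kfold(ds, k=10, seed=0)
        y = ds.label_indices()
        for fold in range(10):
            idx = plan.fold_indices(fold)
            assert (y[idx] == 0).sum() == 2
            assert (y[idx] == 1).sum() == 1

    def test_single_class_even_split(self):
        ds = make_label_dataset({"basophil": 10})
        plan = stratified_kfold(ds, k=5, seed=1)
        assert all(len(plan.fold_indices(f)) == 2 for f in range(5))

    def test_uneven_counts_differ_by_at_most_one(self):
        """Enumeration oracle over all (class, fold) cells."""
        ds = make_label_dataset({"neutrophil": 7, "eosinophil": 5})
        plan = stratified_kfold(ds, k=3, seed=2)
        y = ds.label_indices()
        for ci in (0, 1):
            sizes = [((y[plan.fold_indices(f)]) == ci).sum() for f in range(3)]
            assert max(sizes) - min(sizes) <= 1
            assert sum(sizes) == [7, 5][ci]

    def test_partition_property(self):
        ds = make_label_dataset({"neutrophil": 13, "lymphocyte": 8})
        plan = stratified_kfold(ds, k=4, seed=3)
        seen = np.concatenate([plan.fold_indices(f) for f in range(4)])
        assert sorted(seen.tolist()) == list(range(len(ds)))

    def test_deterministic_given_seed(self):
        ds = make_label_dataset({"monocyte": 9, "basophil": 6})
        a = stratified_kfold(ds, k=3, seed=7).assignments
        b = stratified_kfold(ds, k=3, seed=7).assignments
        np.testing.assert_array_equal(a, b)

    def test_class_smaller_than_k_rejected_by_name(self):
        ds = make_label_dataset({"neutrophil": 10, "basophil": 2})
        with pytest.raises(ValueError, match="basophil"):
            stratified_kfold(ds, k=5)


class TestConfusionMatrix:
    def test_all_correct_gives_diagonal(self):
        labels = [c for c in CLASS_NAMES for _ in range(2)]
        cm = confusion_matrix(labels, labels)
        assert np.trace(cm.counts) == 10
        assert cm.counts.sum() == 10

    def test_rater_matrix_reconstructed_from_label_lists(self):
        true, pred = [], []
        for i, row in enumerate(RATER_MATRIX):
            for j, n in enumerate(row):
                true += [CLASS_NAMES[i]] * n
                pred += [CLASS_NAMES[j]] * n
        cm = confusion_matrix(true, pred)
        np.testing.assert_array_equal(cm.counts, RATER_MATRIX)

    def test_matches_pair_counting_oracle(self, rng):
        t = rng.integers(0, 5, size=50)
        p = rng.integers(0, 5, size=50)
        cm = confusion_matrix(t, p)
        oracle = np.zeros((5, 5), dtype=int)
        for ti, pi in zip(t, p):
            oracle[ti, pi] += 1
        np.testing.assert_array_equal(cm.counts, oracle)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["neutrophil"], ["platelet"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-np.ones((5, 5), dtype=int))


class TestClassificationMetrics:
    def test_rater_matrix_accuracy_95_percent(self):
        report = classification_metrics(ConfusionMatrix(RATER_MATRIX))
        assert report.accuracy == pytest.approx(0.95)

    def test_perfect_thousand_per_class_matrix(self):
        cm = ConfusionMatrix(np.eye(5, dtype=int) * 1000)
        report = classification_metrics(cm)
        assert report.accuracy == 1.0
        assert report.macro_f1 == 1.0

    def test_matches_definition_oracle(self, rng):
        counts = rng.integers(0, 30, size=(5, 5))
        counts[3] += 5  # ensure nonempty
        report = classification_metrics(ConfusionMatrix(counts))
        total = counts.sum()
        assert abs(report.accuracy - np.trace(counts) / total) < 1e-12
        precs, recs, f1s = [], [], []
        for i in range(5):
            col, row = counts[:, i].sum(), counts[i].sum()
            p = counts[i, i] / col if col else 0.0
            r = counts[i, i] / row if row else 0.0
            f = 2 * p * r / (p + r) if p + r else 0.0
            precs.append(p), recs.append(r), f1s.append(f)
            cname = CLASS_NAMES[i]
            assert abs(report.per_class_precision[cname] - p) < 1e-12
            assert abs(report.per_class_recall[cname] - r) < 1e-12
            assert abs(report.per_class_f1[cname] - f) < 1e-12
        assert abs(report.macro_precision - np.mean(precs)) < 1e-12
        assert abs(report.macro_f1 - np.mean(f1s)) < 1e-12

    def test_per_class_accuracy_is_recall(self):
        report = classification_metrics(ConfusionMatrix(RATER_MATRIX))
        assert report.per_class_accuracy == report.per_class_recall

    def test_zero_denominator_flags_and_zeroes(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0] = 10  # only one class ever predicted/true
        report = classification_metrics(ConfusionMatrix(counts))
        assert report.zero_division_flag
        assert report.per_class_precision["basophil"] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionMatrix(np.zeros((5, 5), dtype=int)))


def _mann_whitney_auc(pos_scores, neg_scores):
    """Pair-counting oracle: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


class TestOvrCurves:
    def _scores_for(self, y, sep):
        n = len(y)
        scores = np.zeros((n, 5))
        scores[np.arange(n), y] = sep
        return scores

    def test_perfect_separation_gives_auc_one(self):
        y = np.repeat(np.arange(5), 4)
        curves = ovr_curves(self._scores_for(y, 10.0), y)
        for c in CLASS_NAMES:
            assert curves[c]["roc_auc"] == pytest.approx(1.0)

    def test_identical_scores_give_half(self):
        y = np.repeat(np.arange(5), 4)
        curves = ovr_curves(np.zeros((20, 5)), y)
        for c in CLASS_NAMES:
            assert curves[c]["roc_auc"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_roc_auc_equals_mann_whitney_statistic(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 5, size=20)
        while len(set(y.tolist())) < 5:
            y = rng.integers(0, 5, size=20)
        # quantized scores force ties, exercising tie grouping
        scores = np.round(rng.normal(size=(20, 5)), 1)
        curves = ovr_curves(scores, y)
        for ci, cname in enumerate(CLASS_NAMES):
            pos = scores[y == ci, ci]
            neg = scores[y != ci, ci]
            assert curves[cname]["roc_auc"] == pytest.approx(
                _mann_whitney_auc(pos, neg), abs=1e-12)

    def test_single_class_truth_flagged_undefined(self):
        y = np.zeros(6, dtype=int)
        curves = ovr_curves(np.random.default_rng(0).normal(size=(6, 5)), y)
        assert np.isnan(curves["basophil"]["roc_auc"])
        assert curves["basophil"]["undefined"]

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            ovr_curves(np.full((4, 5), np.nan), np.zeros(4, dtype=int))


class TestCrossValidate:
    def _tiny_arch(self):
        return ArchitectureSpec(
            (LayerSpec("maxpool", kernel=(2, 2), stride=2),
             LayerSpec("maxpool", kernel=(2, 2), stride=2),
             LayerSpec("maxpool", kernel=(2, 2), stride=2),
             LayerSpec("maxpool", kernel=(2, 2), stride=2),
             LayerSpec("maxpool", kernel=(2, 2), stride=2),
             LayerSpec("flatten"),
             LayerSpec("dense", filters=5)),
            input_shape=(128, 128, 3))

    def test_two_fold_protocol_structure(self, tiny_preprocessed_dataset):
        reports, pooled = cross_validate(
            self._tiny_arch(), tiny_preprocessed_dataset,
            TrainingConfig(epochs=1, seed=0), k=2, seed=4)
        assert [r.fold for r in reports] == [0, 1]
        assert 0.0 <= pooled.accuracy <= 1.0
        # every record is tested exactly once across folds
        plan = stratified_kfold(tiny_preprocessed_dataset, k=2, seed=4)
        tested = np.concatenate([plan.fold_indices(f) for f in range(2)])
        assert sorted(tested.tolist()) == list(
            range(len(tiny_preprocessed_dataset)))

    def test_k_too_large_propagates_stratification_error(
            self, tiny_preprocessed_dataset):
        with pytest.raises(ValueError):
            cross_validate(self._tiny_arch(), tiny_preprocessed_dataset,
                           TrainingConfig(epochs=0), k=4, seed=0)
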