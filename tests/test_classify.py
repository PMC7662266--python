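"""LOOCV engine, weighted metrics, and the column error-rate convention."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shoegait as sg
from shoegait.classify import ClassifierSpec, ConfusionMatrix, ReductionConfig
from shoegait.worked_examples import worked_example_matrices


class TestLosoFolds:
    def test_exact_partition(self, stride_table):
        folds = sg.loso_folds(stride_table)
        assert len(folds) == stride_table["participant_id"].nunique()
        test_union = np.concatenate([test for _, _, test in folds])
        assert sorted(test_union) == list(range(len(stride_table)))
        for pid, train, test in folds:
            pids_train = set(stride_table.iloc[train]["participant_id"])
            pids_test = set(stride_table.iloc[test]["participant_id"])
            assert pids_test == {pid}
            assert pid not in pids_train

    def test_single_participant_rejected(self, stride_table):
        solo = stride_table[stride_table["participant_id"] == 1]
        with pytest.raises(ValueError, match="participants"):
            sg.loso_folds(solo)


class TestMetrics:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(np.diag([10, 5, 5, 5, 5]))
        rep = sg.metrics(cm)
        assert rep.accuracy == 1.0
        assert rep.weighted_precision == pytest.approx(1.0)
        assert rep.weighted_recall == pytest.approx(1.0)

    def test_two_class_hand_example(self):
        # [[8,2],[4,6]]: accuracy 0.70, weighted precision
        # (10*(8/12) + 10*(6/8)) / 20 = 0.7083...
        cm = ConfusionMatrix(np.array([[8, 2], [4, 6]]), labels=("a", "b"))
        rep = sg.metrics(cm)
        assert rep.accuracy == pytest.approx(0.70)
        assert rep.weighted_precision == pytest.approx(
            (10 * 8 / 12 + 10 * 6 / 8) / 20)

    def test_zero_prediction_column_precision_zero_with_warning(self):
        counts = np.array([[5, 0, 0, 0, 0],
                           [3, 0, 0, 0, 0],
                           [0, 0, 4, 0, 0],
                           [0, 0, 0, 4, 0],
                           [0, 0, 0, 0, 4]])
        with pytest.warns(UserWarning, match="no predictions"):
            rep = sg.metrics(ConfusionMatrix(counts))
        assert rep.per_class_precision[1] == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_weighted_recall_equals_trace_over_total(self, seed):
        """Algebraic identity on any single confusion matrix."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, (5, 5))
        counts[0, 0] += 1  # nonempty
        cm = ConfusionMatrix(counts)
        rep = sg.metrics(cm)
        assert rep.weighted_recall == pytest.approx(
            np.trace(counts) / counts.sum())
        assert rep.weighted_recall == pytest.approx(rep.accuracy)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sg.metrics(ConfusionMatrix(np.zeros((5, 5), dtype=int)))


class TestColumnErrorRates:
    def test_identity_matrix_zero_error(self):
        rates, avg = sg.column_error_rates(ConfusionMatrix(np.diag([9] * 5)))
        assert np.all(rates == 0) and avg == 0

    @pytest.mark.parametrize("pid,expected", [
        (3, 25.4), (8, 19.0), (13, 0.9), (15, 32.3), (18, 0.8),
    ])
    def test_published_worked_examples(self, pid, expected):
        """Column-wise error averages of the published worst/best
        participant matrices reproduce the printed values."""
        _, avg = sg.column_error_rates(worked_example_matrices()[pid])
        assert round(avg, 1) == expected

    def test_first_column_convention(self):
        # participant 3, first predicted column: 73 errors of 205 -> 35.6%
        rates, _ = sg.column_error_rates(worked_example_matrices()[3])
        assert round(rates[0], 1) == 35.6


class TestTrainEvalFold:
    def test_determinism(self, stride_table):
        folds = sg.loso_folds(stride_table)
        pid, train, test = folds[0]
        spec = ClassifierSpec.random_forest(rng_seed=5)
        cm1, k1 = sg.train_eval_fold(spec, stride_table.iloc[train],
                                     stride_table.iloc[test])
        cm2, k2 = sg.train_eval_fold(spec, stride_table.iloc[train],
                                     stride_table.iloc[test])
        assert np.array_equal(cm1.counts, cm2.counts) and k1 == k2

    def test_separable_fold_accuracy_high(self, stride_table):
        pid, train, test = sg.loso_folds(stride_table)[0]
        cm, _ = sg.train_eval_fold(ClassifierSpec.svm(),
                                   stride_table.iloc[train],
                                   stride_table.iloc[test])
        assert np.trace(cm.counts) / cm.counts.sum() >= 0.95

    def test_empty_fold_side_rejected(self, stride_table):
        with pytest.raises(ValueError, match="nonempty"):
            sg.train_eval_fold(ClassifierSpec.svm(), stride_table.iloc[:0],
                               stride_table.iloc[:5])


@pytest.fixture(scope="module")
def results(stride_table):
    return sg.GaitClassificationModel(stride_table).fit()


class TestModelResults:
    def test_one_fold_per_participant(self, results, stride_table):
        assert results.participants == sorted(
            stride_table["participant_id"].unique())

    def test_mean_sd_recomputable_from_folds(self, results):
        accs = results.per_fold("accuracy")
        m, s = results.mean_sd("accuracy")
        assert m == pytest.approx(accs.mean())
        assert s == pytest.approx(accs.std(ddof=1))

    def test_total_confusion_pools_folds(self, results, stride_table):
        assert results.total_confusion.total == len(stride_table)

    def test_fixed_n_pcs_mode(self, stride_table):
        res = sg.GaitClassificationModel(
            stride_table, ClassifierSpec.svm(),
            ReductionConfig(n_pcs=10),
        ).fit()
        assert all(k == 10 for k in res.fold_n_pcs.values())

    def test_summary_mentions_key_quantities(self, results):
        text = results.summary()
        assert "svm" in text and "Accuracy" in text
        assert f"{len(results.participants)}" in text

    def test_shuffled_labels_near_majority_share(self, stride_table):
        """Permutation null: LOOCV accuracy collapses to roughly the
        majority-class share once the labels are shuffled."""
        rng = np.random.default_rng(11)
        shuffled = stride_table.copy()
        shuffled["gait_class"] = rng.permutation(
            shuffled["gait_class"].to_numpy())
        res = sg.GaitClassificationModel(shuffled).fit()
        majority = (stride_table["gait_class"] == "normal").mean()
        assert abs(res.accuracy - majority) <= 0.1
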