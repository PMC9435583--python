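"""Subset pairing, fold loops, stability selection, SVM evaluation."""

import numpy as np
import pytest

from megfc.classify import (
    EvalReport,
    FoldResult,
    StabilitySelectedSVC,
    build_subset_partition,
    finalize_and_evaluate,
    flag_strong_edges,
    loo_stability_run,
    overlap_select,
    random_split_run,
    train_rbf_svm,
)


def make_cohort_samples(rng, n_subjects_per_group=8, segs=(10, 20),
                        n_features=50, informative=(), shift=1.5):
    """Segment-level samples with optional informative features."""
    X, y, subj = [], [], []
    for g, label in (("cps", 1), ("sps", 0)):
        for s in range(n_subjects_per_group):
            n = int(rng.integers(*segs))
            block = rng.standard_normal((n, n_features))
            if label == 1:
                for f in informative:
                    block[:, f] += shift
            X.append(block)
            y.extend([label] * n)
            subj.extend([f"{g}{s:02d}"] * n)
    return np.vstack(X), np.array(y), np.array(subj)


class TestSubsetPartition:
    def test_full_cohort_partition(self):
        ids = [f"c{i}" for i in range(16)] + [f"s{i}" for i in range(16)]
        groups = ["CPS"] * 16 + ["SPS"] * 16
        counts = list(range(33, 49)) + list(range(40, 56))
        part = build_subset_partition(ids, groups, counts, seed=0)
        assert part.n_subsets == 16
        assert len(part.test_subsets) == 2
        assert len(part.training_subsets) == 14
        assert sorted(sum(part.pairs, ())) == sorted(ids)

    def test_rank_matched_pairing(self):
        # rank matching: low-count CPS pairs with low-count SPS
        part = build_subset_partition(
            ["a", "b", "c", "x", "y", "z"],
            ["CPS", "CPS", "CPS", "SPS", "SPS", "SPS"],
            [100, 10, 50, 95, 12, 55], test_subsets=(0,), n_test=1)
        assert part.pairs == [("b", "y"), ("c", "z"), ("a", "x")]

    def test_too_few_subsets_rejected(self):
        with pytest.raises(ValueError, match="reserve"):
            build_subset_partition(["a", "b", "x", "y"],
                                   ["CPS", "CPS", "SPS", "SPS"],
                                   [5, 6, 7, 8], seed=0)

    def test_unequal_groups_rejected(self):
        with pytest.raises(ValueError, match="equal-sized"):
            build_subset_partition(["a", "b", "c"], ["CPS", "CPS", "SPS"],
                                   [1, 2, 3])

    def test_pinned_test_subsets(self):
        ids = [f"c{i}" for i in range(6)] + [f"s{i}" for i in range(6)]
        part = build_subset_partition(ids, ["CPS"] * 6 + ["SPS"] * 6,
                                      list(range(12)), test_subsets=(1, 4))
        assert part.test_subsets == (1, 4)


class TestTrainRbfSvm:
    def test_separable_toy_set(self):
        X = np.vstack([np.zeros((10, 2)), np.ones((10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        clf = train_rbf_svm(X, y)
        assert (clf.predict(X) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_rbf_svm(np.zeros((5, 2)), np.ones(5))

    def test_duplicated_rows_leave_decision_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 3))
        y = (X[:, 0] > 0).astype(int)
        probe = rng.standard_normal((20, 3))
        d1 = train_rbf_svm(X, y).decision_function(probe)
        d2 = train_rbf_svm(np.vstack([X, X]),
                           np.concatenate([y, y])).decision_function(probe)
        np.testing.assert_allclose(d1, d2, atol=1e-8)


class TestLooStabilityRun:
    def test_fold_count_and_separable_accuracy(self):
        rng = np.random.default_rng(1)
        X, y, subj = make_cohort_samples(rng, informative=(3, 17), shift=4.0)
        subsets = {s: i % 8 for i, s in enumerate(np.unique(subj))}
        sample_subsets = np.array([subsets[s] for s in subj])
        folds = loo_stability_run(X, y, sample_subsets, range(8),
                                  k_fraction=0.05)
        assert len(folds) == 8
        # informative features recovered in every fold; accuracy near ceiling
        assert all({3, 17} <= set(fr.selected_features.tolist())
                   for fr in folds)
        assert all(fr.validation_accuracy >= 0.9 for fr in folds)
        assert all(fr.selected_features.size == 3 for fr in folds)  # ceil(2.5)

    def test_minimum_subsets_guard(self):
        with pytest.raises(ValueError, match="3 training subsets"):
            loo_stability_run(np.zeros((4, 2)), np.array([0, 1, 0, 1]),
                              np.array([0, 0, 1, 1]), [0, 1])

    def test_no_leakage_outside_training_subsets(self):
        # rows outside the training subsets are poisoned with NaN: any
        # leak into scoring or training would propagate and crash
        rng = np.random.default_rng(2)
        X, y, subj = make_cohort_samples(rng, n_subjects_per_group=4,
                                         informative=(0,), shift=4.0)
        uniq = np.unique(subj)
        subsets = {s: i % 4 for i, s in enumerate(uniq)}
        sample_subsets = np.array([subsets[s] for s in subj])
        X = X.copy()
        X[sample_subsets == 3] = np.nan  # held-out test subset
        folds = loo_stability_run(X, y, sample_subsets, [0, 1, 2],
                                  k_fraction=0.05)
        assert all(np.isfinite(fr.fscores).all() for fr in folds)


class TestRandomSplitRun:
    def test_repetition_count_and_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 30))
        y = rng.integers(0, 2, 100)
        a = random_split_run(X, y, n_reps=5, seed=42)
        b = random_split_run(X, y, n_reps=5, seed=42)
        assert len(a) == 5
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.selected_features,
                                          fb.selected_features)
            assert fa.validation_accuracy == fb.validation_accuracy

    def test_chance_level_with_permuted_labels(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 40))
        y = rng.permutation([1] * 100 + [0] * 100)
        folds = random_split_run(X, y, n_reps=10, seed=0, k_fraction=0.1)
        mean_acc = np.mean([fr.validation_accuracy for fr in folds])
        assert 0.4 <= mean_acc <= 0.6

    def test_train_fraction_bounds(self):
        with pytest.raises(ValueError):
            random_split_run(np.zeros((10, 2)), np.zeros(10), train_frac=1.0)


class TestOverlapSelect:
    @staticmethod
    def folds_from_selections(selections):
        return [FoldResult(fold_id=k, selected_features=np.asarray(s),
                           fscores=np.ones(len(s)),
                           validation_accuracy=1.0)
                for k, s in enumerate(selections)]

    def test_threshold_rule(self):
        sels = [[0, 1]] * 11 + [[0, 2]] * 3  # feature 0: 14, 1: 11, 2: 3
        stab = overlap_select(self.folds_from_selections(sels), threshold=12)
        assert list(stab.stable_features) == [0]
        assert stab.occurrence_counts[1] == 11  # just below 12/14

    def test_threshold_one_gives_union(self):
        sels = [[0], [5], [3]]
        stab = overlap_select(self.folds_from_selections(sels), threshold=1)
        assert set(stab.stable_features) == {0, 3, 5}

    def test_threshold_above_fold_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            overlap_select(self.folds_from_selections([[0]]), threshold=2)

    def test_full_threshold_stable_set_in_every_fold(self):
        rng = np.random.default_rng(5)
        sels = [rng.choice(30, size=5, replace=False) for _ in range(6)]
        stab = overlap_select(self.folds_from_selections(sels), threshold=6)
        for s in sels:
            assert set(stab.stable_features) <= set(s.tolist())

    def test_mean_fscore_averages_selected_folds_only(self):
        folds = [
            FoldResult(0, np.array([7]), np.array([2.0]), 1.0),
            FoldResult(1, np.array([7]), np.array([4.0]), 1.0),
            FoldResult(2, np.array([9]), np.array([10.0]), 1.0),
        ]
        stab = overlap_select(folds, threshold=1)
        means = dict(zip(stab.stable_features, stab.mean_fscores))
        assert means[7] == pytest.approx(3.0)
        assert means[9] == pytest.approx(10.0)


class TestFlagStrongEdges:
    def test_threshold_75_percent(self):
        from megfc.classify import StabilityResult
        from collections import Counter
        stab = StabilityResult(Counter(), np.array([0, 1, 2]),
                               np.array([1.0, 0.8, 0.5]), 1, 3)
        np.testing.assert_array_equal(flag_strong_edges(stab),
                                      [True, True, False])

    def test_single_feature_flagged(self):
        from megfc.classify import StabilityResult
        from collections import Counter
        stab = StabilityResult(Counter(), np.array([4]), np.array([0.2]), 1, 3)
        assert flag_strong_edges(stab).tolist() == [True]

    def test_all_equal_all_flagged(self):
        from megfc.classify import StabilityResult
        from collections import Counter
        stab = StabilityResult(Counter(), np.arange(3), np.full(3, 0.7), 1, 3)
        assert flag_strong_edges(stab).all()

    def test_empty_stable_set_rejected(self):
        from megfc.classify import StabilityResult
        from collections import Counter
        stab = StabilityResult(Counter(), np.array([], int), np.array([]), 1, 3)
        with pytest.raises(ValueError, match="empty"):
            flag_strong_edges(stab)


class TestEvaluation:
    def test_confusion_arithmetic(self):
        rep = EvalReport(tp=90, fn=10, tn=80, fp=20)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.sensitivity == pytest.approx(0.90)
        assert rep.specificity == pytest.approx(0.80)

    def test_from_predictions_counts(self):
        y_true = np.array([1, 1, 1, 0, 0, 0])
        y_pred = np.array([1, 1, 0, 0, 0, 1])
        rep = EvalReport.from_predictions(y_true, y_pred)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (2, 1, 2, 1)

    def test_flipped_predictions_complement_accuracy(self):
        rng = np.random.default_rng(6)
        y_true = rng.integers(0, 2, 50)
        y_pred = rng.integers(0, 2, 50)
        a = EvalReport.from_predictions(y_true, y_pred).accuracy
        b = EvalReport.from_predictions(y_true, 1 - y_pred).accuracy
        assert a + b == pytest.approx(1.0)

    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 0])
        rep = EvalReport.from_predictions(y, y)
        assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0

    def test_finalize_requires_stable_features(self):
        with pytest.raises(ValueError, match="empty stable set"):
            finalize_and_evaluate(np.zeros((4, 3)), np.array([0, 1, 0, 1]),
                                  np.zeros((2, 3)), np.array([0, 1]),
                                  np.array([], int))

    def test_finalize_on_separable_data(self):
        rng = np.random.default_rng(7)
        X_tr = rng.standard_normal((60, 10))
        y_tr = np.array([1] * 30 + [0] * 30)
        X_tr[:30, 4] += 4.0
        X_te = rng.standard_normal((20, 10))
        y_te = np.array([1] * 10 + [0] * 10)
        X_te[:10, 4] += 4.0
        rep = finalize_and_evaluate(X_tr, y_tr, X_te, y_te, np.array([4]))
        assert rep.accuracy >= 0.9


class TestStabilitySelectedSVC:
    def test_subsets_scheme_end_to_end(self):
        rng = np.random.default_rng(8)
        X, y, subj = make_cohort_samples(rng, informative=(3, 17), shift=3.0)
        subsets = {s: i % 8 for i, s in enumerate(np.unique(subj))}
        sample_subsets = np.array([subsets[s] for s in subj])
        model = StabilitySelectedSVC(scheme="subsets", select_fraction=0.05,
                                     overlap_threshold=8)
        model.fit(X, y, subset_ids=sample_subsets)
        assert {3, 17} <= set(model.selected_features_.tolist())
        assert len(model.fold_results_) == 8
        assert model.stability_.strong_flags.size == \
            model.selected_features_.size
        assert (model.predict(X) == y).mean() > 0.95

    def test_requires_subset_ids_for_subset_scheme(self):
        with pytest.raises(ValueError, match="subset_ids"):
            StabilitySelectedSVC().fit(np.zeros((10, 5)),
                                       np.array([0, 1] * 5))

    def test_random_scheme_deterministic_given_state(self):
        rng = np.random.default_rng(9)
        X, y, _ = make_cohort_samples(rng, n_subjects_per_group=4,
                                      informative=(2,), shift=3.0)
        m1 = StabilitySelectedSVC(scheme="random", n_reps=6,
                                  overlap_threshold=5, select_fraction=0.05,
                                  random_state=3).fit(X, y)
        m2 = StabilitySelectedSVC(scheme="random", n_reps=6,
                                  overlap_threshold=5, select_fraction=0.05,
                                  random_state=3).fit(X, y)
        np.testing.assert_array_equal(m1.selected_features_,
                                      m2.selected_features_)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        model = StabilitySelectedSVC(C=2.0, gamma=1.0)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
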