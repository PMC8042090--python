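"""CV plans, the leaky vs. nested protocols, and the feature-count sweep."""

import numpy as np
import pytest

from leakage_lab import (
    ClassifierSpec,
    FeatureMatrix,
    VoteParams,
    make_cv_plan,
    run_feature_count_sweep,
    run_outside_cv_protocol,
    run_within_cv_protocol,
)


class TestCVPlan:
    def test_small_balanced_plan_has_one_sample_per_class_per_fold(self):
        labels = np.repeat([0, 1], 10)
        plan = make_cv_plan(labels, n_folds=10, n_repetitions=2, seed=1)
        for r in range(2):
            for f in range(10):
                fold = labels[plan.fold_of[r] == f]
                assert len(fold) == 2 and set(fold) == {0, 1}

    def test_folds_partition_samples(self):
        labels = np.repeat([0, 1], 17)
        plan = make_cv_plan(labels, n_folds=5, n_repetitions=3, seed=2)
        for r, f, trainset, test in plan.loops():
            assert len(np.intersect1d(trainset, test)) == 0
            assert len(trainset) + len(test) == 34
        # union of test folds per repetition covers everything exactly once
        for r in range(3):
            sizes = [np.sum(plan.fold_of[r] == f) for f in range(5)]
            assert sum(sizes) == 34

    def test_same_seed_identical_plan(self):
        labels = np.repeat([0, 1], 12)
        a = make_cv_plan(labels, 4, 2, seed=3)
        b = make_cv_plan(labels, 4, 2, seed=3)
        assert np.array_equal(a.fold_of, b.fold_of)

    def test_class_smaller_than_folds_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan([0] * 20 + [1] * 3, n_folds=5)


def _perfect_feature_data(n=20, d=30, seed=4):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(2 * n, d))
    values[n:, 0] += 10.0  # one overwhelming feature
    return FeatureMatrix(
        values, np.repeat([0, 1], n), [f"f{i}" for i in range(d)], [f"s{i}" for i in range(2 * n)]
    )


class TestProtocols:
    def test_perfect_feature_reaches_full_accuracy_both_protocols(self, both_classifiers):
        data = _perfect_feature_data()
        plan = make_cv_plan(data.labels, n_folds=5, n_repetitions=2, seed=5)
        vp = VoteParams(n_reps=30, seed=6)
        out = run_outside_cv_protocol(data, [25], both_classifiers, plan, vp)
        win = run_within_cv_protocol(data, [25], both_classifiers, plan, vp)
        for kind in ("svm", "rlda"):
            assert out.mean_accuracy(25, kind) == 100.0
            assert win.mean_accuracy(25, kind) == 100.0

    def test_result_mean_is_mean_of_fold_accuracies(self, both_classifiers):
        data = _perfect_feature_data(seed=7)
        plan = make_cv_plan(data.labels, n_folds=5, n_repetitions=2, seed=8)
        out = run_outside_cv_protocol(data, [25], both_classifiers, plan, VoteParams(30, seed=9))
        folds = out.fold_acc[(25, "svm")]
        assert len(folds) == plan.n_loops
        assert out.mean_accuracy(25, "svm") == pytest.approx(folds.mean() * 100)

    def test_outside_protocol_inflates_on_null_data(
        self, small_null_matrix, both_classifiers, fast_vote_params
    ):
        """On no-signal data the nested estimate stays near chance while the
        leaky one rises above it: the selection-bias effect in miniature."""
        plan = make_cv_plan(small_null_matrix.labels, n_folds=5, n_repetitions=2, seed=12)
        out = run_outside_cv_protocol(
            small_null_matrix, [15], both_classifiers, plan, fast_vote_params
        )
        win = run_within_cv_protocol(
            small_null_matrix, [15], both_classifiers, plan, fast_vote_params
        )
        assert out.mean_accuracy(15, "svm") > win.mean_accuracy(15, "svm")
        assert 25.0 < win.mean_accuracy(15, "svm") < 75.0

    def test_within_empty_selection_falls_back_to_top_feature(
        self, small_null_matrix, both_classifiers, fast_vote_params
    ):
        plan = make_cv_plan(small_null_matrix.labels, n_folds=5, n_repetitions=1, seed=13)
        forced_empty = fast_vote_params.n_reps + 1
        win = run_within_cv_protocol(
            small_null_matrix, [forced_empty], both_classifiers, plan, fast_vote_params
        )
        assert win.fallback_counts[forced_empty] == plan.n_loops
        assert win.n_selected[forced_empty] == (1, 1)

    def test_outside_empty_threshold_reported_absent(
        self, small_null_matrix, both_classifiers, fast_vote_params
    ):
        plan = make_cv_plan(small_null_matrix.labels, n_folds=5, n_repetitions=1, seed=14)
        forced_empty = fast_vote_params.n_reps + 1
        out = run_outside_cv_protocol(
            small_null_matrix, [15, forced_empty], both_classifiers, plan, fast_vote_params
        )
        assert out.thresholds == [15]
        assert forced_empty not in out.n_selected

    def test_within_protocol_untouched_by_test_fold_values(self, both_classifiers):
        """Taint check: perturbing test-fold values must not change the model
        trained in that loop (standardization, votes, training all clean)."""
        data = _perfect_feature_data(n=12, d=40, seed=15)
        plan = make_cv_plan(data.labels, n_folds=2, n_repetitions=1, seed=16)
        vp = VoteParams(n_reps=20, seed=17)

        tainted_values = data.values.copy()
        test_rows = np.flatnonzero(plan.fold_of[0] == 0)  # loop 0's test fold
        tainted_values[test_rows] += np.random.default_rng(18).normal(
            0, 5, size=(len(test_rows), data.n_features)
        )
        tainted = FeatureMatrix(tainted_values, data.labels, data.feature_ids, data.sample_ids)

        a = run_within_cv_protocol(data, [10], both_classifiers, plan, vp, keep_models=True)
        b = run_within_cv_protocol(tainted, [10], both_classifiers, plan, vp, keep_models=True)

        assert a.per_loop_selected[10][0] == b.per_loop_selected[10][0]
        for kind in ("svm", "rlda"):
            ma, mb = a.models[(10, kind)][0], b.models[(10, kind)][0]
            assert np.array_equal(ma.weights, mb.weights)
            assert ma.intercept == mb.intercept

    def test_plan_size_mismatch_rejected(self, small_null_matrix, both_classifiers):
        plan = make_cv_plan(np.repeat([0, 1], 5), n_folds=5, n_repetitions=1, seed=19)
        with pytest.raises(ValueError):
            run_outside_cv_protocol(small_null_matrix, [10], both_classifiers, plan)


class TestSweep:
    def test_sweep_matches_threshold_protocol_at_selection_size(self, both_classifiers):
        """With no vote tie at the boundary, the leaky sweep at k equal to a
        threshold's selection size must equal the threshold protocol's value
        under the same plan and seed."""
        data = _perfect_feature_data(n=15, d=25, seed=20)
        plan = make_cv_plan(data.labels, n_folds=5, n_repetitions=2, seed=21)
        vp = VoteParams(n_reps=30, seed=22)
        out = run_outside_cv_protocol(data, [25], both_classifiers, plan, vp)
        k = out.n_selected[25]
        sweep = run_feature_count_sweep(data, "outside_cv", both_classifiers, plan, vp, k_max=k)
        for kind in ("svm", "rlda"):
            assert sweep.mean_accuracy(k, kind) == pytest.approx(out.mean_accuracy(25, kind))

    def test_k1_with_dominant_feature_equals_single_feature_classifier(self, both_classifiers):
        data = _perfect_feature_data(n=15, d=25, seed=23)
        plan = make_cv_plan(data.labels, n_folds=5, n_repetitions=1, seed=24)
        vp = VoteParams(n_reps=30, seed=25)
        sweep = run_feature_count_sweep(data, "outside_cv", both_classifiers, plan, vp, k_max=2)
        # the dominant feature separates perfectly on its own
        assert sweep.mean_accuracy(1, "svm") == 100.0
        assert sweep.mean_accuracy(1, "rlda") == 100.0

    def test_within_sweep_reranks_per_loop(self, small_null_matrix, both_classifiers):
        plan = make_cv_plan(small_null_matrix.labels, n_folds=5, n_repetitions=1, seed=26)
        vp = VoteParams(n_reps=20, seed=27)
        sweep = run_feature_count_sweep(
            small_null_matrix, "within_cv", both_classifiers, plan, vp, k_max=3
        )
        assert sweep.ks == [1, 2, 3]
        frame = sweep.to_frame()
        assert len(frame) == 6 and set(frame["protocol"]) == {"within_cv"}

    def test_invalid_k_rejected(self, small_null_matrix, both_classifiers):
        plan = make_cv_plan(small_null_matrix.labels, n_folds=5, n_repetitions=1, seed=28)
        with pytest.raises(ValueError):
            run_feature_count_sweep(
                small_null_matrix, "outside_cv", both_classifiers, plan, k_max=0
            )
        with pytest.raises(ValueError):
            run_feature_count_sweep(
                small_null_matrix, "outside_cv", both_classifiers, plan,
                k_max=small_null_matrix.n_features + 1,
            )
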