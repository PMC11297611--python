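"""Cross-validation scheme, pooled metrics, bootstrap confidence intervals."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import roc_auc_score

from ehrcsa.evaluation import (
    FoldAssignment,
    OOFPredictions,
    auc_midrank,
    bootstrap_ci,
    compute_metric_cis,
    compute_metrics,
    repeated_cv_predict,
    stratified_kfold,
)
from ehrcsa.shap_engine import KernelShapConfig
from ehrcsa.svm_classifier import SVMHyperparams
from ehrcsa.synthetic_ehr import CohortConfig, generate_cohort


def make_oof(true, pred, score=None, patient_idx=None):
    n = len(true)
    return OOFPredictions(
        patient_idx=np.asarray(patient_idx if patient_idx is not None else range(n)),
        repetition=np.zeros(n, int),
        fold=np.zeros(n, int),
        score=np.asarray(score if score is not None else pred, float),
        pred=np.asarray(pred, int),
        true=np.asarray(true, int),
    )


class TestStratifiedKFold:
    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_stratification_tolerance_random_labels(self, k, rng):
        y = rng.integers(0, 2, 60)
        while min(np.bincount(y, minlength=2)) < k:
            y = rng.integers(0, 2, 60)
        folds = stratified_kfold(y, k=k, repeats=3, seed=1)
        for r in range(3):
            assignment = folds.assignments[r]
            assert set(assignment) == set(range(k))
            for cls in (0, 1):
                counts = np.bincount(assignment[y == cls], minlength=k)
                assert counts.max() - counts.min() <= 1

    def test_study_cohort_fold_sizes(self):
        y = np.concatenate([np.ones(23, int), np.zeros(25, int)])
        folds = stratified_kfold(y, k=4, repeats=2, seed=0)
        for r in range(2):
            for f in range(4):
                _, test_idx = folds.fold_indices(r, f)
                n_cases = int(y[test_idx].sum())
                n_ctrls = len(test_idx) - n_cases
                assert n_cases in (5, 6)
                assert n_ctrls in (6, 7)

    def test_tiny_balanced_cohort_forced_assignment(self):
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        folds = stratified_kfold(y, k=4, repeats=1, seed=0)
        for f in range(4):
            _, test_idx = folds.fold_indices(0, f)
            assert int(y[test_idx].sum()) == 1
            assert len(test_idx) == 2

    def test_deterministic_and_repeats_differ(self):
        y = np.concatenate([np.ones(23, int), np.zeros(25, int)])
        a = stratified_kfold(y, k=4, repeats=3, seed=5)
        b = stratified_kfold(y, k=4, repeats=3, seed=5)
        assert np.array_equal(a.assignments, b.assignments)
        assert not np.array_equal(a.assignments[0], a.assignments[1])

    def test_class_smaller_than_k_rejected(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="k=4"):
            stratified_kfold(y, k=4)


class TestRepeatedCVPredict:
    def test_perfect_feature_all_held_out_correct(self, separable_cohort):
        folds = stratified_kfold(separable_cohort.labels, k=4, repeats=2, seed=0)
        oof, phi = repeated_cv_predict(
            separable_cohort, ["oracle_item"], SVMHyperparams(), folds
        )
        assert (oof.pred == oof.true).all()
        assert phi is None

    def test_row_count_is_patients_times_repeats(self, small_cohort):
        folds = stratified_kfold(small_cohort.labels, k=4, repeats=3, seed=0)
        oof, phi = repeated_cv_predict(
            small_cohort,
            list(small_cohort.feature_names),
            SVMHyperparams(),
            folds,
            KernelShapConfig(n_coalitions=32, background_size=4),
        )
        assert len(oof) == small_cohort.n_patients * 3
        assert phi.shape == (small_cohort.n_patients * 3, small_cohort.n_features)

    def test_every_patient_repetition_pair_once(self, small_cohort):
        folds = stratified_kfold(small_cohort.labels, k=4, repeats=2, seed=1)
        oof, _ = repeated_cv_predict(
            small_cohort, list(small_cohort.feature_names), SVMHyperparams(), folds
        )
        pairs = set(zip(oof.patient_idx.tolist(), oof.repetition.tolist()))
        assert len(pairs) == small_cohort.n_patients * 2

    def test_empty_subset_rejected(self, small_cohort):
        folds = stratified_kfold(small_cohort.labels, k=4, repeats=1, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            repeated_cv_predict(small_cohort, [], SVMHyperparams(), folds)

    def test_single_class_training_fold_named(self, separable_cohort):
        # hand-built degenerate assignment: fold 0 holds out all controls
        y = separable_cohort.labels
        assignment = np.where(y == 1, 0, 1)[None, :]
        folds = FoldAssignment(assignment, k=2, repeats=1, seed=0)
        with pytest.raises(ValueError, match="repetition 0, fold 0"):
            repeated_cv_predict(separable_cohort, ["oracle_item"], SVMHyperparams(), folds)

    def test_null_features_auc_near_chance(self):
        """Pure-noise cohorts give pooled AUC within the null band."""
        aucs = []
        for seed in range(5):
            cohort = generate_cohort(
                CohortConfig(n_cases=100, n_controls=100, n_features=20, seed=seed)
            )
            folds = stratified_kfold(cohort.labels, k=4, repeats=1, seed=seed)
            oof, _ = repeated_cv_predict(
                cohort, list(cohort.feature_names), SVMHyperparams(), folds
            )
            aucs.append(compute_metrics(oof).auc)
        assert all(0.35 <= a <= 0.65 for a in aucs)


class TestComputeMetrics:
    def test_hand_confusion_matrix(self):
        # TP=3, FP=1, FN=2, TN=4
        true = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        score = [2.0, 1.5, 1.0, -0.5, -1.0, 0.5, -0.1, -0.2, -0.3, -0.4]
        m = compute_metrics(make_oof(true, pred, score))
        assert m.precision == pytest.approx(0.75)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.accuracy == pytest.approx(0.7)
        assert m.f1 == pytest.approx(2 / 3)

    def test_all_correct_with_separated_scores(self):
        true = [1, 1, 0, 0]
        m = compute_metrics(make_oof(true, true, [2.0, 1.0, -1.0, -2.0]))
        assert (m.precision, m.sensitivity, m.f1, m.accuracy, m.auc) == (1, 1, 1, 1, 1)

    def test_constant_scores_auc_half(self):
        true = [1, 1, 0, 0, 0]
        m = compute_metrics(make_oof(true, [0] * 5, [0.7] * 5))
        assert m.auc == pytest.approx(0.5)

    def test_no_predicted_positives_warns_precision_zero(self):
        with pytest.warns(UserWarning, match="precision"):
            m = compute_metrics(make_oof([1, 0, 0], [0, 0, 0], [-1.0, -2.0, -3.0]))
        assert m.precision == 0.0
        assert m.f1 == 0.0

    def test_auc_matches_sklearn_with_ties(self, rng):
        for _ in range(20):
            true = rng.integers(0, 2, 40)
            if true.sum() in (0, 40):
                continue
            score = rng.integers(-3, 4, 40).astype(float)  # discrete -> ties
            assert auc_midrank(score, true) == pytest.approx(
                roc_auc_score(true, score), abs=1e-12
            )

    @given(st.data())
    def test_pooled_metrics_match_bruteforce_counter(self, data):
        n = data.draw(st.integers(4, 25))
        true = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda v: 0 < sum(v) < len(v)
            )
        )
        pred = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        m = compute_metrics(make_oof(true, pred, [float(p) for p in pred]))
        tp = sum(1 for t, p in zip(true, pred) if t == 1 and p == 1)
        fp = sum(1 for t, p in zip(true, pred) if t == 0 and p == 1)
        fn = sum(1 for t, p in zip(true, pred) if t == 1 and p == 0)
        tn = n - tp - fp - fn
        assert m.precision == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
        assert m.accuracy == pytest.approx((tp + tn) / n)

    def test_auc_invariant_under_monotone_transform(self, rng):
        true = rng.integers(0, 2, 30)
        true[0], true[1] = 0, 1
        score = rng.normal(size=30)
        base = auc_midrank(score, true)
        assert auc_midrank(np.exp(score), true) == pytest.approx(base)
        assert auc_midrank(3 * score - 7, true) == pytest.approx(base)


class TestBootstrap:
    def test_all_correct_degenerate_ci(self):
        true = [1, 1, 1, 0, 0, 0]
        oof = make_oof(true, true, [1.0, 2.0, 3.0, -1.0, -2.0, -3.0])
        ci = bootstrap_ci(oof, "accuracy", rounds=50, seed=0)
        assert (ci.lower, ci.point, ci.upper) == (1.0, 1.0, 1.0)

    def test_same_seed_identical(self, rng):
        true = rng.integers(0, 2, 30)
        true[:2] = [0, 1]
        pred = rng.integers(0, 2, 30)
        oof = make_oof(true, pred, rng.normal(size=30))
        a = bootstrap_ci(oof, "auc", rounds=100, seed=9)
        b = bootstrap_ci(oof, "auc", rounds=100, seed=9)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_shared_stream_matches_single_metric_path(self, rng):
        true = rng.integers(0, 2, 30)
        true[:2] = [0, 1]
        pred = rng.integers(0, 2, 30)
        oof = make_oof(true, pred, rng.normal(size=30))
        combined = compute_metric_cis(oof, rounds=60, seed=4)
        single = bootstrap_ci(oof, "accuracy", rounds=60, seed=4)
        assert combined["accuracy"].lower == pytest.approx(single.lower)
        assert combined["accuracy"].upper == pytest.approx(single.upper)

    def test_ci_width_shrinks_with_cohort_size(self):
        """Bootstrap CI narrows from 48 to 400 patients, same generative model."""
        wins = 0
        trials = 6
        for seed in range(trials):
            widths = {}
            for n_per in (24, 200):
                cohort = generate_cohort(
                    CohortConfig(n_cases=n_per, n_controls=n_per, n_features=10, seed=seed)
                )
                folds = stratified_kfold(cohort.labels, k=4, repeats=1, seed=seed)
                oof, _ = repeated_cv_predict(
                    cohort, list(cohort.feature_names), SVMHyperparams(), folds
                )
                ci = bootstrap_ci(oof, "accuracy", rounds=100, seed=seed)
                widths[n_per] = ci.upper - ci.lower
            wins += widths[200] < widths[24]
        assert wins >= trials - 1

    def test_rounds_validation(self):
        oof = make_oof([1, 0], [1, 0], [1.0, -1.0])
        with pytest.raises(ValueError, match="rounds"):
            bootstrap_ci(oof, "auc", rounds=1)
        with pytest.raises(ValueError, match="unknown metric"):
            bootstrap_ci(oof, "specificity")
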