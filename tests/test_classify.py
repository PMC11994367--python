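"""Glucose-class labelling, KNN/SVM classifiers, stratified splitting and
confusion-matrix evaluation."""

import numpy as np
import pandas as pd
import pytest

from glycoecg import (
    ClassifierConfig,
    add_glucose_class,
    assign_glucose_class,
    evaluate_classifier,
    generate_cohort_features,
    knn_predict,
    stratified_split,
    svm_fit_predict,
)
from glycoecg.classify import confusion_from_labels
from glycoecg.errors import (
    DegenerateTrainingError,
    ParameterError,
    StratificationError,
)


class TestGlucoseClass:
    @pytest.mark.parametrize("glucose,label", [
        (90.0, "normal"),
        (151.0, "hyperglycemia"),
        (150.0, "normal"),       # band is inclusive: 70-150 mg/dL
        (70.0, "normal"),
        (69.9, "below_normal"),
        (500.0, "hyperglycemia"),
    ])
    def test_labels(self, glucose, label):
        assert assign_glucose_class(glucose) == label

    def test_non_positive_rejected(self):
        with pytest.raises(ParameterError):
            assign_glucose_class(0.0)

    def test_add_column(self):
        t = generate_cohort_features(30, seed=0)
        out = add_glucose_class(t)
        assert "glucose_class" in out.columns
        assert set(out["glucose_class"]) <= {"normal", "hyperglycemia", "below_normal"}


def _brute_force_knn(X, y, q, k):
    """Independent oracle: full distance sort per query, pure python.

    Same documented tie rules: distance ties by training-row order, vote
    ties by smaller mean distance, then lexicographic label order.
    """
    out = []
    for row in np.atleast_2d(q):
        dists = sorted(
            (sum((a - b) ** 2 for a, b in zip(x, row)) ** 0.5, i)
            for i, x in enumerate(X)
        )
        votes: dict = {}
        for d, i in dists[:k]:
            votes.setdefault(y[i], []).append(d)
        max_count = max(len(v) for v in votes.values())
        tied = sorted(lab for lab, v in votes.items() if len(v) == max_count)
        if len(tied) > 1:
            means = {lab: sum(votes[lab]) / len(votes[lab]) for lab in tied}
            best = min(means.values())
            tied = sorted(lab for lab in tied if means[lab] == best)
        out.append(tied[0])
    return np.array(out)


class TestKNN:
    def test_nearest_neighbor(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array(["A", "B"])
        assert knn_predict(X, y, [[0.1, 0.0]], k=1)[0] == "A"

    def test_global_majority_when_k_covers_all(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array(["A", "A", "A", "B", "B"])
        q = rng.normal(size=(4, 2))
        assert all(knn_predict(X, y, q, k=5) == "A")

    def test_matches_brute_force_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 2))
            y = np.where(rng.random(40) < 0.5, "A", "B")
            q = rng.normal(size=(10, 2))
            np.testing.assert_array_equal(
                knn_predict(X, y, q, k=5), _brute_force_knn(X, y, q, 5))

    def test_k_larger_than_train_rejected(self, rng):
        with pytest.raises(ParameterError):
            knn_predict(rng.normal(size=(3, 2)), np.array(["A", "B", "A"]),
                        rng.normal(size=(1, 2)), k=5)

    def test_permutation_invariance_without_ties(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.where(rng.random(30) < 0.5, "A", "B")
        q = rng.normal(size=(8, 2))
        base = knn_predict(X, y, q, k=5)
        perm = rng.permutation(30)
        np.testing.assert_array_equal(knn_predict(X[perm], y[perm], q, k=5), base)


class TestSVM:
    @pytest.fixture()
    def blobs(self, rng):
        X = np.vstack([rng.normal(0.0, 0.3, size=(40, 2)),
                       rng.normal(5.0, 0.3, size=(40, 2))])
        y = np.array(["lo"] * 40 + ["hi"] * 40)
        return X, y

    def test_separable_blobs_fully_classified(self, blobs, rng):
        X, y = blobs
        queries = np.vstack([rng.normal(0.0, 0.3, size=(10, 2)),
                             rng.normal(5.0, 0.3, size=(10, 2))])
        pred = svm_fit_predict(X, y, queries)
        assert all(pred[:10] == "lo") and all(pred[10:] == "hi")

    def test_training_points_keep_their_label(self, blobs):
        X, y = blobs
        np.testing.assert_array_equal(svm_fit_predict(X, y, X), y)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(DegenerateTrainingError):
            svm_fit_predict(X, np.array(["A"] * 10), X)


class TestStratifiedSplit:
    def test_canonical_cohort_sizes(self):
        t = add_glucose_class(generate_cohort_features(210, seed=1))
        t = t[t["glucose_class"] != "below_normal"]
        train, val = stratified_split(t, 2.0 / 3.0, seed=0)
        assert len(train) == 140 and len(val) == 70

    def test_disjoint_and_exhaustive(self):
        t = add_glucose_class(generate_cohort_features(97, seed=2))
        train, val = stratified_split(t, 0.6, seed=3)
        assert len(train) + len(val) == len(t)
        assert set(train.index).isdisjoint(val.index)

    def test_seed_determinism(self):
        t = add_glucose_class(generate_cohort_features(60, seed=4))
        a = stratified_split(t, 2.0 / 3.0, seed=9)
        b = stratified_split(t, 2.0 / 3.0, seed=9)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_per_class_proportions(self):
        t = add_glucose_class(generate_cohort_features(120, seed=5))
        train, _ = stratified_split(t, 2.0 / 3.0, seed=0)
        for cls, group in t.groupby("glucose_class"):
            n_tr = (train["glucose_class"] == cls).sum()
            assert n_tr == int(np.floor(2.0 / 3.0 * len(group) + 0.5))

    def test_bad_fraction_rejected(self):
        t = add_glucose_class(generate_cohort_features(30, seed=0))
        with pytest.raises(ParameterError):
            stratified_split(t, 1.5, seed=0)

    def test_tiny_class_rejected(self):
        t = add_glucose_class(generate_cohort_features(30, seed=0))
        t = pd.concat([t[t["glucose_class"] == "normal"],
                       t[t["glucose_class"] == "hyperglycemia"].head(1)])
        with pytest.raises(StratificationError):
            stratified_split(t, 2.0 / 3.0, seed=0)


class TestEvaluation:
    def test_hand_counted_confusion(self):
        cm = confusion_from_labels(
            np.array(["A", "B", "A", "B"]), np.array(["A", "A", "B", "B"]),
            positive="A", negative="B")
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)
        assert cm.counts.tolist() == [[1, 1], [1, 1]]

    def test_perfect_predictions_have_zero_off_diagonal(self):
        y = np.array(["A", "A", "B", "B", "B"])
        cm = confusion_from_labels(y, y, positive="A", negative="B")
        assert cm.fn == cm.fp == 0
        assert cm.positive_accuracy == 100.0 and cm.negative_accuracy == 100.0

    def test_counts_sum_and_percentage_rows(self):
        t = add_glucose_class(generate_cohort_features(210, seed=7))
        t2 = t[t["glucose_class"] != "below_normal"]
        cm = evaluate_classifier(t, "normal_vs_hyper", ClassifierConfig(seed=7))
        assert cm.n == len(t2) - 140
        np.testing.assert_allclose(cm.percentages.sum(axis=1), 100.0, atol=0.1)

    @pytest.mark.parametrize("method", ["svm", "knn"])
    @pytest.mark.parametrize("task", ["normal_vs_hyper", "healthy_vs_dm"])
    def test_beats_majority_baseline(self, method, task):
        t = add_glucose_class(generate_cohort_features(150, seed=8))
        cm = evaluate_classifier(t, task, ClassifierConfig(method=method, seed=8))
        majority = max(cm.tp + cm.fn, cm.fp + cm.tn) / cm.n
        accuracy = (cm.tp + cm.tn) / cm.n
        assert accuracy > majority

    def test_feature_rescaling_invariance_with_standardization(self):
        t = add_glucose_class(generate_cohort_features(100, seed=9))
        cfg = ClassifierConfig(method="knn", seed=9)
        base = evaluate_classifier(t, "normal_vs_hyper", cfg)
        scaled = t.copy()
        scaled["hrv_s"] = scaled["hrv_s"] * 1000.0  # HRV in ms instead of s
        again = evaluate_classifier(scaled, "normal_vs_hyper", cfg)
        assert base.counts.tolist() == again.counts.tolist()

    def test_unknown_task_rejected(self):
        t = add_glucose_class(generate_cohort_features(30, seed=0))
        with pytest.raises(ParameterError):
            evaluate_classifier(t, "euglycemia_vs_other")

    def test_config_validation(self):
        with pytest.raises(ParameterError):
            ClassifierConfig(k=4)
        with pytest.raises(ParameterError):
            ClassifierConfig(c=-1.0)
        with pytest.raises(ParameterError):
            ClassifierConfig(train_fraction=1.0)
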