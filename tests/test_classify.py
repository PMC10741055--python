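"""Grouped cross-validation, model construction, tuning and metrics."""

import numpy as np
import pytest

from voxpheno.classify import (
    BUDGETS,
    KNN_DISTANCES,
    KNNVoice,
    SearchSpace,
    binary_metrics,
    build_model,
    check_no_leakage,
    evaluate,
    grouped_kfold,
    run_group_experiment,
    tune,
)


def _cluster_data(n_per_class=30, n_classes=3, sep=6.0, seed=0, n_features=2):
    """Well-separated Gaussian blobs with one subject per two rows."""
    rng = np.random.default_rng(seed)
    X, y, subjects = [], [], []
    for c in range(n_classes):
        center = rng.normal(scale=sep, size=n_features)
        X.append(center + rng.normal(size=(n_per_class, n_features)))
        y += [f"C{c}"] * n_per_class
        subjects += [f"C{c}s{i // 2}" for i in range(n_per_class)]
    return np.vstack(X), np.array(y), np.array(subjects)


class TestGroupedKFold:
    def test_partition_covers_all_subjects(self):
        labels = {f"s{i}": "AB"[i % 2] for i in range(20)}
        plan = grouped_kfold(labels, k=10, seed=0)
        assert set(plan.assignment) == set(labels)
        assert all(len(plan.validation_subjects(f)) >= 1 for f in range(10))

    def test_same_seed_same_plan(self):
        labels = {f"s{i}": "ABC"[i % 3] for i in range(30)}
        a = grouped_kfold(labels, seed=7)
        b = grouped_kfold(labels, seed=7)
        assert a.assignment == b.assignment

    def test_different_seed_differs(self):
        labels = {f"s{i}": "ABC"[i % 3] for i in range(30)}
        assert grouped_kfold(labels, seed=1).assignment != grouped_kfold(labels, seed=2).assignment

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            grouped_kfold({f"s{i}": "A" for i in range(5)}, k=10)

    def test_subject_recordings_share_one_fold(self):
        """All recordings of a subject land in a single fold."""
        labels = {f"s{i}": "AB"[i % 2] for i in range(12)}
        plan = grouped_kfold(labels, k=10, seed=3)
        recordings = np.repeat(list(labels), 3)  # 3 recordings per subject
        check_no_leakage(plan, recordings)  # raises on violation
        folds_per_subject = {s: plan.assignment[s] for s in labels}
        for s, f in folds_per_subject.items():
            assert s in plan.validation_subjects(f)


class TestSearchSpace:
    @pytest.mark.parametrize("family", ["knn", "svm", "rf"])
    def test_samples_stay_in_bounds(self, family):
        space = SearchSpace(family)
        rng = np.random.default_rng(0)
        for _ in range(200):
            assert space.contains(space.sample(rng))

    def test_encode_round_trips_distinct_configs(self):
        space = SearchSpace("knn")
        rng = np.random.default_rng(1)
        a, b = space.sample(rng), space.sample(rng)
        if a != b:
            assert not np.array_equal(space.encode(a), space.encode(b))


class TestModels:
    @pytest.mark.parametrize("distance", KNN_DISTANCES)
    def test_knn_predicts_separable_blobs(self, distance):
        # correlation-style distances need enough dimensions to be
        # non-degenerate, hence 8 features
        X, y, _ = _cluster_data(n_per_class=20, seed=4, n_features=8)
        # binary-pattern distances need sign structure; standardize around 0
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        model = KNNVoice(k=3, distance=distance, weight="inverse").fit(X, y)
        acc = np.mean(model.predict(X) == y)
        floor = 0.5 if distance in ("hamming", "jaccard", "spearman") else 0.9
        assert acc >= floor
        proba = model.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize(
        "config",
        [
            {"family": "svm", "coding": "one_vs_one", "box_constraint": 10.0, "kernel_scale": 3.0},
            {"family": "svm", "coding": "one_vs_all", "box_constraint": 10.0, "kernel_scale": 3.0},
            {"family": "rf", "min_leaf": 2, "max_splits": 10, "split_criterion": "gdi", "n_vars_sampled": 2},
            {"family": "rf", "min_leaf": 2, "max_splits": 10, "split_criterion": "deviance", "n_vars_sampled": 2},
        ],
    )
    def test_sklearn_families_fit_and_score(self, config):
        X, y, _ = _cluster_data(seed=5)
        model = build_model(config, seed=0)
        model.fit(X, y)
        assert np.mean(model.predict(X) == y) >= 0.9


class TestMetrics:
    def test_hand_computed_confusion(self):
        m = binary_metrics(tp=3, fp=1, fn=1, tn=5)
        assert m["precision"] == pytest.approx(75.0)
        assert m["recall"] == pytest.approx(75.0)
        assert m["specificity"] == pytest.approx(100 * 5 / 6)
        # F1 identity: harmonic mean of precision and recall
        assert m["f1"] == pytest.approx(2 * 75 * 75 / 150)

    def test_undefined_ratios_are_nan(self):
        m = binary_metrics(tp=0, fp=0, fn=2, tn=5)
        assert np.isnan(m["precision"])
        assert m["recall"] == 0.0

    def test_perfect_model_scores_100(self):
        X, y, subjects = _cluster_data(sep=20.0, seed=6)
        plan = grouped_kfold(
            {s: y[np.flatnonzero(subjects == s)[0]] for s in set(subjects)},
            k=10, seed=0,
        )
        report = evaluate(
            lambda: KNNVoice(k=3, distance="euclidean", weight="equal"),
            X, y, subjects, plan,
        )
        assert report.global_accuracy[0] == pytest.approx(100.0)
        assert report.global_accuracy[1] == pytest.approx(0.0)
        for c in report.classes:
            for metric in ("precision", "recall", "specificity", "f1"):
                assert report.per_class[c][metric][0] == pytest.approx(100.0)

    def test_random_scores_give_chance_auc(self):
        """Uninformative scores yield one-vs-rest AUC near 50%."""
        rng = np.random.default_rng(7)

        class RandomScorer:
            def fit(self, X, y):
                self.classes_ = np.unique(y)
                return self

            def predict_proba(self, X):
                p = rng.uniform(size=(len(X), len(self.classes_)))
                return p / p.sum(axis=1, keepdims=True)

            def predict(self, X):
                return self.classes_[
                    np.argmax(self.predict_proba(X), axis=1)
                ]

        n = 300
        X = rng.normal(size=(n, 2))
        y = np.array(["A", "B"] * (n // 2))
        subjects = np.array([f"s{i}" for i in range(n)])
        plan = grouped_kfold(dict(zip(subjects, y)), k=10, seed=1)
        report = evaluate(RandomScorer, X, y, subjects, plan)
        for c in report.classes:
            assert abs(report.per_class[c]["auc"][0] - 50.0) <= 5.0


class TestTune:
    def test_budget_honored_and_deterministic(self):
        X, y, subjects = _cluster_data(n_per_class=20, seed=8)
        plan = grouped_kfold(
            {s: y[np.flatnonzero(subjects == s)[0]] for s in set(subjects)},
            k=10, seed=0,
        )
        best1, hist1 = tune("knn", X, y, subjects, plan, budget=12, seed=5)
        best2, hist2 = tune("knn", X, y, subjects, plan, budget=12, seed=5)
        assert len(hist1) == 12  # objective evaluated exactly budget times
        assert best1 == best2
        assert [h[1] for h in hist1] == [h[1] for h in hist2]

    def test_default_budgets(self):
        assert BUDGETS == {"knn": 30, "svm": 60, "rf": 60}

    def test_beats_small_random_search_on_separable_data(self):
        X, y, subjects = _cluster_data(n_per_class=16, n_classes=2, seed=9)
        plan = grouped_kfold(
            {s: y[np.flatnonzero(subjects == s)[0]] for s in set(subjects)},
            k=10, seed=0,
        )
        _, hist = tune("knn", X, y, subjects, plan, budget=15, seed=2)
        best = max(a for _, a in hist)
        _, rand_hist = tune(
            "knn", X, y, subjects, plan, budget=10, seed=3, method="random"
        )
        assert best >= max(a for _, a in rand_hist) - 1e-9

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        y = np.array(["A"] * 10)
        subjects = np.array([f"s{i}" for i in range(10)])
        plan = grouped_kfold(dict(zip(subjects, y)), k=10, seed=0)
        with pytest.raises(ValueError):
            tune("knn", X, y, subjects, plan, budget=3, seed=0)


class TestGroupExperiment:
    def test_winner_on_separable_cohort(self, ps_feature_table):
        res = run_group_experiment(
            ps_feature_table, "PS", budgets={"knn": 6, "svm": 6, "rf": 6}, seed=0
        )
        assert res["winner"] in res["reports"]
        assert res["reports"][res["winner"]].global_accuracy[0] >= 90.0
        report = res["reports"][res["winner"]]
        d = report.to_dict()
        assert set(d["per_class"]) == set(report.classes)

    def test_missing_group_rejected(self, ps_feature_table):
        with pytest.raises(ValueError):
            run_group_experiment(ps_feature_table, "MA")
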