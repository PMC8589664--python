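"""Centroid replication, prediction metrics, k-means comparators."""

import itertools

import numpy as np
import pandas as pd
import pytest

from psystrat.cohort import PANSS_ITEMS
from psystrat.predict import (
    Centroids,
    PredictConfig,
    assign_by_centroid,
    average_precision,
    compare_partitions,
    confusion_counts,
    dichotomize_outcome,
    evaluate_scores,
    fit_outcome_model,
    fivefold_cv,
    group_centroids,
    group_onehot,
    kmeans_partition,
    metrics_from_confusion,
    partition_agreement,
    pr_curve,
)
from psystrat.simulate import default_params, generate_cohort


class TestCentroids:
    def test_single_patient_group_centroid_is_the_patient(self):
        X = np.vstack([np.full(30, 2.0), np.full(30, 4.0), np.full(30, 6.0)])
        c = group_centroids(X, np.array(["A", "B", "C"]))
        assert np.allclose(c.means.loc["A"], 2.0)

    def test_two_patient_mean(self):
        X = np.vstack([np.full(30, 2.0), np.full(30, 4.0), np.full(30, 1.0), np.full(30, 5.0)])
        c = group_centroids(X, np.array(["A", "A", "B", "C"]))
        assert np.allclose(c.means.loc["A"], 3.0)
        assert c.sizes == {"A": 2, "B": 1, "C": 1}

    def test_column_mean_oracle(self):
        cohort, labels = generate_cohort(default_params(n_patients=80, seed=3))
        c = group_centroids(cohort.panss, labels)
        for g in "ABC":
            expected = cohort.panss[(labels == g).to_numpy()].mean(axis=0)
            assert np.allclose(c.means.loc[g], expected)
        assert ((c.means.to_numpy() >= 1) & (c.means.to_numpy() <= 7)).all()

    def test_empty_group_raises(self):
        X = np.vstack([np.full(30, 2.0), np.full(30, 4.0)])
        with pytest.raises(ValueError, match="C"):
            group_centroids(X, np.array(["A", "B"]))

    def test_assignment_recovers_exact_centroid_match(self):
        means = pd.DataFrame(
            [np.full(30, 2.0), np.full(30, 4.0), np.full(30, 6.0)],
            index=["A", "B", "C"], columns=list(PANSS_ITEMS),
        )
        labels = assign_by_centroid(np.array([np.full(30, 6.0), np.full(30, 2.1)]),
                                    Centroids(means=means))
        assert labels.tolist() == ["C", "A"]

    def test_tie_goes_to_first_label(self):
        means = pd.DataFrame(
            [np.full(30, 2.0), np.full(30, 4.0)], index=["A", "B"],
            columns=list(PANSS_ITEMS),
        )
        labels = assign_by_centroid(np.array([np.full(30, 3.0)]), Centroids(means=means))
        assert labels.tolist() == ["A"]

    def test_second_cohort_agreement_with_generative_labels(self):
        params1 = default_params(n_patients=300, seed=31)
        cohort1, truth1 = generate_cohort(params1)
        centroids = group_centroids(cohort1.panss, truth1)
        cohort2, truth2 = generate_cohort(default_params(n_patients=300, seed=32))
        labels2 = assign_by_centroid(cohort2.panss, centroids)
        assert partition_agreement(truth2, labels2) >= 0.90


class TestDichotomize:
    def test_threshold_is_strict(self):
        labels = dichotomize_outcome(pd.Series([65.0, 65.1, 40.0]))
        assert labels.tolist() == [False, True, False]

    def test_missing_excluded(self):
        labels = dichotomize_outcome(pd.Series([np.nan, 70.0]))
        assert labels.tolist() == [True]

    def test_all_missing_empty(self):
        assert dichotomize_outcome(pd.Series([np.nan, np.nan])).empty


class TestMetrics:
    def test_hand_confusion_arithmetic(self):
        c = {"tp": 6, "fp": 3, "fn": 6, "tn": 15}
        m = metrics_from_confusion(c)
        assert m["precision"] == pytest.approx(6 / 9)
        assert m["recall"] == pytest.approx(6 / 12)
        assert m["accuracy"] == pytest.approx(21 / 30)

    def test_exhaustive_brute_force_small_sets(self):
        # every (labels, predictions) pair up to n = 6
        for n in range(1, 7):
            for lab_bits in itertools.product([False, True], repeat=n):
                for pred_bits in itertools.product([False, True], repeat=n):
                    y = np.array(lab_bits)
                    pred = np.array(pred_bits)
                    c = confusion_counts(y, pred)
                    tp = sum(p and t for p, t in zip(pred_bits, lab_bits))
                    fp = sum(p and not t for p, t in zip(pred_bits, lab_bits))
                    fn = sum(t and not p for p, t in zip(pred_bits, lab_bits))
                    tn = n - tp - fp - fn
                    assert (c["tp"], c["fp"], c["fn"], c["tn"]) == (tp, fp, fn, tn)
                    m = metrics_from_confusion(c)
                    assert m["accuracy"] == (tp + tn) / n
                    if tp + fp:
                        assert m["precision"] == tp / (tp + fp)
                    if tp + fn:
                        assert m["recall"] == tp / (tp + fn)

    def test_perfect_classifier(self):
        y = np.array([True, False, True, False])
        scores = np.array([0.9, 0.1, 0.8, 0.2])
        rep = evaluate_scores(y, scores)
        assert rep["accuracy"] == rep["precision"] == rep["recall"] == 1.0
        assert rep["pr_auc"] == 1.0

    def test_always_good_precision_equals_prevalence(self, rng):
        y = rng.random(40) < 0.3
        y[0] = True  # nonzero prevalence
        scores = np.ones(40)
        rep = evaluate_scores(y, scores)
        assert rep["precision"] == rep["baseline"] == y.mean()
        assert rep["pr_auc"] == pytest.approx(y.mean())

    def test_average_precision_matches_sklearn(self, rng):
        from sklearn.metrics import average_precision_score

        y = rng.random(60) < 0.4
        y[:2] = [True, False]
        scores = rng.random(60)
        assert average_precision(y, scores) == pytest.approx(
            average_precision_score(y, scores)
        )

    def test_pr_curve_thresholds_are_unique_scores(self, rng):
        y = rng.random(20) < 0.5
        scores = rng.integers(0, 4, size=20) / 3
        curve = pr_curve(y, scores)
        assert len(curve) == len(np.unique(scores))


class TestModel:
    def test_monotone_in_single_feature(self):
        X = np.linspace(0, 1, 20)[:, None]
        y = X[:, 0] > 0.5
        model = fit_outcome_model(X, y)
        probs = model.predict_proba(X)[:, 1]
        assert np.all(np.diff(probs) > 0)

    def test_saturated_group_model_matches_empirical_rates(self, rng):
        n = 3000
        labels = rng.choice(["A", "B", "C"], size=n)
        rates = {"A": 0.75, "B": 0.20, "C": 0.35}
        y = np.array([rng.random() < rates[g] for g in labels])
        X = group_onehot(labels).to_numpy()
        model = fit_outcome_model(X, y, PredictConfig(regularization_strength=1000.0))
        for i, g in enumerate("ABC"):
            row = np.zeros(3)
            row[i] = 1.0
            fitted = model.predict_proba(row[None])[0, 1]
            empirical = y[labels == g].mean()
            assert abs(fitted - empirical) < 0.05

    def test_duplicated_rows_same_fit_when_unpenalized(self, rng):
        # with a fixed penalty weight, duplicating the data halves the
        # effective regularization, so exact invariance holds only in the
        # (near-)unpenalized limit
        X = rng.normal(size=(40, 3))
        y = rng.random(40) < 0.5
        y[:2] = [True, False]
        cfg = PredictConfig(regularization_strength=1e6)
        m1 = fit_outcome_model(X, y, cfg)
        m2 = fit_outcome_model(np.vstack([X, X]), np.concatenate([y, y]), cfg)
        assert np.allclose(m1.coef_, m2.coef_, atol=1e-3)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            fit_outcome_model(np.zeros((5, 2)), np.ones(5, dtype=bool))

    def test_fivefold_partitions_the_data(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.random(50) < 0.5
        y[:2] = [True, False]
        rep = fivefold_cv(X, y, PredictConfig(seed=3))
        assert rep["n"] == 50  # every patient scored exactly once


class TestKMeans:
    def test_zero_variance_clusters_exact(self):
        X = np.repeat(np.array([[1.0] * 30, [4.0] * 30, [7.0] * 30]), 10, axis=0)
        labels = kmeans_partition(X, 3, seed=0)
        assert len(set(labels[:10])) == 1
        assert len({labels[0], labels[10], labels[20]}) == 3

    def test_same_seed_same_labels(self, rng):
        X = rng.normal(size=(60, 30))
        assert np.array_equal(kmeans_partition(X, 3, seed=5), kmeans_partition(X, 3, seed=5))

    def test_kmeans_overlaps_planted_groups(self, medium_cohort):
        cohort, truth = medium_cohort
        labels = kmeans_partition(cohort.panss, 3, seed=0)
        comp = compare_partitions(truth, labels)
        assert comp["matched_fraction"] > 0.5  # dominant diagonal


class TestPartitionComparison:
    def test_identical_partitions_ari_one(self):
        p = ["A", "B", "C"] * 10
        assert compare_partitions(p, p)["ari"] == 1.0

    def test_single_cluster_vs_any_ari_zero(self, rng):
        p1 = ["X"] * 30
        p2 = rng.choice(["A", "B", "C"], size=30)
        assert compare_partitions(p1, p2)["ari"] == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_contingency_by_formula_oracle(self):
        p1 = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        p2 = ["x"] * 10 + ["y"] * 10 + ["z"] * 10
        comp = compare_partitions(p1, p2)
        # ARI formula on contingency ((10,0,0),(0,10,0),(0,0,10))
        from scipy.special import comb

        sum_ij = 3 * comb(10, 2)
        sum_a = sum_b = 3 * comb(10, 2)
        expected = (sum_a * sum_b) / comb(30, 2)
        ari = (sum_ij - expected) / ((sum_a + sum_b) / 2 - expected)
        assert comp["ari"] == pytest.approx(ari) == 1.0

    def test_mismatched_sizes_raise(self):
        with pytest.raises(ValueError):
            compare_partitions(["A"], ["A", "B"])
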