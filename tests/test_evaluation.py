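"""Retrieval metrics against brute-force oracles, CIs, reports, projection."""

import numpy as np
import pandas as pd
import pytest

from cbmir.dicom_io import UIDGenerator
from cbmir.evaluation import (
    EvalConfig,
    RelevanceJudgment,
    average_precision,
    bootstrap_ci,
    classification_report,
    evaluate_retrieval,
    mean_average_precision,
    precision_at_k,
    project_features,
)
from cbmir.retrieval import FeatureVector, VectorIndex


def _oracle_precision_at_k(rel, k):
    hits = 0
    for i in range(k):
        hits += int(rel[i])
    return hits / k


def _oracle_average_precision(rel, R):
    total = 0.0
    hits = 0
    for i, r in enumerate(rel, start=1):
        if r:
            hits += 1
            total += hits / i
    return total / R


class TestMetricOracles:
    def test_precision_examples(self):
        assert precision_at_k(np.ones(10, dtype=int), 10) == 1.0
        rel = np.array([1, 1, 1, 1, 1, 1, 1, 0, 0, 0])
        assert precision_at_k(rel, 10) == pytest.approx(0.7)

    def test_precision_matches_count_oracle_on_random_lists(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            rel = rng.integers(0, 2, size=rng.integers(1, 50))
            k = int(rng.integers(1, rel.size + 1))
            assert precision_at_k(rel, k) == _oracle_precision_at_k(rel, k)

    def test_ap_hand_examples(self):
        assert average_precision(np.array([1, 1, 0, 0]), total_relevant=2) == 1.0
        assert average_precision(np.array([0, 1, 0, 1]), total_relevant=2) == pytest.approx(0.5)

    def test_ap_matches_oracle_to_1e12(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            rel = rng.integers(0, 2, size=rng.integers(2, 60))
            R = int(rel.sum())
            if R == 0:
                assert average_precision(rel) is None
                continue
            assert average_precision(rel, total_relevant=R) == pytest.approx(
                _oracle_average_precision(rel, R), abs=1e-12
            )

    def test_ap_zero_relevant_is_excluded_signal(self):
        assert average_precision(np.zeros(5, dtype=int)) is None

    def test_ap_is_one_iff_relevant_fill_top_ranks(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            rel = rng.integers(0, 2, size=20)
            R = int(rel.sum())
            if R == 0:
                continue
            ap = average_precision(rel, total_relevant=R)
            assert 0.0 <= ap <= 1.0
            assert (ap == 1.0) == bool(rel[:R].all())

    def test_map_examples_and_oracle(self):
        assert mean_average_precision([0.5, 1.0]) == 0.75
        assert mean_average_precision([0.42]) == 0.42
        rng = np.random.default_rng(3)
        aps = rng.uniform(0, 1, size=10_000)
        assert mean_average_precision(aps) == pytest.approx(float(aps.mean()), abs=1e-12)
        with pytest.raises(ValueError):
            mean_average_precision([])

    def test_relevance_judgment_binary_rule(self):
        j = RelevanceJudgment("glioma", ["glioma", "normal_brain", "glioma"])
        assert j.rel.tolist() == [1, 0, 1]


class TestBootstrap:
    def test_constant_values_give_zero_width(self):
        lo, mean, hi = bootstrap_ci([0.7] * 50, replicates=500, seed=0)
        assert lo == mean == hi == pytest.approx(0.7)

    def test_mean_inside_interval(self):
        rng = np.random.default_rng(4)
        for s in range(20):
            v = rng.uniform(0, 1, size=50)
            lo, mean, hi = bootstrap_ci(v, replicates=500, seed=s)
            assert lo <= mean <= hi

    def test_deterministic_given_seed(self):
        v = np.random.default_rng(5).normal(size=100)
        assert bootstrap_ci(v, seed=3) == bootstrap_ci(v, seed=3)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            bootstrap_ci([0.5])


def _clustered_features(seed, n_per_class=12, dim=16, spread=0.01, classes=None):
    """Index + query features drawn around shared well-separated class centroids."""
    classes = classes or ["a", "b", "c", "d", "e", "f", "g"]
    rng = np.random.default_rng(seed)
    gen = UIDGenerator(seed)
    centers = {c: np.random.default_rng(1000 + i).normal(size=dim) * 10 for i, c in enumerate(classes)}
    feats = []
    for c in classes:
        for _ in range(n_per_class):
            feats.append(
                FeatureVector(values=centers[c] + rng.normal(size=dim) * spread, uids=gen.triple(), label=c)
            )
    return feats


class TestEvaluateRetrieval:
    def test_separable_clusters_reach_perfect_scores(self):
        index = VectorIndex(_clustered_features(0))
        queries = _clustered_features(1)
        report = evaluate_retrieval(queries, index, EvalConfig(bootstrap_replicates=200))
        assert report.overall("mAP") == pytest.approx(1.0)
        assert report.overall("P@10") == pytest.approx(1.0)

    def test_report_structure(self):
        index = VectorIndex(_clustered_features(2))
        report = evaluate_retrieval(_clustered_features(3), index, EvalConfig(bootstrap_replicates=200))
        assert len(report.table) == 8  # 7 classes + overall
        assert report.table["class"].iloc[-1] == "overall"
        for _, row in report.table.iterrows():
            assert row["mAP_lo"] <= row["mAP"] <= row["mAP_hi"]
            assert 0.0 <= row["mAP"] <= 1.0

    def test_permuted_labels_approach_class_prior(self):
        # destroy the label-feature association; P@10 for a class should sit
        # near that class's share of the index (binomial null)
        rng = np.random.default_rng(6)
        feats = _clustered_features(4, n_per_class=30, spread=25.0)
        labels = [f.label for f in feats]
        rng.shuffle(labels)
        for f, l in zip(feats, labels):
            f.label = l
        index = VectorIndex(feats)
        queries = _clustered_features(5, n_per_class=15, spread=25.0)
        qlabels = [q.label for q in queries]
        rng.shuffle(qlabels)
        for q, l in zip(queries, qlabels):
            q.label = l
        report = evaluate_retrieval(queries, index, EvalConfig(bootstrap_replicates=200))
        prior = 30 / 210
        for _, row in report.table.iterrows():
            if row["class"] == "overall":
                continue
            n_q = row["n_queries"]
            se = np.sqrt(prior * (1 - prior) / (10 * n_q))
            assert abs(row["P@10"] - prior) < 3 * se + 1e-9

    def test_macro_overall_mode_averages_class_means(self):
        index = VectorIndex(_clustered_features(13))
        queries = _clustered_features(14)
        per_query = evaluate_retrieval(queries, index, EvalConfig(bootstrap_replicates=200))
        macro = evaluate_retrieval(
            queries, index, EvalConfig(bootstrap_replicates=200, overall_mode="macro")
        )
        class_means = per_query.per_query.groupby("label")["AP"].mean()
        assert macro.overall("mAP") == pytest.approx(float(class_means.mean()))

    def test_patient_overlap_rejected(self):
        feats = _clustered_features(7)
        index = VectorIndex(feats)
        with pytest.raises(ValueError, match="overlap"):
            evaluate_retrieval(
                _clustered_features(8), index,
                EvalConfig(bootstrap_replicates=200),
                query_patients=["p1", "p2"],
                index_patients=["p2", "p3"],
            )

    def test_query_class_absent_from_index_is_excluded_and_counted(self):
        feats = _clustered_features(9, classes=["a", "b"])
        index = VectorIndex(feats)
        queries = _clustered_features(10, classes=["a", "b"])
        queries[0].label = "zz"
        report = evaluate_retrieval(queries, index, EvalConfig(bootstrap_replicates=200))
        assert report.excluded_queries == 1


class TestClassificationReport:
    def test_perfect_predictions(self):
        labels = ["a"] * 5 + ["b"] * 5
        out = classification_report(labels, labels)
        assert out["overall"]["precision"] == 1.0
        cm = out["confusion_matrix"]
        assert (np.diag(cm.values) == [5, 5]).all()
        assert cm.values.sum() == 10

    def test_toy_counts_match_definitions(self):
        # pos class: TP=8, FP=2, FN=4, TN=6
        true = ["pos"] * 8 + ["neg"] * 2 + ["pos"] * 4 + ["neg"] * 6
        pred = ["pos"] * 8 + ["pos"] * 2 + ["neg"] * 4 + ["neg"] * 6
        out = classification_report(pred, true, class_names=["neg", "pos"])
        row = out["per_class"].set_index("class").loc["pos"]
        assert row["precision"] == pytest.approx(0.8)
        assert row["recall"] == pytest.approx(2 / 3)
        assert row["f1"] == pytest.approx(8 / 11)

    def test_row_sums_equal_true_counts(self):
        rng = np.random.default_rng(11)
        true = list(rng.choice(["a", "b", "c"], size=60))
        pred = list(rng.choice(["a", "b", "c"], size=60))
        cm = classification_report(pred, true)["confusion_matrix"]
        counts = pd.Series(true).value_counts()
        for cls in cm.index:
            assert cm.loc[cls].sum() == counts[cls]

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError):
            classification_report(["a", "x"], ["a", "a"], class_names=["a"])


class TestProjection:
    def test_shape_seed_and_finiteness(self):
        rng = np.random.default_rng(12)
        feats = rng.normal(size=(40, 16))
        a = project_features(feats, iterations=300, seed=1)
        b = project_features(feats, iterations=300, seed=1)
        assert a.shape == (40, 3)
        assert np.all(np.isfinite(a))
        assert np.allclose(a, b)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            project_features(np.zeros((3, 4)))
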