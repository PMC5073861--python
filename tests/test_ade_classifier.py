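"""Feature assembly, forest training, and evaluation-metric tests."""

import numpy as np
import pytest

from degraph.ade_classifier import (
    EdgeContexts,
    build_feature_frame,
    cross_validate,
    evaluate,
    feature_columns,
    featurize,
    split_train_test,
    train_edge_classifier,
)
from degraph.deg_core import ADVERSE, DEGEdge, sample_pseudo_negatives
from degraph.semantic_context import EdgeSentimentContext
from degraph.synthetic_fixtures import PlantedDEGParams, generate_planted_sider
from degraph.topo_features import TOPO_COLUMNS, feature_frame, featurize_edge

from conftest import make_deg


@pytest.fixture
def twitter_deg():
    deg = make_deg(["d1", "d2"], ["e1", "e2"], [])
    deg.add_edge(DEGEdge("d1", "e1", label=ADVERSE, temporal_weight=2.0, frequency_weight=3))
    deg.add_edge(DEGEdge("d2", "e2", temporal_weight=5.0, frequency_weight=1))
    return deg


@pytest.fixture
def contexts():
    return EdgeContexts(
        sentiment={
            ("d1", "e1"): EdgeSentimentContext(1.0, -1.0),
            ("d2", "e2"): EdgeSentimentContext(0.0, 0.5),
        },
        topic={
            "d1": np.array([0.7, 0.3]),
            "d2": np.array([0.2, 0.8]),
            "e1": np.array([0.6, 0.4]),
            "e2": np.array([0.1, 0.9]),
        },
        k=2,
    )


class TestFeaturize:
    def test_topo_selector_block(self, twitter_deg):
        vec = featurize(("d1", "e1"), twitter_deg, None, None, "topo")
        assert len(vec) == len(feature_columns("topo"))
        np.testing.assert_allclose(
            vec[: len(TOPO_COLUMNS)],
            featurize_edge(twitter_deg, "d1", "e1").as_array(),
        )
        assert vec[-2] == 2.0 and vec[-1] == 3.0  # the two edge weights

    def test_sentiment_block_appended(self, twitter_deg, contexts):
        vec = featurize(("d1", "e1"), twitter_deg, None, contexts, "topo_sent")
        assert vec[-2] == 1.0 and vec[-1] == -1.0

    def test_topic_block_is_concatenated_contexts(self, twitter_deg, contexts):
        vec = featurize(("d1", "e1"), twitter_deg, None, contexts, "topo_sent_topic")
        np.testing.assert_allclose(vec[-4:], [0.7, 0.3, 0.6, 0.4])

    def test_enriched_equals_sider_featurization(self, twitter_deg, contexts):
        sider = make_deg(
            ["d1", "d2"], ["e1", "e2"], [("d1", "e1"), ("d2", "e1"), ("d2", "e2")]
        )
        vec = featurize(("d1", "e1"), twitter_deg, sider, contexts, "enriched")
        expected_sider = featurize_edge(sider, "d1", "e1").as_array()
        np.testing.assert_allclose(vec[-7:-1], expected_sider)
        assert vec[-1] == 0.0  # both endpoints present in SIDER

    def test_missing_sider_endpoint_sentinel(self, twitter_deg, contexts):
        sider = make_deg(["d1"], ["e1"], [("d1", "e1")])
        vec = featurize(("d2", "e2"), twitter_deg, sider, contexts, "enriched")
        np.testing.assert_allclose(vec[-7:-1], np.zeros(6))
        assert vec[-1] == 1.0

    def test_missing_context_raises(self, twitter_deg):
        with pytest.raises(ValueError, match="sentiment"):
            featurize(("d1", "e1"), twitter_deg, None, EdgeContexts(), "topo_sent")

    def test_feature_length_constant_per_selector(self, twitter_deg, contexts):
        sider = make_deg(["d1", "d2"], ["e1", "e2"], [("d1", "e1")])
        for selector in ("topo", "topo_sent", "topo_sent_topic", "enriched"):
            cols = feature_columns(selector, k=2)
            frame = build_feature_frame(twitter_deg, sider, contexts, selector)
            assert list(frame.columns) == ["label", *cols]
            assert frame.shape == (2, 1 + len(cols))

    def test_enriched_superset_of_baseline_columns(self):
        base = feature_columns("topo")
        enriched = feature_columns("enriched", k=3)
        assert set(base) <= set(enriched)


class TestMetrics:
    def test_perfect_predictions(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]] * 5)
        y = np.array([0, 0, 1, 1] * 5)
        model = train_edge_classifier(X, y, seed=0)
        assert evaluate(model, X, y) == (1.0, 1.0, 1.0)

    def test_confusion_formula(self):
        class Fixed:
            def predict(self, X):
                # TP=3, FP=1, FN=1, TN=0
                return np.array([1, 1, 1, 1, 0])

        y = np.array([1, 1, 1, 0, 1])
        p, r, f = evaluate(Fixed(), np.zeros((5, 1)), y)
        assert (p, r, f) == (0.75, 0.75, 0.75)

    def test_no_positive_predictions_zero_precision(self):
        class Never:
            def predict(self, X):
                return np.zeros(len(X), dtype=int)

        y = np.array([1, 0, 1])
        p, r, f = evaluate(Never(), np.zeros((3, 1)), y)
        assert (p, r, f) == (0.0, 0.0, 0.0)

    def test_metrics_match_independent_tally(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 4))
        y = (X[:, 0] + 0.5 * rng.normal(size=200) > 0).astype(int)
        model = train_edge_classifier(X[:100], y[:100], seed=0)
        p, r, f = evaluate(model, X[100:], y[100:])
        pred = model.predict(X[100:])
        truth = y[100:]
        tp = np.sum((pred == 1) & (truth == 1))
        fp = np.sum((pred == 1) & (truth == 0))
        fn = np.sum((pred == 0) & (truth == 1))
        assert p == pytest.approx(tp / (tp + fp))
        assert r == pytest.approx(tp / (tp + fn))
        assert f == pytest.approx(2 * p * r / (p + r))


class TestTraining:
    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            train_edge_classifier(np.zeros((4, 2)), [1, 1, 1, 1], seed=0)

    def test_seed_identical_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 3))
        y = (X.sum(axis=1) > 0).astype(int)
        a = train_edge_classifier(X, y, seed=7).predict(X)
        b = train_edge_classifier(X, y, seed=7).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_uses_ten_trees_by_default(self):
        X = np.array([[0.0], [1.0]] * 10)
        y = np.array([0, 1] * 10)
        model = train_edge_classifier(X, y, seed=0)
        assert len(model.estimators_) == 10


class TestCrossValidate:
    def test_separable_data_perfect(self):
        X = np.array([[0.0], [10.0]] * 30)
        y = np.array([0, 1] * 30)
        result = cross_validate(X, y, folds=10, seed=0)
        assert result["f1"]["mean"] == 1.0
        assert result["f1"]["sd"] == 0.0

    def test_seed_reproducible(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(int)
        a = cross_validate(X, y, folds=5, seed=4)
        b = cross_validate(X, y, folds=5, seed=4)
        assert a == b

    def test_mean_is_mean_of_folds(self):
        # re-derive the mean from a manual fold loop with the same splitter
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.model_selection import StratifiedKFold

        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 2))
        y = (X[:, 0] + 0.3 * rng.normal(size=50) > 0).astype(int)
        result = cross_validate(X, y, folds=5, seed=1)
        f1s = []
        for tr, va in StratifiedKFold(5, shuffle=True, random_state=1).split(X, y):
            clf = RandomForestClassifier(n_estimators=10, random_state=1)
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[va])
            tp = np.sum((pred == 1) & (y[va] == 1))
            fp = np.sum((pred == 1) & (y[va] == 0))
            fn = np.sum((pred == 0) & (y[va] == 1))
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f1s.append(2 * p * r / (p + r) if p + r else 0.0)
        assert result["f1"]["mean"] == pytest.approx(np.mean(f1s), abs=1e-12)


class TestSplit:
    def test_disjoint_exhaustive(self):
        train, test = split_train_test(range(101), 0.5, seed=0)
        assert len(train) + len(test) == 101
        assert not (set(train) & set(test))

    def test_half_split_sizes(self):
        train, test = split_train_test(range(1000), 0.5, seed=1)
        assert len(train) == len(test) == 500

    def test_seed_reproducible(self):
        assert split_train_test(range(50), 0.3, seed=9) == split_train_test(
            range(50), 0.3, seed=9
        )

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_train_test(range(10), 1.0, seed=0)


class TestPlantedSignal:
    def test_f1_degrades_as_signal_vanishes(self):
        """Weakening the planted block contrast lowers held-out F1."""

        def run(p_in):
            deg, _ = generate_planted_sider(
                PlantedDEGParams(n_drugs=30, n_effects=60, p_in=p_in, seed=0)
            )
            adverse = sorted(deg.adverse_pairs())
            negs = sorted(sample_pseudo_negatives(deg, len(adverse), seed=0))
            pairs = adverse + negs
            y = np.array([1] * len(adverse) + [0] * len(negs))
            X = feature_frame(deg, pairs)[list(TOPO_COLUMNS)].to_numpy()
            tr, te = split_train_test(range(len(pairs)), 0.5, seed=0)
            model = train_edge_classifier(X[tr], y[tr], seed=0)
            return evaluate(model, X[te], y[te])[2]

        strong = run(0.6)
        weak = run(0.1)
        assert strong > weak - 0.05  # allows sampling noise, expects no inversion
        assert strong >= 0.85
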