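import numpy as np
import pytest

from fundushybrid.classifier_eval import (
    MLPConfig,
    error_histogram,
    evaluate,
    metrics_from_confusion,
    predict,
    predict_proba,
    roc_auc,
    train_ann,
)
from fundushybrid.dataset import DatasetSplit
from fundushybrid.errors import InvalidArgumentError


def make_split(n, seed=0, frac_val=0.2, frac_test=0.2):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    n_test, n_val = int(frac_test * n), int(frac_val * n)
    return DatasetSplit(
        train=tuple(idx[n_test + n_val :].tolist()),
        validation=tuple(idx[n_test : n_test + n_val].tolist()),
        test=tuple(idx[:n_test].tolist()),
    )


@pytest.fixture
def two_clusters(rng):
    X = np.vstack([rng.normal(-2, 0.4, size=(100, 2)), rng.normal(2, 0.4, size=(100, 2))])
    y = np.array(["a"] * 100 + ["b"] * 100)
    return X, y


class TestTrainAnn:
    def test_separable_data_high_train_accuracy(self, two_clusters):
        X, y = two_clusters
        split = make_split(200)
        cfg = MLPConfig(input_dim=2, output_classes=2, seed=0)
        model, trace = train_ann(X, y, split, cfg)
        tr = np.asarray(split.train)
        acc = (predict(model, X[tr]) == y[tr]).mean()
        assert acc >= 0.99
        assert trace.epochs_run <= cfg.max_epochs

    def test_patience_stop_on_constant_features(self):
        rng = np.random.default_rng(0)
        X = np.ones((60, 4))
        y = np.array(["a", "b", "c"] * 20)
        split = make_split(60)
        cfg = MLPConfig(input_dim=4, output_classes=3, validation_patience=6, seed=1)
        model, trace = train_ann(X, y, split, cfg)
        assert trace.stop_reason in ("validation_patience", "gradient_floor")
        assert trace.epochs_run <= trace.best_epoch + cfg.validation_patience + 1

    def test_best_epoch_validation_minimum(self, two_clusters):
        X, y = two_clusters
        split = make_split(200)
        cfg = MLPConfig(input_dim=2, output_classes=2, seed=3)
        _, trace = train_ann(X, y, split, cfg)
        val = trace.cross_entropy["validation"]
        assert val[trace.best_epoch] <= min(val[trace.best_epoch :]) + 1e-12

    def test_deterministic(self, two_clusters):
        X, y = two_clusters
        split = make_split(200)
        cfg = MLPConfig(input_dim=2, output_classes=2, seed=5)
        m1, _ = train_ann(X, y, split, cfg)
        m2, _ = train_ann(X.copy(), y.copy(), split, cfg)
        for (W1, b1), (W2, b2) in zip(m1.weights, m2.weights):
            assert np.array_equal(W1, W2) and np.array_equal(b1, b2)

    def test_single_class_training_set_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array(["a"] * 20)
        split = make_split(20)
        with pytest.raises(InvalidArgumentError):
            train_ann(X, y, split, MLPConfig(input_dim=3, output_classes=2))

    def test_trace_lengths_consistent(self, two_clusters):
        X, y = two_clusters
        split = make_split(200)
        _, trace = train_ann(X, y, split, MLPConfig(input_dim=2, output_classes=2, seed=1))
        n = trace.epochs_run
        for phase in ("train", "validation", "test"):
            assert len(trace.cross_entropy[phase]) == n
            assert len(trace.mse[phase]) == n

    def test_mse_trace_nonnegative(self, two_clusters):
        X, y = two_clusters
        split = make_split(200)
        _, trace = train_ann(X, y, split, MLPConfig(input_dim=2, output_classes=2, seed=1))
        assert all(v >= 0 for v in trace.mse["train"])

    def test_configurable_depth(self, two_clusters):
        X, y = two_clusters
        split = make_split(200)
        cfg = MLPConfig(input_dim=2, output_classes=2, hidden_layers=2, seed=0)
        model, _ = train_ann(X, y, split, cfg)
        assert len(model.weights) == 3  # two hidden layers + output


class TestEvaluate:
    def _perfect_model(self, X, y, classes):
        split = make_split(len(y))
        cfg = MLPConfig(input_dim=X.shape[1], output_classes=len(classes), seed=0)
        model, _ = train_ann(X, y, split, cfg)
        return model

    def test_confusion_totals(self, two_clusters):
        X, y = two_clusters
        model = self._perfect_model(X, y, ("a", "b"))
        cm = evaluate(model, X, y)
        assert cm.sum() == len(y)
        assert cm.shape == (2, 2)

    def test_marginals_match_tally(self, two_clusters):
        X, y = two_clusters
        model = self._perfect_model(X, y, ("a", "b"))
        preds = predict(model, X)
        cm = evaluate(model, X, y)
        # hand tally
        manual = np.zeros((2, 2), dtype=int)
        lookup = {"a": 0, "b": 1}
        for t, p in zip(y, preds):
            manual[lookup[t], lookup[p]] += 1
        assert np.array_equal(cm, manual)

    def test_dim_mismatch(self, two_clusters):
        X, y = two_clusters
        model = self._perfect_model(X, y, ("a", "b"))
        with pytest.raises(InvalidArgumentError):
            evaluate(model, X[:, :1], y)


class TestMetricsFromConfusion:
    def test_binary_example(self):
        cm = np.array([[9, 1], [2, 8]])
        rep = metrics_from_confusion(cm, classes=("pos", "neg"))
        pos = rep["per_class"]["pos"]
        assert pos["accuracy"] == pytest.approx(85.0)
        assert pos["sensitivity"] == pytest.approx(90.0)
        assert pos["precision"] == pytest.approx(100 * 9 / 11)
        assert pos["specificity"] == pytest.approx(80.0)

    def test_perfect_diagonal(self):
        cm = np.diag([10, 10, 10, 10])
        rep = metrics_from_confusion(cm)
        for metrics in rep["per_class"].values():
            for v in metrics.values():
                assert v == pytest.approx(100.0)
        assert rep["pooled_accuracy"] == pytest.approx(100.0)

    def test_single_misclassification_arithmetic(self):
        cm = np.diag([5, 5, 5, 5])
        cm[0, 1] += 1  # one class-0 sample predicted as class 1
        rep = metrics_from_confusion(cm, classes=("c0", "c1", "c2", "c3"))
        c0 = rep["per_class"]["c0"]
        # one-vs-rest for c0: TP=5, FN=1, FP=0, TN=15
        assert c0["sensitivity"] == pytest.approx(100 * 5 / 6)
        assert c0["precision"] == pytest.approx(100.0)
        assert c0["accuracy"] == pytest.approx(100 * 20 / 21)
        c1 = rep["per_class"]["c1"]
        assert c1["precision"] == pytest.approx(100 * 5 / 6)  # FP=1
        assert c1["specificity"] == pytest.approx(100 * 15 / 16)

    def test_macro_is_unweighted_mean(self):
        cm = np.array([[8, 2], [1, 9]])
        rep = metrics_from_confusion(cm, classes=("x", "y"))
        for metric, value in rep["average_ratio"].items():
            per = [rep["per_class"]["x"][metric], rep["per_class"]["y"][metric]]
            assert value == pytest.approx(np.mean(per))

    def test_ovr_counts_identities(self, rng):
        cm = rng.integers(0, 20, size=(4, 4))
        cm[0, 0] += 1  # ensure non-empty
        tp_sum = sum(cm[k, k] for k in range(4))
        assert tp_sum == np.trace(cm)
        for k in range(4):
            assert cm[k, k] + (cm[k].sum() - cm[k, k]) == cm[k].sum()

    def test_metrics_in_percentage_range(self, rng):
        cm = rng.integers(0, 30, size=(4, 4)) + 1
        rep = metrics_from_confusion(cm)
        for metrics in rep["per_class"].values():
            for v in metrics.values():
                assert 0.0 <= v <= 100.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            metrics_from_confusion(np.zeros((3, 3), dtype=int))


def auc_pair_counting_oracle(pos_mask, scores):
    """All-pairs concordance count."""
    pos = scores[pos_mask]
    neg = scores[~pos_mask]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        y = np.array(["a", "a", "b", "b"])
        out = roc_auc(scores, y, ("a", "b"))
        assert out["per_class"]["a"] == pytest.approx(100.0)
        assert out["macro"] == pytest.approx(100.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        raw = rng.random((n, 2))
        scores = raw / raw.sum(axis=1, keepdims=True)
        y = rng.choice(["a", "b"], size=n)
        out = roc_auc(scores, y, ("a", "b"))
        assert out["macro"] == pytest.approx(50.0, abs=3.0)

    def test_six_sample_pair_counting_oracle(self):
        s = np.array([0.9, 0.4, 0.35, 0.8, 0.2, 0.5])
        scores = np.stack([s, 1 - s], axis=1)
        y = np.array(["a", "b", "a", "a", "b", "b"])
        out = roc_auc(scores, y, ("a", "b"))
        expected = 100 * auc_pair_counting_oracle(y == "a", s)
        assert out["per_class"]["a"] == pytest.approx(expected)

    def test_absent_class_excluded(self):
        scores = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.3, 0.4, 0.3]])
        y = np.array(["a", "b", "a"])
        out = roc_auc(scores, y, ("a", "b", "c"))
        assert out["per_class"]["c"] is None
        assert out["macro"] is not None

    def test_rows_must_sum_to_one(self):
        with pytest.raises(InvalidArgumentError):
            roc_auc(np.array([[0.5, 0.1]]), np.array(["a"]), ("a", "b"))


class TestErrorHistogram:
    def test_identical_all_mass_at_zero(self):
        t = np.eye(4)[np.array([0, 1, 2, 3])]
        hist = error_histogram(t, t, np.array(["train"] * 4), bins=20)
        counts = hist["counts"]["train"]
        expected, _ = np.histogram([0.0], bins=hist["bin_edges"])
        assert counts.sum() == t.size
        assert np.array_equal(counts, expected * t.size)

    def test_extreme_errors_in_outer_bins(self):
        t = np.array([[1.0], [0.0]])
        o = np.array([[0.0], [1.0]])
        hist = error_histogram(t, o, np.array(["train", "train"]), bins=20)
        counts = hist["counts"]["train"]
        assert counts[0] == 1 and counts[-1] == 1
        assert counts[1:-1].sum() == 0

    def test_matches_direct_binning(self, rng):
        t = rng.random((30, 4))
        o = rng.random((30, 4))
        tags = np.array(["train"] * 20 + ["test"] * 10)
        hist = error_histogram(t, o, tags, bins=20)
        errors = t - o
        for phase, mask in (("train", tags == "train"), ("test", tags == "test")):
            expected, _ = np.histogram(errors[mask].ravel(), bins=hist["bin_edges"])
            assert np.array_equal(hist["counts"][phase], expected)

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            error_histogram(np.empty((0, 2)), np.empty((0, 2)), np.empty(0))


class TestPredictProba:
    def test_rows_sum_to_one(self, two_clusters):
        X, y = two_clusters
        split = make_split(200)
        model, _ = train_ann(X, y, split, MLPConfig(input_dim=2, output_classes=2, seed=0))
        probs = predict_proba(model, X)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert probs.shape == (200, 2)
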