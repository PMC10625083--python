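import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from chatmood import ssl_classify as sl


def separable_blobs(n_per_class=30, n_classes=8, spread=0.05, seed=0):
    """Well-separated Gaussian blobs, one per category, on an 8-dim simplex."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        center = np.zeros(8)
        center[c] = 5.0
        X.append(center + rng.normal(scale=spread, size=(n_per_class, 8)))
        y.extend([c] * n_per_class)
    return np.vstack(X), np.array(y)


class TestSplitTrainTest:
    def test_eighty_twenty_sizes(self):
        X, y = separable_blobs(n_per_class=25)
        tr, te = sl.split_train_test(X, y, seed=0)
        assert len(tr) == 160 and len(te) == 40

    def test_deterministic_per_seed(self):
        X, y = separable_blobs(n_per_class=10)
        tr1, te1 = sl.split_train_test(X, y, seed=9)
        tr2, te2 = sl.split_train_test(X, y, seed=9)
        assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)

    def test_stratified_per_stratum_arithmetic(self):
        X, y = separable_blobs(n_per_class=25)
        tr, te = sl.split_train_test(X, y, seed=1, stratified=True)
        for c in range(8):
            assert (y[tr] == c).sum() == 20
            assert (y[te] == c).sum() == 5

    def test_disjoint_and_exhaustive(self):
        X, y = separable_blobs(n_per_class=5)
        tr, te = sl.split_train_test(X, y, seed=2)
        assert not set(tr) & set(te)
        assert len(tr) + len(te) == len(y)

    def test_singleton_category_rejected_when_stratified(self):
        X = np.zeros((9, 2))
        y = np.array([0] * 8 + [1])
        with pytest.raises(ValueError):
            sl.split_train_test(X, y, stratified=True)


class TestTrainAndEvaluate:
    def test_separable_mlp_is_perfect(self):
        X, y = separable_blobs()
        tr, te = sl.split_train_test(X, y, seed=0)
        rows = sl.train_and_evaluate([sl.ModelSpec("mlp", seed=0)],
                                     X[tr], y[tr], X[te], y[te])
        spec, metrics, err = rows[0]
        assert err is None
        assert metrics.accuracy == 1.0 and metrics.f1 == 1.0

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(1000, 8))
        y = rng.integers(0, 8, size=1000)  # labels independent of features
        tr, te = sl.split_train_test(X, y, seed=0, stratified=False)
        rows = sl.train_and_evaluate(
            [sl.ModelSpec("mlp", {"max_iter": 100}, seed=0)],
            X[tr], y[tr], X[te], y[te])
        acc = rows[0][1].accuracy
        # binomial band around 1/8 at n=200 test items (~4.7 SD)
        assert abs(acc - 0.125) < 0.11

    def test_duplicate_specs_identical_metrics(self):
        X, y = separable_blobs(n_per_class=10, spread=1.0)
        tr, te = sl.split_train_test(X, y, seed=3)
        spec = sl.ModelSpec("random_forest", {"n_estimators": 30}, seed=5)
        rows = sl.train_and_evaluate([spec, spec], X[tr], y[tr], X[te], y[te])
        assert rows[0][1] == rows[1][1]

    def test_failing_model_is_flagged_and_run_continues(self):
        bad = sl.ModelSpec("svm", {"C": -1.0})  # invalid hyperparameter
        good = sl.ModelSpec("naive_bayes")
        X, y = separable_blobs(n_per_class=5)
        rows = sl.train_and_evaluate([bad, good], X, y, X, y)
        assert rows[0][1] is None and rows[0][2] is not None
        assert rows[1][1] is not None

    @pytest.mark.parametrize("family", sl.MODEL_FAMILIES)
    def test_every_family_fits_and_scores(self, family):
        X, y = separable_blobs(n_per_class=8, spread=0.5)
        tr, te = sl.split_train_test(X, y, seed=0)
        spec = sl.ModelSpec(family, {"max_iter": 150} if family == "mlp" else {},
                            seed=0)
        model = sl.fit_model(spec, X[tr], y[tr])
        metrics = sl.evaluate(y[te], model.predict_proba(X[te]))
        assert 0.0 <= metrics.accuracy <= 1.0


class TestPredictProba:
    def test_rows_sum_to_one_and_argmax_consistent(self):
        X, y = separable_blobs(n_per_class=6)
        model = sl.fit_model(sl.ModelSpec("mlp", {"max_iter": 150}), X, y)
        proba = sl.predict_proba(model, X)
        assert proba.shape == (len(y), 8)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(np.argmax(proba, axis=1), model.predict(X))

    def test_repeat_call_identical(self):
        X, y = separable_blobs(n_per_class=6)
        model = sl.fit_model(sl.ModelSpec("random_forest", {"n_estimators": 20}), X, y)
        assert np.array_equal(model.predict_proba(X), model.predict_proba(X))

    def test_untrained_input_rejected(self):
        with pytest.raises(TypeError):
            sl.predict_proba(object(), np.zeros((2, 8)))

    def test_missing_training_classes_get_zero_probability(self):
        X, y = separable_blobs(n_per_class=10)
        keep = y < 3
        model = sl.fit_model(sl.ModelSpec("naive_bayes"), X[keep], y[keep])
        proba = model.predict_proba(X[:5])
        assert proba.shape[1] == 8
        assert np.all(proba[:, 3:] == 0.0)
        assert np.allclose(proba.sum(axis=1), 1.0)


class TestMacroAuroc:
    @staticmethod
    def pairwise_auc(y_bin, scores):
        pos = scores[y_bin == 1]
        neg = scores[y_bin == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        return wins / (len(pos) * len(neg))

    def test_matches_bruteforce_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            y = rng.integers(0, 8, size=40)
            proba = rng.dirichlet(np.ones(8), size=40)
            got = sl.evaluate(y, proba)
            aucs = []
            for c in range(8):
                y_bin = (y == c).astype(int)
                if y_bin.min() == y_bin.max():
                    continue
                auc = self.pairwise_auc(y_bin, proba[:, c])
                assert auc == pytest.approx(
                    roc_auc_score(y_bin, proba[:, c]), abs=1e-9)
                aucs.append(auc)
            assert got.auroc == pytest.approx(float(np.mean(aucs)), abs=1e-9)


class TestSelfTrain:
    def test_threshold_one_yields_supervised_baseline(self):
        X, y = separable_blobs(n_per_class=10)
        pool = np.random.default_rng(0).normal(size=(50, 8))
        spec = sl.ModelSpec("mlp", {"max_iter": 150}, seed=0)
        model, history = sl.self_train(spec, X, y, pool, threshold=1.0)
        assert history[0].stop_reason == "no_new_labels"
        assert sum(len(h.pseudo_labeled) for h in history) == 0
        baseline = sl.fit_model(spec, X, y)
        assert np.array_equal(model.predict(pool), baseline.predict(pool))

    def test_max_iters_bounds_history(self):
        X, y = separable_blobs(n_per_class=10)
        model, history = sl.self_train(
            sl.ModelSpec("mlp", {"max_iter": 150}, seed=0), X, y, X.copy(),
            threshold=0.5, max_iters=1)
        assert len(history) <= 1

    def test_pseudo_labeled_sets_disjoint_across_iterations(self):
        X, y = separable_blobs(n_per_class=15, spread=0.8)
        pool, _ = separable_blobs(n_per_class=40, spread=0.8, seed=9)
        spec = sl.ModelSpec("mlp", {"max_iter": 200}, seed=1)
        _, history = sl.self_train(spec, X, y, pool, threshold=0.8, max_iters=4)
        seen: set[int] = set()
        for h in history:
            new = set(h.pseudo_labeled)
            assert not new & seen
            seen |= new
        for h in history:
            for _, conf in h.pseudo_labeled.values():
                assert conf > 0.8

    def test_confident_pseudo_labels_beat_test_accuracy_on_separable_data(self):
        X, y = separable_blobs(n_per_class=12, spread=0.6)
        tr, te = sl.split_train_test(X, y, seed=0)
        pool, pool_truth = separable_blobs(n_per_class=30, spread=0.6, seed=4)
        spec = sl.ModelSpec("mlp", {"max_iter": 200}, seed=0)
        model, history = sl.self_train(spec, X[tr], y[tr], pool,
                                       threshold=0.9, max_iters=2)
        pseudo = {i: lab for h in history for i, (lab, _) in h.pseudo_labeled.items()}
        assert pseudo  # something was labeled
        pseudo_acc = np.mean([pool_truth[i] == lab for i, lab in pseudo.items()])
        test_acc = sl.evaluate(y[te], model.predict_proba(X[te])).accuracy
        assert pseudo_acc >= test_acc - 1e-9

    def test_empty_labeled_set_rejected(self):
        with pytest.raises(ValueError):
            sl.self_train(sl.ModelSpec("mlp"), np.zeros((0, 8)), [],
                          np.zeros((5, 8)))


class TestHighConfidenceEval:
    def test_threshold_zero_equals_plain_evaluation(self):
        X, y = separable_blobs(n_per_class=10, spread=1.5)
        model = sl.fit_model(sl.ModelSpec("mlp", {"max_iter": 150}), X, y)
        full = sl.evaluate(y, model.predict_proba(X))
        high = sl.high_confidence_eval(model, X, y, threshold=0.0)
        assert high == full

    def test_unreachable_threshold_gives_empty_signal(self):
        X, y = separable_blobs(n_per_class=10, spread=3.0)
        model = sl.fit_model(sl.ModelSpec("naive_bayes"), X, y)
        assert sl.high_confidence_eval(model, X, y, threshold=1.1) is None

    def test_high_confidence_subset_at_least_as_accurate(self):
        for seed in range(5):
            X, y = separable_blobs(n_per_class=25, spread=1.2, seed=seed)
            tr, te = sl.split_train_test(X, y, seed=seed)
            model = sl.fit_model(
                sl.ModelSpec("mlp", {"max_iter": 200}, seed=seed), X[tr], y[tr])
            full = sl.evaluate(y[te], model.predict_proba(X[te]))
            high = sl.high_confidence_eval(model, X[te], y[te], threshold=0.9)
            if high is not None:
                assert high.accuracy >= full.accuracy - 1e-9
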