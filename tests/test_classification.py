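import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold

from notesieve.classification import (CVResult, default_grid, fast_grid,
                                      grid_search, ncd_knn_classify,
                                      predict_proba, train, _make_estimator)
from notesieve.errors import FeatureSpaceError, TrainingError
from notesieve.representations import FeatureMatrix


def _separable_toy(n=20, rng=None):
    rng = rng or np.random.default_rng(0)
    X0 = rng.normal(loc=-2.0, scale=0.3, size=(n // 2, 2))
    X1 = rng.normal(loc=+2.0, scale=0.3, size=(n // 2, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


def _fm(X, tag="BOW"):
    return FeatureMatrix(row_ids=[str(i) for i in range(X.shape[0])],
                         columns=[f"c{i}" for i in range(X.shape[1])],
                         X=X, tag=tag)


class TestTrain:
    def test_rf_fits_separable_toy(self):
        X, y = _separable_toy()
        model = train("RF", _fm(X), y, {"n_estimators": 50}, seed=1)
        proba = predict_proba(model, _fm(X))
        assert np.mean((proba >= 0.5) == y) == 1.0

    def test_deterministic_under_seed(self):
        X, y = _separable_toy(40)
        p1 = predict_proba(train("RF", _fm(X), y, {"n_estimators": 50},
                                 seed=7), _fm(X))
        p2 = predict_proba(train("RF", _fm(X), y, {"n_estimators": 50},
                                 seed=7), _fm(X))
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_raises(self):
        X, _ = _separable_toy()
        with pytest.raises(TrainingError):
            train("RF", _fm(X), np.ones(X.shape[0], dtype=int))

    def test_gbt_and_knn_families(self):
        X, y = _separable_toy(30)
        for family, hp in (("GBT", {"n_estimators": 20}),
                           ("KNN", {"n_neighbors": 3})):
            model = train(family, _fm(X), y, hp, seed=1)
            proba = predict_proba(model, _fm(X))
            assert np.mean((proba >= 0.5) == y) == 1.0

    def test_save_load(self, tmp_path):
        from notesieve.classification import TrainedModel
        X, y = _separable_toy()
        model = train("RF", _fm(X), y, {"n_estimators": 10}, seed=1)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = TrainedModel.load(path)
        np.testing.assert_array_equal(predict_proba(loaded, _fm(X)),
                                      predict_proba(model, _fm(X)))


class TestPredictProba:
    def test_confident_deep_in_class(self):
        X, y = _separable_toy(40)
        model = train("RF", _fm(X), y, {"n_estimators": 100}, seed=1)
        proba = predict_proba(model, _fm(np.array([[2.0, 2.0]])))
        assert proba[0] > 0.9

    def test_bounded_and_binary_complement(self):
        X, y = _separable_toy(30)
        model = train("RF", _fm(X), y, {"n_estimators": 30}, seed=1)
        proba = predict_proba(model, _fm(X))
        assert np.all((proba >= 0) & (proba <= 1))
        full = model.estimator.predict_proba(X)
        np.testing.assert_allclose(full.sum(axis=1), 1.0)

    def test_knn_k1_probabilities_binary(self):
        X, y = _separable_toy(20)
        model = train("KNN", _fm(X), y, {"n_neighbors": 1}, seed=1)
        proba = predict_proba(model, _fm(X))
        assert set(np.unique(proba)).issubset({0.0, 1.0})

    def test_column_mismatch_raises(self):
        X, y = _separable_toy(20)
        model = train("RF", _fm(X), y, {"n_estimators": 10}, seed=1)
        with pytest.raises(FeatureSpaceError):
            predict_proba(model, _fm(np.zeros((3, 5))))


# --- independent cross-validation oracle --------------------------------

def cv_oracle(family, X, y, grid, folds, seed):
    """Explicit fold loops + hand-computed metrics; same split protocol."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    results = []
    for params in grid:
        f1s, recalls = [], []
        for tr, te in splits:
            est = _make_estimator(family, params, seed)
            est.fit(X[tr], y[tr])
            pred = est.predict(X[te])
            tp = np.sum((y[te] == 1) & (pred == 1))
            fp = np.sum((y[te] == 0) & (pred == 1))
            fn = np.sum((y[te] == 1) & (pred == 0))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
            recalls.append(rec)
        results.append((np.mean(f1s), np.mean(recalls)))
    best = 0
    for i in range(1, len(results)):
        if results[i] > results[best]:
            best = i
    return best, results


class TestGridSearch:
    def test_singleton_grid(self):
        X, y = _separable_toy(30)
        cv = grid_search("KNN", _fm(X), y, [{"n_neighbors": 3}], folds=5,
                         seed=2)
        assert cv.selected_params == {"n_neighbors": 3}
        assert len(cv.fold_scores[0]["f1"]) == 5
        for metric in ("f1", "precision", "recall", "specificity"):
            assert metric in cv.mean_scores[0]

    def test_matches_oracle_on_fixture(self, rng):
        X = rng.normal(size=(30, 3))
        y = (X[:, 0] + 0.3 * rng.normal(size=30) > 0).astype(int)
        grid = [{"n_neighbors": 1}, {"n_neighbors": 7}]
        cv = grid_search("KNN", _fm(X), y, grid, folds=5, seed=4)
        best, oracle_scores = cv_oracle("KNN", X, y, grid, folds=5, seed=4)
        assert cv.selected_index == best
        for i in range(len(grid)):
            assert cv.mean_scores[i]["f1"] == pytest.approx(
                oracle_scores[i][0])

    def test_noisy_labels_prefer_smoother_k(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(800 + seed)
            X = rng.normal(size=(200, 2))
            y = (X[:, 0] > 0).astype(int)
            flip = rng.random(200) < 0.2
            y = np.where(flip, 1 - y, y)
            cv = grid_search("KNN", _fm(X), y,
                             [{"n_neighbors": 1}, {"n_neighbors": 15}],
                             folds=5, seed=seed)
            wins += cv.selected_params["n_neighbors"] == 15
        assert wins >= 8

    def test_empty_grid_raises(self):
        X, y = _separable_toy(20)
        with pytest.raises(TrainingError):
            grid_search("KNN", _fm(X), y, [], folds=5, seed=1)

    def test_too_few_per_class_raises(self):
        X = np.zeros((6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(TrainingError):
            grid_search("KNN", _fm(X), y, [{"n_neighbors": 1}], folds=5,
                        seed=1)

    def test_grid_presets_cover_printed_ranges(self):
        rf = default_grid("RF")
        assert len(rf) == 5 * 4 * 3 * 3 * 2 * 2
        trees = {g["n_estimators"] for g in rf}
        assert trees == {100, 200, 300, 400, 500}
        depths = {g["max_depth"] for g in rf}
        assert depths == {10, 20, 30, None}
        ks = {g["n_neighbors"] for g in default_grid("KNN")}
        assert ks == set(range(1, 20, 2))
        assert 1 < len(fast_grid("RF")) <= 8


class TestNcdKnn:
    def _topic_docs(self, rng, n_per=25, length=60):
        va = [f"resp{i}" for i in range(20)]
        vb = [f"gen{i}" for i in range(20)]
        pos = [" ".join(rng.choice(va, length)) for _ in range(n_per)]
        neg = [" ".join(rng.choice(vb, length)) for _ in range(n_per)]
        return pos + neg, np.array([1] * n_per + [0] * n_per)

    def test_identical_positive_query_k1(self, rng):
        docs, y = self._topic_docs(rng, n_per=5)
        proba = ncd_knn_classify(docs, y, [docs[0]], k=1)
        assert proba[0] == 1.0

    def test_k_equals_train_size_gives_global_fraction(self, rng):
        docs, y = self._topic_docs(rng, n_per=5)
        proba = ncd_knn_classify(docs, y, ["anything at all", docs[3]],
                                 k=len(docs))
        np.testing.assert_allclose(proba, y.mean())

    def test_two_topic_heldout_accuracy(self):
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            docs, y = self._topic_docs(rng, n_per=25)
            idx = rng.permutation(len(docs))
            tr, te = idx[:40], idx[40:]
            proba = ncd_knn_classify([docs[i] for i in tr], y[tr],
                                     [docs[i] for i in te], k=5)
            accs.append(np.mean((proba >= 0.5) == y[te]))
        assert np.mean([a > 0.8 for a in accs]) >= 0.8

    def test_empty_training_raises(self):
        with pytest.raises(TrainingError):
            ncd_knn_classify([], np.array([]), ["x"], k=1)

    def test_k_too_large_raises(self):
        with pytest.raises(TrainingError):
            ncd_knn_classify(["a"], np.array([1]), ["x"], k=2)

    def test_grid_search_over_texts(self, rng):
        docs, y = self._topic_docs(rng, n_per=10)
        cv = grid_search("NCD_KNN", docs, y,
                         [{"n_neighbors": 1}, {"n_neighbors": 3}],
                         folds=5, seed=1)
        assert cv.selected_params["n_neighbors"] in (1, 3)
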