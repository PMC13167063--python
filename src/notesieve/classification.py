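"""Classifier families (RF, gradient-boosted trees, kNN, NCD-kNN), default
hyperparameter grids, and grid-search with stratified 5-fold CV.

Grid selection uses mean positive-class F1, ties broken by higher mean
recall, then by grid order. All four confusion metrics are recorded per
fold and candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .errors import FeatureSpaceError, TrainingError
from .representations.compression import ncd_distance_matrix
from .representations.matrix import FeatureMatrix

__all__ = ["FAMILIES", "TrainedModel", "CVResult", "train", "predict_proba",
           "grid_search", "ncd_knn_classify", "default_grid", "fast_grid"]

FAMILIES = ("RF", "GBT", "KNN", "NCD_KNN")


# --- hyperparameter grids ----------------------------------------------

def _expand(axes: dict[str, list]) -> list[dict]:
    """Cartesian product preserving axis order (first axis slowest)."""
    grid = [{}]
    for name, values in axes.items():
        grid = [dict(g, **{name: v}) for g in grid for v in values]
    return grid


_DEFAULT_AXES = {
    "RF": {
        "n_estimators": [100, 200, 300, 400, 500],
        "max_depth": [10, 20, 30, None],
        "min_samples_split": [2, 5, 10],
        "min_samples_leaf": [1, 2, 4],
        "max_features": ["sqrt", "log2"],
        "class_weight": [None, "balanced"],
    },
    "GBT": {
        "learning_rate": [0.01, 0.05, 0.1, 0.3],
        "n_estimators": [100, 300, 500, 1000],
        "max_depth": [3, 6, 10],
        "min_samples_leaf": [1, 3, 6],
        "subsample": [0.5, 0.75, 1.0],
        "max_features": [0.5, 0.75, 1.0],
    },
    "KNN": {
        "n_neighbors": [1, 3, 5, 7, 9, 11, 13, 15, 17, 19],
        "weights": ["uniform", "distance"],
        "metric": ["euclidean", "manhattan", "minkowski3"],
        "leaf_size": [10, 30, 50],
    },
    "NCD_KNN": {
        "n_neighbors": [1, 3, 5, 7, 9, 11, 13, 15, 17, 19],
    },
}

# compact preset for CI / desk-scale runs
_FAST_AXES = {
    "RF": {
        "n_estimators": [100, 200],
        "max_depth": [10, None],
        "class_weight": [None, "balanced"],
    },
    "GBT": {
        "learning_rate": [0.1, 0.3],
        "n_estimators": [100, 200],
        "max_depth": [3, 6],
    },
    "KNN": {
        "n_neighbors": [5, 15],
        "weights": ["uniform", "distance"],
        "metric": ["euclidean", "manhattan"],
    },
    "NCD_KNN": {
        "n_neighbors": [5, 15],
    },
}


def default_grid(family: str) -> list[dict]:
    return _expand(_DEFAULT_AXES[family])


def fast_grid(family: str) -> list[dict]:
    return _expand(_FAST_AXES[family])


# --- training -----------------------------------------------------------

@dataclass
class TrainedModel:
    family: str
    estimator: object  # sklearn estimator, or (texts, labels, k) for NCD_KNN
    hyperparams: dict
    representation_tag: str
    seed: int
    n_features: int

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        return joblib.load(path)


def _make_estimator(family: str, hyperparams: dict, seed: int):
    params = dict(hyperparams)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "GBT":
        return GradientBoostingClassifier(random_state=seed, **params)
    if family == "KNN":
        metric = params.pop("metric", "euclidean")
        if metric == "minkowski3":
            params.update(metric="minkowski", p=3)
        else:
            params.update(metric=metric)
        return KNeighborsClassifier(**params)
    raise ValueError(f"unknown family {family!r}")


def _as_array(features) -> np.ndarray | object:
    if isinstance(features, FeatureMatrix):
        return features.X
    return features


def train(family: str, features, labels, hyperparams: dict | None = None,
          seed: int = 0) -> TrainedModel:
    """Fit one model. ``features`` is a FeatureMatrix (or array) for
    RF/GBT/KNN, or a list of raw texts for NCD_KNN."""
    hyperparams = dict(hyperparams or {})
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    tag = features.tag if isinstance(features, FeatureMatrix) else "COMP"
    if family == "NCD_KNN":
        texts = list(features)
        if len(texts) != len(y):
            raise TrainingError("texts and labels misaligned")
        k = int(hyperparams.get("n_neighbors", 5))
        if k > len(texts):
            raise TrainingError("k exceeds training-set size")
        return TrainedModel(family, (texts, y, k), hyperparams, "COMP",
                            seed, n_features=0)
    X = _as_array(features)
    if X.shape[0] != len(y):
        raise TrainingError("features and labels misaligned")
    est = _make_estimator(family, hyperparams, seed)
    est.fit(X, y)
    return TrainedModel(family, est, hyperparams, tag, seed,
                        n_features=X.shape[1])


def predict_proba(model: TrainedModel, features) -> np.ndarray:
    """Positive-class probability per document, in [0, 1]."""
    if model.family == "NCD_KNN":
        texts, labels, k = model.estimator
        return ncd_knn_classify(texts, labels, list(features), k)
    X = _as_array(features)
    if X.shape[1] != model.n_features:
        raise FeatureSpaceError(
            f"expected {model.n_features} features, got {X.shape[1]}")
    proba = model.estimator.predict_proba(X)
    pos_col = int(np.where(model.estimator.classes_ == 1)[0][0])
    return proba[:, pos_col]


def ncd_knn_classify(train_texts: list[str], train_labels, query_texts,
                     k: int) -> np.ndarray:
    """kNN over NCD distances with uniform weights.

    Probability = positive fraction among the k nearest references; ties in
    distance resolved by reference order (stable sort).
    """
    labels = np.asarray(train_labels)
    if len(train_texts) == 0:
        raise TrainingError("empty NCD-kNN training set")
    if k > len(train_texts):
        raise TrainingError("k exceeds training-set size")
    D = ncd_distance_matrix(list(query_texts), train_texts)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    return labels[order].mean(axis=1)


# --- grid search --------------------------------------------------------

@dataclass
class CVResult:
    """Per-candidate, per-fold CV scores and the selected candidate."""

    grid: list[dict]
    fold_scores: list[dict[str, list[float]]]  # per candidate
    mean_scores: list[dict[str, float]]
    selected_index: int
    selection_metric: str = "f1"
    folds: int = 5
    seed: int = 0

    @property
    def selected_params(self) -> dict:
        return self.grid[self.selected_index]


def _fold_metrics(y_true, y_pred) -> dict[str, float]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"f1": f1, "precision": precision, "recall": recall,
            "specificity": specificity}


def grid_search(family: str, features, labels, grid: list[dict],
                folds: int = 5, seed: int = 0) -> CVResult:
    """Stratified k-fold grid search selecting max mean F1 (ties: higher
    mean recall, then first grid entry)."""
    if not grid:
        raise TrainingError("empty hyperparameter grid")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise TrainingError("grid search needs both classes present")
    counts = np.bincount(y)
    if counts[counts > 0].min() < folds:
        raise TrainingError(
            f"need >= {folds} samples per class for {folds}-fold CV")

    is_text = family == "NCD_KNN"
    X = list(features) if is_text else _as_array(features)
    tag = features.tag if isinstance(features, FeatureMatrix) else "COMP"

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))

    fold_scores: list[dict[str, list[float]]] = []
    mean_scores: list[dict[str, float]] = []
    for params in grid:
        scores: dict[str, list[float]] = {m: [] for m in
                                          ("f1", "precision", "recall",
                                           "specificity")}
        for train_idx, test_idx in splits:
            if is_text:
                tr_texts = [X[i] for i in train_idx]
                te_texts = [X[i] for i in test_idx]
                k = min(int(params.get("n_neighbors", 5)), len(tr_texts))
                proba = ncd_knn_classify(tr_texts, y[train_idx], te_texts, k)
                pred = (proba >= 0.5).astype(int)
            else:
                est = _make_estimator(family, params, seed)
                Xtr = X[train_idx]
                est.fit(Xtr, y[train_idx])
                pred = est.predict(X[test_idx])
            m = _fold_metrics(y[test_idx], pred)
            for name, value in m.items():
                scores[name].append(value)
        fold_scores.append(scores)
        mean_scores.append({name: float(np.mean(vals))
                            for name, vals in scores.items()})

    best = 0
    for i in range(1, len(grid)):
        a, b = mean_scores[i], mean_scores[best]
        if (a["f1"], a["recall"]) > (b["f1"], b["recall"]):
            best = i
    # FeatureMatrix tag recorded implicitly via caller's subsequent train()
    _ = tag
    return CVResult(grid=grid, fold_scores=fold_scores,
                    mean_scores=mean_scores, selected_index=best,
                    folds=folds, seed=seed)
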