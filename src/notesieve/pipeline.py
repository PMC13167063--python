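"""End-to-end experiment orchestration.

One run = label silver pools -> sample a balanced training subset ->
featurize -> grid-search/train -> calibrate the decision threshold on the
gold validation split -> evaluate on the gold test split with bootstrap
CIs. The report is a plain JSON-serializable dict carrying the resolved
configuration, seeds, input digests and library versions, and is
byte-identical across reruns with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import classification as clf
from . import evaluation as ev
from .corpus_model import CodeSet, Corpus, read_corpus
from .errors import ConfigError, NoteSieveError
from .representations import (BowModel, TfidfModel, EmbeddingParams,
                              compression_features, concept_vectorize,
                              default_lexicon, embed_documents, load_lexicon,
                              train_embedding)
from .silver_labeling import (Pool, SubsetConfig, build_pools, read_gold_csv,
                              sample_training_subset, split_gold)

__all__ = ["RunConfig", "run_experiment", "compare_runs"]

log = logging.getLogger("notesieve")

REPRESENTATIONS = ("bow", "tfidf", "emb", "comp", "concept")
FAMILY_BY_NAME = {"rf": "RF", "gbt": "GBT", "xgb": "GBT", "knn": "KNN",
                  "ncd_knn": "NCD_KNN"}


@dataclass
class RunConfig:
    corpus_path: str
    gold_path: str
    codeset_path: str | None = None
    lexicon_path: str | None = None
    representation: str = "bow"
    family: str = "rf"
    grid: str = "fast"  # "fast" | "default"
    subset_name: str = "MIXED"
    n_pos: int = 100
    validation_n: int | None = None  # default: ~84/307 of the gold set
    lookback_months: int = 24
    negatives_scope: str = "patient"
    min_df: int = 2
    folds: int = 5
    bootstrap_iterations: int = 1000
    min_recall: float | None = None
    embedding: dict = field(default_factory=dict)
    sampling_seed: int = 13
    training_seed: int = 7
    bootstrap_seed: int = 11
    split_seed: int = 5

    def __post_init__(self):
        if self.representation not in REPRESENTATIONS:
            raise ConfigError(
                f"unknown representation {self.representation!r}; "
                f"choose from {REPRESENTATIONS}")
        if self.family not in FAMILY_BY_NAME:
            raise ConfigError(f"unknown classifier family {self.family!r}")
        if self.family == "ncd_knn" and self.representation != "comp":
            raise ConfigError(
                "ncd_knn operates on raw text; set representation='comp'")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml
            obj = yaml.safe_load(text)
        else:
            obj = json.loads(text)
        return cls(**obj)

    def validate_paths(self) -> None:
        for name in ("corpus_path", "gold_path", "codeset_path",
                     "lexicon_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{name} does not exist: {value}")
        if self.representation == "concept" and self.lexicon_path is not None \
                and not Path(self.lexicon_path).exists():
            raise ConfigError(f"missing lexicon: {self.lexicon_path}")


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _versions() -> dict[str, str]:
    import sklearn
    import scipy
    from . import __version__
    return {"python": sys.version.split()[0], "numpy": np.__version__,
            "scipy": scipy.__version__, "sklearn": sklearn.__version__,
            "notesieve": __version__}


class _Featurizer:
    """Fits on training texts, then maps any text list to model inputs."""

    def __init__(self, config: RunConfig):
        self.config = config
        self._model = None
        self._lexicon = None

    def fit(self, texts: list[str], ids: list[str]):
        c = self.config
        if c.representation == "bow":
            self._model = BowModel(min_df=c.min_df)
            return self._model.fit(texts, ids)
        if c.representation == "tfidf":
            self._model = TfidfModel(min_df=c.min_df)
            return self._model.fit(texts, ids)
        if c.representation == "emb":
            params = EmbeddingParams(seed=c.training_seed, **c.embedding)
            self._model = train_embedding(texts, params, doc_ids=ids)
            return embed_documents(self._model, texts, ids)
        if c.representation == "concept":
            self._lexicon = (load_lexicon(c.lexicon_path)
                             if c.lexicon_path else default_lexicon())
            return concept_vectorize(texts, self._lexicon, row_ids=ids)
        if c.family == "ncd_knn":
            return texts  # raw text is the model input
        return compression_features(texts, row_ids=ids)

    def transform(self, texts: list[str], ids: list[str]):
        c = self.config
        if c.representation in ("bow", "tfidf"):
            return self._model.transform(texts, ids)
        if c.representation == "emb":
            return embed_documents(self._model, texts, ids)
        if c.representation == "concept":
            return concept_vectorize(texts, self._lexicon, row_ids=ids)
        if c.family == "ncd_knn":
            return texts
        return compression_features(texts, row_ids=ids)


def _subset_config(config: RunConfig) -> SubsetConfig:
    builders = {"MIXED": SubsetConfig.mixed, "NON_ONLY": SubsetConfig.non_only,
                "PRE_ONLY": SubsetConfig.pre_only}
    try:
        builder = builders[config.subset_name]
    except KeyError:
        raise ConfigError(f"unknown subset name {config.subset_name!r}")
    return builder(config.n_pos, config.sampling_seed)


def run_experiment(config: RunConfig, corpus: Corpus | None = None) -> dict:
    """Execute the full pipeline and return the report dict."""
    t0 = time.monotonic()
    config.validate_paths()
    codeset = (CodeSet.from_json(config.codeset_path)
               if config.codeset_path else CodeSet.default_copd())
    if corpus is None:
        corpus = read_corpus(config.corpus_path)
    log.info("stage=load notes=%d", len(corpus))

    pool_by_note, pool_report = build_pools(
        corpus, codeset, config.lookback_months, config.negatives_scope)
    log.info("stage=label pools=%s", pool_report)

    subset = sample_training_subset(corpus, pool_by_note,
                                    _subset_config(config))
    train_texts = [d.text for d in subset]
    train_ids = [d.note_id for d in subset]
    y_train = np.array([d.label for d in subset])

    gold = read_gold_csv(config.gold_path)
    validation_n = config.validation_n
    if validation_n is None:
        validation_n = max(1, round(len(gold) * 84 / 307))
    val, test = split_gold(gold, validation_n, config.split_seed,
                           pool_by_note)
    log.info("stage=split validation=%d test=%d", len(val), len(test))

    featurizer = _Featurizer(config)
    X_train = featurizer.fit(train_texts, train_ids)
    val_texts = [corpus.notes[i].text for i, _ in val]
    test_texts = [corpus.notes[i].text for i, _ in test]
    X_val = featurizer.transform(val_texts, [i for i, _ in val])
    X_test = featurizer.transform(test_texts, [i for i, _ in test])
    log.info("stage=featurize representation=%s", config.representation)

    family = FAMILY_BY_NAME[config.family]
    grid = (clf.fast_grid(family) if config.grid == "fast"
            else clf.default_grid(family))
    cv = clf.grid_search(family, X_train, y_train, grid,
                         folds=config.folds, seed=config.training_seed)
    model = clf.train(family, X_train, y_train, cv.selected_params,
                      seed=config.training_seed)
    log.info("stage=train family=%s selected=%s", family, cv.selected_params)

    y_val = np.array([label for _, label in val])
    proba_val = clf.predict_proba(model, X_val)
    table = ev.threshold_sweep(proba_val, y_val)
    threshold = ev.select_threshold(table, min_recall=config.min_recall)
    log.info("stage=calibrate threshold=%.1f", threshold)

    y_test = np.array([label for _, label in test])
    proba_test = clf.predict_proba(model, X_test)
    pred_test = (proba_test >= threshold).astype(int)
    cm = ev.confusion(y_test, pred_test)
    metrics = ev.compute_metrics(cm)
    ci = ev.bootstrap_ci(y_test, pred_test, "f1",
                         iterations=config.bootstrap_iterations,
                         seed=config.bootstrap_seed)

    baseline_cm, baseline_metrics, baseline_ci = ev.evaluate_baseline(
        pool_by_note, test, iterations=config.bootstrap_iterations,
        seed=config.bootstrap_seed)
    log.info("stage=evaluate f1=%.3f baseline_f1=%.3f wall=%.1fs",
             metrics.f1, baseline_metrics.f1, time.monotonic() - t0)

    report = {
        "config": asdict(config),
        "pools": pool_report,
        "subset": {"n": len(subset), "n_pos": int(y_train.sum()),
                   "n_neg": int((1 - y_train).sum())},
        "gold": {"n_validation": len(val), "n_test": len(test),
                 "digest": _digest(config.gold_path)},
        "cv": {"selected": cv.selected_params,
               "mean_scores": cv.mean_scores[cv.selected_index],
               "n_candidates": len(cv.grid)},
        "threshold": {"selected": threshold, "table": table.rows()},
        "test": {"confusion": cm.as_dict(), "metrics": metrics.as_dict(),
                 "f1_ci": ci.as_dict()},
        "baseline": {"confusion": baseline_cm.as_dict(),
                     "metrics": baseline_metrics.as_dict(),
                     "f1_ci": baseline_ci.as_dict()},
        "manifest": {
            "seeds": {"sampling": config.sampling_seed,
                      "training": config.training_seed,
                      "bootstrap": config.bootstrap_seed,
                      "split": config.split_seed},
            "digests": {"corpus": _digest(config.corpus_path),
                        "gold": _digest(config.gold_path)},
            "versions": _versions(),
        },
    }
    return report


def compare_runs(reports: list[dict]) -> list[dict]:
    """Representation x family comparison table from run reports,
    sorted by test F1 (descending). Gold sets must match."""
    if len(reports) < 2:
        raise NoteSieveError("compare_runs needs at least 2 reports")
    digests = {r["gold"]["digest"] for r in reports}
    if len(digests) != 1:
        raise NoteSieveError(
            "reports evaluate different gold sets; comparison is invalid")
    rows = []
    for r in reports:
        m = r["test"]["metrics"]
        rows.append({
            "representation": r["config"]["representation"],
            "family": r["config"]["family"],
            "precision": m["precision"], "recall": m["recall"],
            "specificity": m["specificity"], "f1": m["f1"],
            "f1_ci": [r["test"]["f1_ci"]["lower"],
                      r["test"]["f1_ci"]["upper"]],
            "threshold": r["threshold"]["selected"],
        })
    rows.sort(key=lambda x: -x["f1"])
    return rows


def write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
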