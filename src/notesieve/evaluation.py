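"""Confusion-matrix metrics, threshold sweep and selection, percentile
bootstrap confidence intervals, and the ICD-heuristic baseline evaluation.

Conventions:

* prediction rule is ``probability >= threshold`` (so threshold 0.0 is the
  all-positive row of the sweep);
* zero-denominator metrics return 0.0 with an explicit undefined flag
  rather than raising;
* bootstrap CIs are plain 2.5/97.5 percentile intervals over document-level
  resamples (1000 iterations by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NoteSieveError
from .silver_labeling import Pool

__all__ = ["ConfusionMatrix", "MetricSet", "ThresholdTable", "BootstrapCI",
           "confusion", "compute_metrics", "threshold_sweep",
           "select_threshold", "bootstrap_ci", "evaluate_baseline",
           "THRESHOLDS"]

THRESHOLDS = tuple(round(t / 10, 1) for t in range(11))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


@dataclass
class MetricSet:
    precision: float
    recall: float
    specificity: float
    f1: float
    undefined: set[str] = field(default_factory=set)

    def rounded(self, digits: int = 2) -> dict[str, float]:
        return {k: round(getattr(self, k), digits)
                for k in ("precision", "recall", "specificity", "f1")}

    def as_dict(self) -> dict:
        out = {k: getattr(self, k)
               for k in ("precision", "recall", "specificity", "f1")}
        out["undefined"] = sorted(self.undefined)
        return out


def confusion(gold_labels, predicted_labels) -> ConfusionMatrix:
    """Count tp/fp/fn/tn over aligned binary label sequences (1=relevant)."""
    gold = np.asarray(gold_labels)
    pred = np.asarray(predicted_labels)
    if gold.shape != pred.shape:
        raise NoteSieveError(
            f"label lists differ in length: {gold.shape} vs {pred.shape}")
    return ConfusionMatrix(
        tp=int(np.sum((gold == 1) & (pred == 1))),
        fp=int(np.sum((gold == 0) & (pred == 1))),
        fn=int(np.sum((gold == 1) & (pred == 0))),
        tn=int(np.sum((gold == 0) & (pred == 0))),
    )


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Precision, recall, specificity and F1 for the positive class."""
    undefined: set[str] = set()

    def ratio(num, den, name):
        if den == 0:
            undefined.add(name)
            return 0.0
        return num / den

    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    specificity = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    if "precision" in undefined and "recall" in undefined:
        undefined.add("f1")
        f1 = 0.0
    elif precision + recall == 0:
        undefined.add("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(precision=precision, recall=recall,
                     specificity=specificity, f1=f1, undefined=undefined)


@dataclass
class ThresholdTable:
    thresholds: tuple[float, ...]
    metrics: list[MetricSet]
    confusions: list[ConfusionMatrix]
    selected: float | None = None

    def rows(self) -> list[dict]:
        out = []
        for t, m, cm in zip(self.thresholds, self.metrics, self.confusions):
            row = {"threshold": t, **m.as_dict(), "confusion": cm.as_dict()}
            out.append(row)
        return out


def threshold_sweep(probabilities, gold_labels) -> ThresholdTable:
    """Evaluate predict-relevant-iff-p>=t at t in {0.0, 0.1, ..., 1.0}."""
    p = np.asarray(probabilities, dtype=float)
    gold = np.asarray(gold_labels)
    if p.shape != gold.shape:
        raise NoteSieveError("probabilities and labels misaligned")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise NoteSieveError("probabilities must lie in [0, 1]")
    metrics, cms = [], []
    for t in THRESHOLDS:
        pred = (p >= t).astype(int)
        cm = confusion(gold, pred)
        cms.append(cm)
        metrics.append(compute_metrics(cm))
    return ThresholdTable(thresholds=THRESHOLDS, metrics=metrics,
                          confusions=cms)


def select_threshold(table: ThresholdTable, min_recall: float | None = None
                     ) -> float:
    """Argmax F1; ties broken by higher recall, then lower threshold.

    With ``min_recall`` set, only rows meeting it compete (falling back to
    the unconstrained rule if none does).
    """
    if not table.metrics:
        raise NoteSieveError("empty threshold table")

    def pick(rows):
        best_t, best_key = None, None
        for t, m in rows:
            key = (m.f1, m.recall, -t)
            if best_key is None or key > best_key:
                best_t, best_key = t, key
        return best_t

    rows = list(zip(table.thresholds, table.metrics))
    if min_recall is not None:
        eligible = [r for r in rows if r[1].recall >= min_recall]
        if eligible:
            rows = eligible
    selected = pick(rows)
    table.selected = selected
    return selected


@dataclass
class BootstrapCI:
    statistic: str
    point: float
    lower: float
    upper: float
    iterations: int
    seed: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {"statistic": self.statistic, "point": self.point,
                "lower": self.lower, "upper": self.upper,
                "iterations": self.iterations, "seed": self.seed,
                "degenerate": self.degenerate}


def bootstrap_ci(gold_labels, predicted_labels, statistic: str = "f1",
                 iterations: int = 1000, seed: int = 0) -> BootstrapCI:
    """Percentile bootstrap CI for a confusion-matrix statistic.

    Documents are resampled with replacement; the 2.5th/97.5th percentiles
    of the replicate statistics form the interval. A degenerate flag is set
    when the statistic is undefined in more than half of replicates.
    """
    if iterations < 1:
        raise NoteSieveError("iterations must be >= 1")
    gold = np.asarray(gold_labels)
    pred = np.asarray(predicted_labels)
    if gold.shape != pred.shape or gold.size == 0:
        raise NoteSieveError("need non-empty aligned label lists")
    point = getattr(compute_metrics(confusion(gold, pred)), statistic)
    rng = np.random.default_rng(seed)
    n = gold.size
    values = np.empty(iterations)
    undefined = 0
    for i in range(iterations):
        idx = rng.integers(0, n, n)
        m = compute_metrics(confusion(gold[idx], pred[idx]))
        if statistic in m.undefined:
            undefined += 1
        values[i] = getattr(m, statistic)
    lower, upper = np.percentile(values, [2.5, 97.5])
    return BootstrapCI(statistic=statistic, point=float(point),
                       lower=float(lower), upper=float(upper),
                       iterations=iterations, seed=seed,
                       degenerate=undefined > iterations / 2)


def evaluate_baseline(pool_by_note, gold_annotations,
                      iterations: int = 1000, seed: int = 0
                      ) -> tuple[ConfusionMatrix, MetricSet, BootstrapCI]:
    """Evaluate the code-heuristic baseline on a gold set.

    The baseline predicts relevant iff the note sits in the positive
    (code-bearing) pool. ``gold_annotations`` is a list of
    ``(note_id, label)`` pairs; every note must have a pool assignment.
    """
    gold, pred = [], []
    for note_id, label in gold_annotations:
        pool = pool_by_note.get(note_id)
        if pool is None:
            raise NoteSieveError(
                f"gold note {note_id!r} has no pool assignment")
        gold.append(label)
        pred.append(1 if pool is Pool.COPD_ENCOUNTER else 0)
    cm = confusion(gold, pred)
    metrics = compute_metrics(cm)
    ci = bootstrap_ci(gold, pred, "f1", iterations=iterations, seed=seed)
    return cm, metrics, ci
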