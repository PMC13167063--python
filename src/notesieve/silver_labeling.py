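"""Weak-supervision heuristics: silver pools, training subsets, gold split.

Every note in a corpus lands in exactly one of four pools:

* ``COPD_ENCOUNTER`` — the note's encounter carries a target diagnosis code
  (silver positive);
* ``NON_COPD`` — no target code in scope (silver negative; scope is
  patient-level by default, see ``negatives_scope``);
* ``PRE_COPD`` — the note predates the patient's first target-coded
  encounter by at least ``lookback_months`` calendar months (silver
  negative);
* ``EXCLUDED`` — uncoded note inside the pre-diagnosis gray zone or after
  diagnosis; never used as a silver label.
"""

from __future__ import annotations

import calendar
import csv
import datetime as _dt
import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .corpus_model import ClinicalNote, CodeSet, Corpus, Patient
from .errors import (
    ConsistencyError,
    ReferentialIntegrityError,
    SamplingError,
)

__all__ = [
    "Pool",
    "SubsetConfig",
    "LabeledDocument",
    "shift_months",
    "assign_pool",
    "build_pools",
    "sample_training_subset",
    "split_gold",
    "write_pools",
    "read_pools",
    "read_gold_csv",
    "write_gold_csv",
]


class Pool(str, Enum):
    COPD_ENCOUNTER = "COPD_ENCOUNTER"
    NON_COPD = "NON_COPD"
    PRE_COPD = "PRE_COPD"
    EXCLUDED = "EXCLUDED"


#: silver label carried by each pool (1 positive, 0 negative, None unused)
POOL_LABELS = {
    Pool.COPD_ENCOUNTER: 1,
    Pool.NON_COPD: 0,
    Pool.PRE_COPD: 0,
    Pool.EXCLUDED: None,
}


def shift_months(date: _dt.date, months: int) -> _dt.date:
    """Shift a date by whole calendar months, clamping the day of month."""
    total = date.year * 12 + (date.month - 1) + months
    year, month = divmod(total, 12)
    month += 1
    day = min(date.day, calendar.monthrange(year, month)[1])
    return _dt.date(year, month, day)


def assign_pool(
    note: ClinicalNote,
    patient: Patient,
    codeset: CodeSet,
    lookback_months: int = 24,
    negatives_scope: str = "patient",
) -> Pool:
    """Assign a single note to its silver pool.

    ``negatives_scope='patient'`` (default) only admits NON_COPD notes from
    patients with no target code anywhere; ``'encounter'`` admits any
    uncoded encounter outside the pre-diagnosis window.
    """
    if note.patient_id != patient.patient_id:
        raise ConsistencyError(
            f"note {note.note_id!r} belongs to patient {note.patient_id!r}, "
            f"not {patient.patient_id!r}")
    encounter = next(
        (e for e in patient.encounters if e.encounter_id == note.encounter_id),
        None)
    if encounter is None:
        raise ConsistencyError(
            f"note {note.note_id!r} references encounter "
            f"{note.encounter_id!r} not attached to its patient")
    if encounter.has_target_code(codeset):
        return Pool.COPD_ENCOUNTER
    first = patient.first_target_date(codeset)
    if first is None:
        return Pool.NON_COPD
    # boundary inclusive: "lookback months or more prior"
    if note.date <= shift_months(first, -lookback_months):
        return Pool.PRE_COPD
    if negatives_scope == "encounter":
        return Pool.NON_COPD
    return Pool.EXCLUDED


def build_pools(
    corpus: Corpus,
    codeset: CodeSet,
    lookback_months: int = 24,
    negatives_scope: str = "patient",
) -> tuple[dict[str, Pool], dict[str, int]]:
    """Partition every note into a pool.

    Returns ``(pool_by_note, report)`` where report maps pool name to count.
    The partition is disjoint and exhaustive by construction.
    """
    pool_by_note: dict[str, Pool] = {}
    for note in corpus.notes.values():
        patient = corpus.patients[note.patient_id]
        pool_by_note[note.note_id] = assign_pool(
            note, patient, codeset, lookback_months, negatives_scope)
    report = Counter(p.value for p in pool_by_note.values())
    for pool in Pool:
        report.setdefault(pool.value, 0)
    return pool_by_note, dict(report)


@dataclass
class SubsetConfig:
    """Balanced training-subset configuration.

    Invariant: ``n_pos == n_neg_non + n_neg_pre``.
    """

    name: str
    n_pos: int
    n_neg_non: int
    n_neg_pre: int
    seed: int

    def __post_init__(self):
        if self.name not in ("MIXED", "NON_ONLY", "PRE_ONLY"):
            raise ValueError(f"unknown subset config name {self.name!r}")
        if self.n_pos != self.n_neg_non + self.n_neg_pre:
            raise ValueError("subset must be balanced: "
                             "n_pos == n_neg_non + n_neg_pre")
        if self.name == "NON_ONLY" and self.n_neg_pre != 0:
            raise ValueError("NON_ONLY requires n_neg_pre == 0")
        if self.name == "PRE_ONLY" and self.n_neg_non != 0:
            raise ValueError("PRE_ONLY requires n_neg_non == 0")
        if self.name == "MIXED" and self.n_neg_non != self.n_neg_pre:
            raise ValueError("MIXED requires equal halves of negatives")

    @classmethod
    def mixed(cls, n_pos: int, seed: int) -> "SubsetConfig":
        if n_pos % 2:
            raise ValueError("MIXED needs an even n_pos")
        return cls("MIXED", n_pos, n_pos // 2, n_pos // 2, seed)

    @classmethod
    def non_only(cls, n_pos: int, seed: int) -> "SubsetConfig":
        return cls("NON_ONLY", n_pos, n_pos, 0, seed)

    @classmethod
    def pre_only(cls, n_pos: int, seed: int) -> "SubsetConfig":
        return cls("PRE_ONLY", n_pos, 0, n_pos, seed)


@dataclass
class LabeledDocument:
    note_id: str
    text: str
    label: int  # 1 relevant / 0 irrelevant
    provenance: str  # "silver:<POOL>" or "gold"


def _stratified_draw(
    notes: list[ClinicalNote],
    n: int,
    rng: np.random.Generator,
    patient_cap: int,
    patient_counts: dict[str, int],
    pool_name: str,
) -> list[ClinicalNote]:
    """Draw n notes without replacement, proportionally across
    (calendar year, note_type) strata with largest-remainder rounding,
    honoring a global per-patient cap where feasible."""
    if len(notes) < n:
        raise SamplingError(
            f"pool {pool_name} holds {len(notes)} notes, {n} requested")
    strata: dict[tuple[int, str], list[ClinicalNote]] = defaultdict(list)
    for note in sorted(notes, key=lambda x: x.note_id):
        strata[(note.date.year, note.note_type)].append(note)
    keys = sorted(strata)
    sizes = np.array([len(strata[k]) for k in keys], dtype=float)
    quotas = sizes / sizes.sum() * n
    alloc = np.floor(quotas).astype(int)
    remainder = n - alloc.sum()
    if remainder > 0:
        order = np.argsort(-(quotas - alloc), kind="stable")
        for idx in order[:remainder]:
            alloc[idx] += 1
    # never allocate more than a stratum holds; spill goes to the fill pass
    alloc = np.minimum(alloc, sizes.astype(int))

    chosen: list[ClinicalNote] = []
    leftovers: list[ClinicalNote] = []
    for key, take in zip(keys, alloc):
        members = strata[key]
        perm = rng.permutation(len(members))
        got = 0
        for i in perm:
            note = members[i]
            if got < take and patient_counts[note.patient_id] < patient_cap:
                chosen.append(note)
                patient_counts[note.patient_id] += 1
                got += 1
            else:
                leftovers.append(note)
    # fill any shortfall (cap collisions / stratum exhaustion)
    if len(chosen) < n:
        perm = rng.permutation(len(leftovers))
        for i in perm:
            if len(chosen) >= n:
                break
            note = leftovers[i]
            if patient_counts[note.patient_id] < patient_cap:
                chosen.append(note)
                patient_counts[note.patient_id] += 1
        if len(chosen) < n:  # cap infeasible: relax it rather than fail
            taken = {x.note_id for x in chosen}
            for i in perm:
                if len(chosen) >= n:
                    break
                note = leftovers[i]
                if note.note_id not in taken:
                    chosen.append(note)
                    patient_counts[note.patient_id] += 1
    return chosen


def sample_training_subset(
    corpus: Corpus,
    pool_by_note: dict[str, Pool],
    config: SubsetConfig,
) -> list[LabeledDocument]:
    """Sample a balanced silver training subset, deterministically.

    At most ``ceil(n_total/20)`` notes per patient; draws are stratified
    over calendar year x note type with largest-remainder allocation.
    """
    rng = np.random.default_rng(config.seed)
    by_pool: dict[Pool, list[ClinicalNote]] = defaultdict(list)
    for note_id, pool in pool_by_note.items():
        by_pool[pool].append(corpus.notes[note_id])

    n_total = config.n_pos + config.n_neg_non + config.n_neg_pre
    cap = max(1, math.ceil(n_total / 20))
    patient_counts: dict[str, int] = defaultdict(int)

    requests = [(Pool.COPD_ENCOUNTER, config.n_pos)]
    if config.n_neg_non:
        requests.append((Pool.NON_COPD, config.n_neg_non))
    if config.n_neg_pre:
        requests.append((Pool.PRE_COPD, config.n_neg_pre))

    docs: list[LabeledDocument] = []
    for pool, count in requests:
        picked = _stratified_draw(
            by_pool.get(pool, []), count, rng, cap, patient_counts, pool.value)
        label = POOL_LABELS[pool]
        docs.extend(
            LabeledDocument(n.note_id, n.text, label, f"silver:{pool.value}")
            for n in picked)
    return docs


def split_gold(
    annotations: list[tuple[str, int]],
    validation_n: int,
    seed: int,
    pool_by_note: dict[str, Pool] | None = None,
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Split gold annotations into (validation, test), stratified by
    pool-of-origin when a pool map is supplied.

    Deterministic under ``seed``; duplicate or unresolvable note ids raise
    :class:`ReferentialIntegrityError`.
    """
    ids = [a[0] for a in annotations]
    dupes = [i for i, c in Counter(ids).items() if c > 1]
    if dupes:
        raise ReferentialIntegrityError(
            f"duplicate note ids in annotations: {dupes[:5]}")
    if pool_by_note is not None:
        unknown = [i for i in ids if i not in pool_by_note]
        if unknown:
            raise ReferentialIntegrityError(
                f"annotated notes missing from corpus pools: {unknown[:5]}")
    if not 0 <= validation_n <= len(annotations):
        raise ValueError("validation_n out of range")

    rng = np.random.default_rng(seed)
    strata: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for ann in annotations:
        key = pool_by_note[ann[0]].value if pool_by_note else "all"
        strata[key].append(ann)
    keys = sorted(strata)
    sizes = np.array([len(strata[k]) for k in keys], dtype=float)
    quotas = sizes / sizes.sum() * validation_n
    alloc = np.floor(quotas).astype(int)
    short = validation_n - alloc.sum()
    if short > 0:
        order = np.argsort(-(quotas - alloc), kind="stable")
        for idx in order[:short]:
            alloc[idx] += 1
    validation: list[tuple[str, int]] = []
    test: list[tuple[str, int]] = []
    for key, take in zip(keys, alloc):
        members = sorted(strata[key])
        perm = rng.permutation(len(members))
        val_idx = set(perm[: int(take)])
        for i, ann in enumerate(members):
            (validation if i in val_idx else test).append(ann)
    return validation, test


# --- file formats -------------------------------------------------------

def write_pools(pool_by_note: dict[str, Pool], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for note_id in pool_by_note:
            pool = pool_by_note[note_id]
            label = POOL_LABELS[pool]
            fh.write(json.dumps(
                {"note_id": note_id, "pool": pool.value,
                 "label": {1: "positive", 0: "negative", None: "none"}[label]},
                sort_keys=True))
            fh.write("\n")


def read_pools(path) -> dict[str, Pool]:
    out: dict[str, Pool] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                obj = json.loads(line)
                out[obj["note_id"]] = Pool(obj["pool"])
    return out


def read_gold_csv(path) -> list[tuple[str, int]]:
    """Read ``note_id,label`` CSV with label in {relevant, irrelevant}."""
    out: list[tuple[str, int]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if not row or row[0] == "note_id":
                continue
            note_id, label = row[0], row[1].strip().lower()
            if label not in ("relevant", "irrelevant"):
                raise ValueError(f"bad gold label {label!r} for {note_id!r}")
            out.append((note_id, 1 if label == "relevant" else 0))
    return out


def write_gold_csv(annotations: list[tuple[str, int]], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["note_id", "label"])
        for note_id, label in annotations:
            writer.writerow([note_id, "relevant" if label else "irrelevant"])
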