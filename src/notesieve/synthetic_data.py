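"""Synthetic EHR cohort generator.

Produces patients with encounter timelines, diagnosis coding with
controllable noise, and note text drawn from a two-topic unigram mixture in
which truly relevant notes up-weight a respiratory topic (terms seeded from
the bundled toy lexicon). The generator records ground truth for every note:
its true relevance and the silver-pool branch it was constructed to hit,
which makes every heuristic and classifier in the package testable without
real data.

Noise knobs:

* ``miscoding_rate`` — P(note at a target-coded encounter is truly
  irrelevant);
* ``uncoded_relevant_rate`` — P(note at an uncoded encounter is truly
  relevant);
* ``pre_window_contamination`` — P(relevant content in uncoded notes inside
  the 0-24 month pre-diagnosis gray zone).

Everything is deterministic under ``params.seed``.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .corpus_model import (ClinicalNote, CodeSet, CodeSystem, Corpus,
                           Encounter, normalize_code, write_corpus)
from .errors import ConfigError, SamplingError
from .representations.concepts import default_lexicon
from .silver_labeling import Pool, shift_months, write_gold_csv

__all__ = ["CohortParams", "GroundTruth", "SyntheticCohort",
           "generate_cohort", "generate_gold_annotations", "write_cohort"]

_NOTE_TYPES = ("progress", "discharge", "nursing", "radiology")

# plausible non-target administrative codes for background encounters
_OTHER_CODES = (("I10", CodeSystem.ICD10CM), ("E11.9", CodeSystem.ICD10CM),
                ("M54.5", CodeSystem.ICD10CM), ("401.9", CodeSystem.ICD9CM),
                ("250.00", CodeSystem.ICD9CM), ("K21.9", CodeSystem.ICD10CM))


@dataclass
class CohortParams:
    n_patients: int = 100
    copd_prevalence: float = 0.5
    encounters_per_patient: tuple[int, int] = (8, 16)
    study_start: _dt.date = _dt.date(2012, 1, 1)
    study_end: _dt.date = _dt.date(2020, 12, 31)
    post_coding_rate: float = 0.75  # P(post-dx encounter carries a target code)
    miscoding_rate: float = 0.0
    uncoded_relevant_rate: float = 0.0
    pre_window_contamination: float = 0.0
    lookback_months: int = 24
    vocab_respiratory: int = 120
    vocab_general: int = 300
    relevant_topic_weight: float = 0.6   # respiratory share in relevant notes
    irrelevant_topic_weight: float = 0.03
    mean_note_length: int = 60
    seed: int = 0

    def validate(self) -> None:
        for name in ("copd_prevalence", "post_coding_rate", "miscoding_rate",
                     "uncoded_relevant_rate", "pre_window_contamination",
                     "relevant_topic_weight", "irrelevant_topic_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.encounters_per_patient
        if lo < 1 or hi < lo:
            raise ConfigError("encounters_per_patient range is empty")
        span_months = ((self.study_end.year - self.study_start.year) * 12
                       + self.study_end.month - self.study_start.month)
        if span_months < self.lookback_months + 6:
            raise ConfigError(
                "study window too short to host a pre-diagnosis pool "
                f"({span_months} months < lookback + 6)")
        if self.n_patients < 1:
            raise ConfigError("need at least one patient")


@dataclass
class GroundTruth:
    """Per-note true relevance and intended silver-pool branch."""

    relevance: dict[str, int] = field(default_factory=dict)
    branch: dict[str, Pool] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    corpus: Corpus
    truth: GroundTruth
    params: CohortParams


def _topic_vocabularies(params: CohortParams) -> tuple[list[str], list[str]]:
    lex_tokens = sorted({tok for term in default_lexicon().terms
                         for tok in term})
    resp = list(lex_tokens[: params.vocab_respiratory])
    i = 0
    while len(resp) < params.vocab_respiratory:
        resp.append(f"resp{i:03d}")
        i += 1
    general = [f"gen{i:03d}" for i in range(params.vocab_general)]
    return resp, general


def _zipf_probs(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def _note_text(rng: np.random.Generator, relevant: bool,
               resp: list[str], resp_p: np.ndarray,
               general: list[str], gen_p: np.ndarray,
               params: CohortParams) -> str:
    length = max(10, int(rng.poisson(params.mean_note_length)))
    share = (params.relevant_topic_weight if relevant
             else params.irrelevant_topic_weight)
    n_resp = rng.binomial(length, share)
    words = list(rng.choice(resp, size=n_resp, p=resp_p))
    words += list(rng.choice(general, size=length - n_resp, p=gen_p))
    rng.shuffle(words)
    return " ".join(words)


def _random_date(rng: np.random.Generator, start: _dt.date,
                 end: _dt.date) -> _dt.date:
    span = (end - start).days
    return start + _dt.timedelta(days=int(rng.integers(0, span + 1)))


def generate_cohort(params: CohortParams) -> SyntheticCohort:
    """Generate a fully linked corpus plus ground truth (deterministic)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    resp, general = _topic_vocabularies(params)
    resp_p = _zipf_probs(len(resp))
    gen_p = _zipf_probs(len(general))
    codeset = CodeSet.default_copd()
    target_codes = ([(c, CodeSystem.ICD9CM) for c in sorted(codeset.icd9)]
                    + [(c, CodeSystem.ICD10CM) for c in sorted(codeset.icd10)])

    corpus = Corpus()
    truth = GroundTruth()
    note_seq = 0
    dx_lo = shift_months(params.study_start, params.lookback_months + 6)
    dx_hi = shift_months(params.study_end, -6)

    for p in range(params.n_patients):
        patient_id = f"P{p:05d}"
        is_case = rng.random() < params.copd_prevalence
        lo, hi = params.encounters_per_patient
        n_enc = int(rng.integers(lo, hi + 1))
        first_dx = _random_date(rng, dx_lo, dx_hi) if is_case else None
        dates = sorted(_random_date(rng, params.study_start, params.study_end)
                       for _ in range(n_enc - (1 if is_case else 0)))
        if is_case:
            dates.append(first_dx)
            dates.sort()
        birth = _dt.date(int(rng.integers(1935, 1975)), 6, 15)

        for e, date in enumerate(dates):
            encounter_id = f"{patient_id}-E{e:03d}"
            coded = False
            codes = []
            if is_case and date >= first_dx:
                coded = (date == first_dx
                         or rng.random() < params.post_coding_rate)
            if coded:
                raw, system = target_codes[int(rng.integers(0, len(target_codes)))]
                codes.append(normalize_code(raw, system))
            elif rng.random() < 0.5:
                raw, system = _OTHER_CODES[int(rng.integers(0, len(_OTHER_CODES)))]
                codes.append(normalize_code(raw, system))
            encounter = Encounter(encounter_id=encounter_id,
                                  patient_id=patient_id, date=date,
                                  codes=codes)

            # intended silver-pool branch and true relevance
            if coded:
                branch = Pool.COPD_ENCOUNTER
                relevant = rng.random() >= params.miscoding_rate
            elif is_case and date <= shift_months(first_dx,
                                                  -params.lookback_months):
                branch = Pool.PRE_COPD
                relevant = rng.random() < params.uncoded_relevant_rate
            elif is_case:
                branch = Pool.EXCLUDED
                rate = (params.pre_window_contamination if date < first_dx
                        else params.uncoded_relevant_rate)
                relevant = rng.random() < rate
            else:
                branch = Pool.NON_COPD
                relevant = rng.random() < params.uncoded_relevant_rate

            note_id = f"N{note_seq:06d}"
            note_seq += 1
            note = ClinicalNote(
                note_id=note_id, patient_id=patient_id,
                encounter_id=encounter_id, date=date,
                note_type=_NOTE_TYPES[int(rng.integers(0, len(_NOTE_TYPES)))],
                text=_note_text(rng, relevant, resp, resp_p, general, gen_p,
                                params),
            )
            corpus.add_note(note, encounter, birth_date=birth)
            truth.relevance[note_id] = int(relevant)
            truth.branch[note_id] = branch

    return SyntheticCohort(corpus=corpus, truth=truth,
                           params=replace(params))


def generate_gold_annotations(truth: GroundTruth, n: int, seed: int,
                              strata_weights: tuple[int, int, int] = (107, 100, 100)
                              ) -> list[tuple[str, int]]:
    """Sample n notes stratified across the three silver-pool branches
    (positive/non/pre, proportional to ``strata_weights``) and emit their
    true relevance as gold labels. Deterministic under seed."""
    if n < 0:
        raise SamplingError("n must be >= 0")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    pools = (Pool.COPD_ENCOUNTER, Pool.NON_COPD, Pool.PRE_COPD)
    members = {pool: sorted(nid for nid, b in truth.branch.items()
                            if b is pool)
               for pool in pools}
    weights = np.asarray(strata_weights, dtype=float)
    quotas = weights / weights.sum() * n
    alloc = np.floor(quotas).astype(int)
    short = n - alloc.sum()
    if short > 0:
        order = np.argsort(-(quotas - alloc), kind="stable")
        for idx in order[:short]:
            alloc[idx] += 1
    out: list[tuple[str, int]] = []
    for pool, take in zip(pools, alloc):
        pool_members = members[pool]
        if take > len(pool_members):
            raise SamplingError(
                f"pool {pool.value} holds {len(pool_members)} notes, "
                f"{int(take)} requested for gold annotation")
        idx = rng.choice(len(pool_members), size=int(take), replace=False)
        out.extend((pool_members[i], truth.relevance[pool_members[i]])
                   for i in sorted(idx))
    return out


def write_cohort(cohort: SyntheticCohort, out_dir, gold_n: int | None = None,
                 gold_seed: int | None = None) -> dict[str, str]:
    """Write notes.jsonl + truth.jsonl (+ gold.csv when requested)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    notes_path = out_dir / "notes.jsonl"
    write_corpus(cohort.corpus, notes_path)
    truth_path = out_dir / "truth.jsonl"
    with open(truth_path, "w", encoding="utf-8") as fh:
        for note_id in cohort.truth.relevance:
            fh.write(json.dumps(
                {"note_id": note_id,
                 "relevant": cohort.truth.relevance[note_id],
                 "branch": cohort.truth.branch[note_id].value},
                sort_keys=True))
            fh.write("\n")
    paths = {"notes": str(notes_path), "truth": str(truth_path)}
    if gold_n is not None:
        seed = cohort.params.seed if gold_seed is None else gold_seed
        gold = generate_gold_annotations(cohort.truth, gold_n, seed)
        gold_path = out_dir / "gold.csv"
        write_gold_csv(gold, gold_path)
        paths["gold"] = str(gold_path)
    return paths
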