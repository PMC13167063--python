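import datetime as dt

import numpy as np
import pytest

from notesieve.corpus_model import (ClinicalNote, CodeSet, Corpus, Encounter,
                                    normalize_code)


def make_corpus(spec_rows):
    """Build a linked corpus from rows of
    (note_id, patient_id, encounter_id, iso_date, note_type, text, codes)
    where codes is a list of (raw, system) pairs."""
    corpus = Corpus()
    for note_id, pid, eid, date, ntype, text, codes in spec_rows:
        enc = Encounter(
            encounter_id=eid, patient_id=pid,
            date=dt.date.fromisoformat(date),
            codes=[normalize_code(raw, system) for raw, system in codes])
        note = ClinicalNote(note_id=note_id, patient_id=pid,
                            encounter_id=eid,
                            date=dt.date.fromisoformat(date),
                            note_type=ntype, text=text)
        corpus.add_note(note, enc)
    return corpus


def random_corpus(rng: np.random.Generator, n_patients=3,
                  max_encounters=4) -> Corpus:
    """A small random—but-valid corpus for round-trip property tests."""
    corpus = Corpus()
    words = ["copd", "cough", "visit", "stable", "féver", "≥", "°C",
             "note", "wheeze", "plan"]
    codes = [("J44.9", "ICD10CM"), ("491.21", "ICD9CM"),
             ("I10", "ICD10CM"), ("E11.9", "ICD10CM")]
    note_seq = 0
    for p in range(n_patients):
        pid = f"P{p}"
        for e in range(int(rng.integers(1, max_encounters + 1))):
            eid = f"{pid}-E{e}"
            date = dt.date(2015, 1, 1) + dt.timedelta(
                days=int(rng.integers(0, 2000)))
            n_codes = int(rng.integers(0, 3))
            picks = [codes[int(i)] for i in rng.integers(0, len(codes),
                                                         n_codes)]
            enc = Encounter(encounter_id=eid, patient_id=pid, date=date,
                            codes=[normalize_code(r, s) for r, s in picks])
            for n in range(int(rng.integers(1, 3))):
                text = " ".join(rng.choice(words,
                                           int(rng.integers(0, 15))))
                note = ClinicalNote(note_id=f"N{note_seq}", patient_id=pid,
                                    encounter_id=eid, date=date,
                                    note_type="progress", text=text)
                corpus.add_note(note, enc)
                note_seq += 1
    return corpus


@pytest.fixture
def copd_codeset() -> CodeSet:
    return CodeSet.default_copd()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
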