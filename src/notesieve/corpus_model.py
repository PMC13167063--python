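"""EHR corpus data model, line-delimited JSON corpus I/O, and code matching.

A corpus is stored as UTF-8 line-delimited JSON, one object per note, with
encounter fields denormalized onto each line::

    {"note_id": ..., "patient_id": ..., "encounter_id": ...,
     "date": "YYYY-MM-DD", "note_type": ..., "text": ...,
     "codes": [{"code": "J44.9", "system": "ICD10CM"}, ...],
     "birth_date": "YYYY-MM-DD"}          # optional

Diagnosis codes are compared after uppercasing and dot removal, as exact set
membership against a :class:`CodeSet` — no prefix/child expansion.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .errors import (
    CorpusFormatError,
    InvalidCodeError,
    ReferentialIntegrityError,
)

__all__ = [
    "CodeSystem",
    "DiagnosisCode",
    "Encounter",
    "ClinicalNote",
    "Patient",
    "CodeSet",
    "Corpus",
    "normalize_code",
    "is_target_code",
    "read_corpus",
    "write_corpus",
]


class CodeSystem(str, Enum):
    ICD9CM = "ICD9CM"
    ICD10CM = "ICD10CM"


@dataclass(frozen=True)
class DiagnosisCode:
    """A diagnosis code as recorded, plus its normalized comparison form."""

    raw: str
    system: CodeSystem
    normalized: str


def normalize_code(raw: str, system: CodeSystem | str) -> DiagnosisCode:
    """Normalize a raw code: trim, uppercase, strip dots.

    Raises :class:`InvalidCodeError` for empty/whitespace-only input.
    Normalization is idempotent.
    """
    system = CodeSystem(system)
    trimmed = raw.strip()
    if not trimmed:
        raise InvalidCodeError(f"empty diagnosis code (raw={raw!r})")
    normalized = trimmed.upper().replace(".", "")
    return DiagnosisCode(raw=trimmed, system=system, normalized=normalized)


# The closed administrative code lists defining the target condition.
_DEFAULT_ICD9 = (
    "491", "491.1", "491.2", "491.21", "491.22", "491.8", "491.9",
    "492", "492.8", "493.92", "496",
)
_DEFAULT_ICD10 = (
    "J41.0", "J41.1", "J41.8", "J42", "J43.1", "J43.2", "J43.8", "J43.9",
    "J44.0", "J44.1", "J44.9",
)


@dataclass
class CodeSet:
    """A named pair of normalized ICD-9-CM / ICD-10-CM code sets."""

    name: str
    icd9: frozenset[str]
    icd10: frozenset[str]

    @classmethod
    def from_codes(cls, name: str, icd9, icd10) -> "CodeSet":
        return cls(
            name=name,
            icd9=frozenset(
                normalize_code(c, CodeSystem.ICD9CM).normalized for c in icd9
            ),
            icd10=frozenset(
                normalize_code(c, CodeSystem.ICD10CM).normalized for c in icd10
            ),
        )

    @classmethod
    def default_copd(cls) -> "CodeSet":
        return cls.from_codes("COPD-default", _DEFAULT_ICD9, _DEFAULT_ICD10)

    @classmethod
    def from_json(cls, path) -> "CodeSet":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls.from_codes(obj.get("name", Path(path).stem),
                              obj.get("icd9", []), obj.get("icd10", []))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"name": self.name, "icd9": sorted(self.icd9),
                 "icd10": sorted(self.icd10)},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")

    def contains(self, code: DiagnosisCode) -> bool:
        pool = self.icd9 if code.system is CodeSystem.ICD9CM else self.icd10
        return code.normalized in pool


def is_target_code(code: DiagnosisCode, codeset: CodeSet) -> bool:
    """Exact set membership of the normalized code in its system's set."""
    return codeset.contains(code)


@dataclass
class Encounter:
    encounter_id: str
    patient_id: str
    date: _dt.date
    codes: list[DiagnosisCode] = field(default_factory=list)

    def has_target_code(self, codeset: CodeSet) -> bool:
        return any(is_target_code(c, codeset) for c in self.codes)


@dataclass
class ClinicalNote:
    note_id: str
    patient_id: str
    encounter_id: str
    date: _dt.date
    note_type: str
    text: str


@dataclass
class Patient:
    patient_id: str
    birth_date: _dt.date | None = None
    encounters: list[Encounter] = field(default_factory=list)

    def first_target_date(self, codeset: CodeSet) -> _dt.date | None:
        """Earliest encounter date carrying a target code; None if none."""
        dates = [e.date for e in self.encounters if e.has_target_code(codeset)]
        return min(dates) if dates else None

    def has_any_target_code(self, codeset: CodeSet) -> bool:
        return any(e.has_target_code(codeset) for e in self.encounters)


class Corpus:
    """Fully linked patients, encounters and notes."""

    def __init__(self):
        self.patients: dict[str, Patient] = {}
        self.encounters: dict[str, Encounter] = {}
        self.notes: dict[str, ClinicalNote] = {}

    def __len__(self) -> int:
        return len(self.notes)

    def add_note(self, note: ClinicalNote, encounter: Encounter,
                 birth_date: _dt.date | None = None) -> None:
        if note.note_id in self.notes:
            raise ReferentialIntegrityError(
                f"duplicate note_id {note.note_id!r}")
        existing = self.encounters.get(encounter.encounter_id)
        if existing is None:
            self.encounters[encounter.encounter_id] = encounter
            existing = encounter
        else:
            if existing.patient_id != encounter.patient_id:
                raise ReferentialIntegrityError(
                    f"encounter {encounter.encounter_id!r} claimed by two "
                    f"patients")
            if existing.date != encounter.date:
                raise ReferentialIntegrityError(
                    f"encounter {encounter.encounter_id!r} has conflicting "
                    f"dates {existing.date} vs {encounter.date}")
            seen = {(c.system, c.normalized) for c in existing.codes}
            for c in encounter.codes:
                if (c.system, c.normalized) not in seen:
                    existing.codes.append(c)
        if note.encounter_id != existing.encounter_id:
            raise ReferentialIntegrityError(
                f"note {note.note_id!r} references missing encounter "
                f"{note.encounter_id!r}")
        pat = self.patients.get(note.patient_id)
        if pat is None:
            pat = Patient(patient_id=note.patient_id, birth_date=birth_date)
            self.patients[note.patient_id] = pat
        if birth_date is not None and pat.birth_date is None:
            pat.birth_date = birth_date
        if existing not in pat.encounters:
            pat.encounters.append(existing)
        self.notes[note.note_id] = note

    def notes_in_order(self) -> list[ClinicalNote]:
        return list(self.notes.values())


def _parse_date(value: str, line_number: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(value)
    except (TypeError, ValueError) as exc:
        raise CorpusFormatError(f"bad date {value!r}: {exc}", line_number)


_REQUIRED_KEYS = ("note_id", "patient_id", "encounter_id", "date",
                  "note_type", "text")


def read_corpus(path) -> Corpus:
    """Read a line-delimited JSON note corpus into a linked :class:`Corpus`.

    Raises :class:`CorpusFormatError` (with line number) on malformed lines
    and :class:`ReferentialIntegrityError` on dangling or conflicting
    references. An empty file yields an empty corpus.
    """
    corpus = Corpus()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"invalid JSON: {exc}", lineno)
            if not isinstance(obj, dict):
                raise CorpusFormatError("expected a JSON object", lineno)
            missing = [k for k in _REQUIRED_KEYS if k not in obj]
            if missing:
                raise CorpusFormatError(
                    f"missing required keys {missing}", lineno)
            date = _parse_date(obj["date"], lineno)
            if "codes" in obj:
                try:
                    codes = [normalize_code(c["code"], c["system"])
                             for c in obj["codes"]]
                except (KeyError, TypeError) as exc:
                    raise CorpusFormatError(f"bad codes entry: {exc}", lineno)
                except InvalidCodeError as exc:
                    raise CorpusFormatError(str(exc), lineno)
                enc_date = obj.get("encounter_date", obj["date"])
                encounter = Encounter(
                    encounter_id=str(obj["encounter_id"]),
                    patient_id=str(obj["patient_id"]),
                    date=_parse_date(enc_date, lineno),
                    codes=codes,
                )
            else:
                # No embedded encounter payload: the encounter must already
                # be known from an earlier line.
                if str(obj["encounter_id"]) not in corpus.encounters:
                    raise ReferentialIntegrityError(
                        f"line {lineno}: note {obj['note_id']!r} references "
                        f"missing encounter {obj['encounter_id']!r}")
                encounter = corpus.encounters[str(obj["encounter_id"])]
            birth = obj.get("birth_date")
            note = ClinicalNote(
                note_id=str(obj["note_id"]),
                patient_id=str(obj["patient_id"]),
                encounter_id=str(obj["encounter_id"]),
                date=date,
                note_type=str(obj["note_type"]),
                text=str(obj["text"]),
            )
            corpus.add_note(
                note, encounter,
                birth_date=_parse_date(birth, lineno) if birth else None,
            )
    return corpus


def write_corpus(corpus: Corpus, path) -> None:
    """Write a corpus as line-delimited JSON; round-trips with read_corpus."""
    with open(path, "w", encoding="utf-8") as fh:
        for note in corpus.notes.values():
            enc = corpus.encounters[note.encounter_id]
            pat = corpus.patients[note.patient_id]
            obj = {
                "note_id": note.note_id,
                "patient_id": note.patient_id,
                "encounter_id": note.encounter_id,
                "date": note.date.isoformat(),
                "note_type": note.note_type,
                "text": note.text,
                "codes": [{"code": c.raw, "system": c.system.value}
                          for c in enc.codes],
            }
            if enc.date != note.date:
                obj["encounter_date"] = enc.date.isoformat()
            if pat.birth_date is not None:
                obj["birth_date"] = pat.birth_date.isoformat()
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True))
            fh.write("\n")
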