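"""Lexicon-driven concept extraction with negation-aware assertion status.

A :class:`ConceptLexicon` maps surface terms (up to 5 tokens) to concept
identifiers. Matching is greedy longest-match over token n-grams,
case-insensitive. A concept mention is asserted negative (-1) when a
negation trigger ends within the 6 tokens preceding the mention in the
same sentence (sentence bounds: ".", "!", "?", newline), else positive (+1).

Document vectors hold one column per concept id with values in {-1, 0, +1}.
By default an affirmed mention dominates a negated one for the same concept
within a document; ``negation_dominates=True`` flips that rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .bow import tokenize
from .matrix import FeatureMatrix

__all__ = ["ConceptLexicon", "load_lexicon", "load_triggers",
           "default_lexicon", "extract_concepts", "concept_vectorize"]

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_SENT_BREAK = re.compile(r"[.!?\n]")

MAX_TERM_TOKENS = 5
NEGATION_WINDOW = 6

_DEFAULT_TRIGGERS = (
    "no", "not", "never", "without", "denies", "denied", "negative for",
    "no evidence of", "no sign of", "free of", "absence of", "absent",
    "ruled out", "rules out", "unlikely",
)


@dataclass
class ConceptLexicon:
    """Surface-term -> concept-id map plus negation triggers."""

    terms: dict[tuple[str, ...], str]
    triggers: list[tuple[str, ...]] = field(
        default_factory=lambda: [tuple(tokenize(t)) for t in _DEFAULT_TRIGGERS])

    def __post_init__(self):
        bad = [t for t in self.terms if not t or len(t) > MAX_TERM_TOKENS]
        if bad:
            raise ValueError(f"lexicon terms must be 1..{MAX_TERM_TOKENS} "
                             f"tokens, got {bad[:3]}")

    @property
    def concept_ids(self) -> list[str]:
        return sorted(set(self.terms.values()))


def load_lexicon(path, triggers_path=None) -> ConceptLexicon:
    """Load a TSV lexicon (columns: term, concept_id), case-insensitive."""
    terms: dict[tuple[str, ...], str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            term, cui = line.split("\t")[:2]
            terms[tuple(tokenize(term))] = cui.strip()
    lexicon = ConceptLexicon(terms=terms)
    if triggers_path is not None:
        lexicon.triggers = load_triggers(triggers_path)
    return lexicon


def load_triggers(path) -> list[tuple[str, ...]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(tuple(tokenize(line)))
    return out


def default_lexicon() -> ConceptLexicon:
    """The bundled toy respiratory lexicon and trigger list."""
    data = resources.files("notesieve.data")
    with resources.as_file(data / "respiratory_lexicon.tsv") as lex_path, \
            resources.as_file(data / "negation_triggers.txt") as trig_path:
        return load_lexicon(lex_path, trig_path)


def _tokens_with_meta(text: str):
    """Token strings with char spans and sentence ids."""
    lowered = text.lower()
    breaks = [m.start() for m in _SENT_BREAK.finditer(lowered)]
    tokens = []
    sent = 0
    b = 0
    for m in _TOKEN_RE.finditer(lowered):
        while b < len(breaks) and breaks[b] < m.start():
            sent += 1
            b += 1
        tokens.append((m.group(), m.start(), m.end(), sent))
    return tokens


def extract_concepts(text: str, lexicon: ConceptLexicon
                     ) -> list[tuple[str, int, tuple[int, int]]]:
    """Greedy longest-match extraction; returns (concept_id, assertion,
    (start_char, end_char)) per mention, in text order."""
    toks = _tokens_with_meta(text)
    words = [t[0] for t in toks]
    n = len(words)

    # token index just past each trigger occurrence, with its sentence id
    trigger_ends: list[tuple[int, int]] = []
    for i in range(n):
        for trig in lexicon.triggers:
            if words[i:i + len(trig)] == list(trig):
                trigger_ends.append((i + len(trig), toks[i][3]))

    results = []
    i = 0
    while i < n:
        match = None
        for size in range(min(MAX_TERM_TOKENS, n - i), 0, -1):
            cui = lexicon.terms.get(tuple(words[i:i + size]))
            if cui is not None:
                match = (size, cui)
                break
        if match is None:
            i += 1
            continue
        size, cui = match
        sent = toks[i][3]
        negated = any(
            sent == t_sent and i - NEGATION_WINDOW <= t_end <= i
            for t_end, t_sent in trigger_ends)
        span = (toks[i][1], toks[i + size - 1][2])
        results.append((cui, -1 if negated else 1, span))
        i += size
    return results


def concept_vectorize(docs: list[str], lexicon: ConceptLexicon,
                      negation_dominates: bool = False,
                      row_ids: list[str] | None = None) -> FeatureMatrix:
    """One column per concept id; cells in {-1, 0, +1}."""
    ids = lexicon.concept_ids
    col = {c: j for j, c in enumerate(ids)}
    X = np.zeros((len(docs), len(ids)), dtype=float)
    for r, doc in enumerate(docs):
        affirmed: set[str] = set()
        negated: set[str] = set()
        for cui, assertion, _ in extract_concepts(doc, lexicon):
            (affirmed if assertion > 0 else negated).add(cui)
        for cui in affirmed | negated:
            if cui in affirmed and cui in negated:
                value = -1.0 if negation_dominates else 1.0
            else:
                value = 1.0 if cui in affirmed else -1.0
            X[r, col[cui]] = value
    rids = list(row_ids) if row_ids is not None else [str(i) for i in range(len(docs))]
    return FeatureMatrix(row_ids=rids, columns=ids, X=X, tag="CONCEPT")
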