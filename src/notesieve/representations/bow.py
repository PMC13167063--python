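"""Tokenization, bag-of-words and TF-IDF feature spaces.

The tokenizer lowercases and keeps maximal runs of ASCII letters/digits.
TF-IDF uses the smoothed formula ``idf(t) = ln((1+N)/(1+df(t))) + 1`` with
L2 row normalization (scikit-learn's default variant).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer

from ..errors import EmptyVocabularyError
from .matrix import FeatureMatrix

__all__ = ["tokenize", "Vocabulary", "BowModel", "TfidfModel",
           "fit_bow", "fit_tfidf"]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercased maximal runs of letters/digits, in order of appearance."""
    return _TOKEN_RE.findall(text.lower())


@dataclass
class Vocabulary:
    """Dense token-indexed vocabulary with per-token document frequency."""

    tokens: list[str]
    index: dict[str, int]
    doc_freq: np.ndarray

    def __len__(self) -> int:
        return len(self.tokens)


def _build_vocabulary(vectorizer, docs_matrix) -> Vocabulary:
    tokens = vectorizer.get_feature_names_out().tolist()
    df = np.asarray((docs_matrix > 0).sum(axis=0)).ravel().astype(int)
    return Vocabulary(tokens=tokens,
                      index={t: i for i, t in enumerate(tokens)},
                      doc_freq=df)


class _FittedText:
    tag = "BOW"

    def __init__(self, min_df: int = 1):
        self.min_df = min_df
        self._vec = None
        self.vocabulary: Vocabulary | None = None

    def _make(self):
        raise NotImplementedError

    def fit(self, docs: list[str], row_ids: list[str] | None = None):
        if not docs:
            raise EmptyVocabularyError("no documents to fit")
        self._vec = self._make()
        try:
            X = self._vec.fit_transform(docs)
        except ValueError as exc:
            raise EmptyVocabularyError(str(exc)) from exc
        counts = CountVectorizer(analyzer=tokenize,
                                 vocabulary=self._vec.vocabulary_)
        self.vocabulary = _build_vocabulary(self._vec,
                                            counts.fit_transform(docs))
        return self._to_matrix(X, row_ids, len(docs))

    def transform(self, docs: list[str],
                  row_ids: list[str] | None = None) -> FeatureMatrix:
        if self._vec is None:
            raise EmptyVocabularyError("model not fitted")
        return self._to_matrix(self._vec.transform(docs), row_ids, len(docs))

    def _to_matrix(self, X, row_ids, n) -> FeatureMatrix:
        ids = list(row_ids) if row_ids is not None else [str(i) for i in range(n)]
        return FeatureMatrix(row_ids=ids, columns=self.vocabulary.tokens,
                             X=X.tocsr(), tag=self.tag)


class BowModel(_FittedText):
    """Raw token counts, tokens with document frequency < min_df dropped."""

    tag = "BOW"

    def _make(self):
        return CountVectorizer(analyzer=tokenize, min_df=self.min_df)


class TfidfModel(_FittedText):
    tag = "TFIDF"

    def _make(self):
        return TfidfVectorizer(analyzer=tokenize, min_df=self.min_df,
                               norm="l2", smooth_idf=True, sublinear_tf=False)


def fit_bow(docs: list[str], min_df: int = 1,
            row_ids: list[str] | None = None
            ) -> tuple[Vocabulary, FeatureMatrix]:
    model = BowModel(min_df=min_df)
    fm = model.fit(docs, row_ids)
    return model.vocabulary, fm


def fit_tfidf(docs: list[str], min_df: int = 1,
              row_ids: list[str] | None = None
              ) -> tuple[Vocabulary, FeatureMatrix]:
    model = TfidfModel(min_df=min_df)
    fm = model.fit(docs, row_ids)
    return model.vocabulary, fm
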