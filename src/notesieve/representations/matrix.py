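"""FeatureMatrix container with MTX + JSON-sidecar persistence."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["FeatureMatrix"]

_TAGS = ("BOW", "TFIDF", "EMB", "COMP", "CONCEPT")


@dataclass
class FeatureMatrix:
    """documents x features matrix with aligned row ids and column names."""

    row_ids: list[str]
    columns: list[str]
    X: object  # scipy sparse matrix or dense ndarray
    tag: str

    def __post_init__(self):
        if self.tag not in _TAGS:
            raise ValueError(f"unknown representation tag {self.tag!r}")
        n, m = self.shape
        if n != len(self.row_ids):
            raise ValueError("row_ids do not align with matrix rows")
        if m != len(self.columns):
            raise ValueError("columns do not align with matrix width")
        dense = self.X.toarray() if sp.issparse(self.X) else np.asarray(self.X)
        if not np.all(np.isfinite(dense)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.X):
            return self.X.toarray()
        return np.asarray(self.X, dtype=float)

    def save(self, prefix) -> None:
        """Write ``<prefix>.mtx`` plus ``<prefix>.json`` sidecar."""
        prefix = Path(prefix)
        X = self.X if sp.issparse(self.X) else sp.coo_matrix(np.atleast_2d(self.X))
        mmwrite(str(prefix.with_suffix(".mtx")), X)
        with open(prefix.with_suffix(".json"), "w", encoding="utf-8") as fh:
            json.dump({"row_ids": self.row_ids, "columns": self.columns,
                       "tag": self.tag}, fh, sort_keys=True)

    @classmethod
    def load(cls, prefix) -> "FeatureMatrix":
        prefix = Path(prefix)
        X = mmread(str(prefix.with_suffix(".mtx")))
        if sp.issparse(X):
            X = X.tocsr()
        with open(prefix.with_suffix(".json"), encoding="utf-8") as fh:
            meta = json.load(fh)
        return cls(row_ids=list(meta["row_ids"]), columns=list(meta["columns"]),
                   X=X, tag=meta["tag"])
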