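"""Compression-based text features: gzip length and normalized compression
distance (NCD).

All compression is gzip/DEFLATE at level 6 with a zeroed header timestamp so
byte lengths are stable across calls and platforms.

NCD(x, y) = (C(x||y) - min(C(x), C(y))) / max(C(x), C(y)), with || denoting
byte concatenation and C the compressed byte length. Both-empty input is
defined as distance 0.
"""

from __future__ import annotations

import gzip

import numpy as np

from .matrix import FeatureMatrix

__all__ = ["compressed_length", "compression_features", "ncd",
           "ncd_distance_matrix"]

_LEVEL = 6


def _compress(data: bytes) -> bytes:
    return gzip.compress(data, compresslevel=_LEVEL, mtime=0)


def compressed_length(text: str) -> int:
    """Byte length of the pinned-settings gzip compression of ``text``."""
    return len(_compress(text.encode("utf-8")))


def compression_features(docs: list[str], extra: bool = False,
                         row_ids: list[str] | None = None) -> FeatureMatrix:
    """One column [compressed_length]; with ``extra`` also raw byte length
    and compression ratio."""
    comp = np.array([compressed_length(d) for d in docs], dtype=float)
    if extra:
        raw = np.array([len(d.encode("utf-8")) for d in docs], dtype=float)
        ratio = np.divide(comp, raw, out=np.ones_like(comp), where=raw > 0)
        X = np.column_stack([comp, raw, ratio])
        columns = ["compressed_length", "raw_byte_length", "compression_ratio"]
    else:
        X = comp[:, None]
        columns = ["compressed_length"]
    ids = list(row_ids) if row_ids is not None else [str(i) for i in range(len(docs))]
    return FeatureMatrix(row_ids=ids, columns=columns, X=X, tag="COMP")


def ncd(x: str, y: str,
        cx: int | None = None, cy: int | None = None) -> float:
    """Normalized compression distance between two texts.

    ``cx``/``cy`` allow reuse of precomputed single-text lengths; the result
    is identical with or without them.
    """
    bx = x.encode("utf-8")
    by = y.encode("utf-8")
    if not bx and not by:
        return 0.0
    cx = len(_compress(bx)) if cx is None else cx
    cy = len(_compress(by)) if cy is None else cy
    cxy = len(_compress(bx + by))
    return (cxy - min(cx, cy)) / max(cx, cy)


def ncd_distance_matrix(queries: list[str],
                        references: list[str]) -> np.ndarray:
    """|queries| x |references| matrix of NCD values.

    Single-text compressed lengths are computed once per input and reused.
    """
    c_q = [compressed_length(q) for q in queries]
    c_r = [compressed_length(r) for r in references]
    out = np.empty((len(queries), len(references)), dtype=float)
    for i, q in enumerate(queries):
        for j, r in enumerate(references):
            out[i, j] = ncd(q, r, cx=c_q[i], cy=c_r[j])
    return out
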