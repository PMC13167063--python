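"""Lightweight document embeddings: paragraph vectors trained with
hierarchical softmax.

Two sub-models are trained (both always with hierarchical softmax over a
Huffman-coded vocabulary):

* distributed memory (DM): the document vector plus the mean of context
  word vectors predicts each center word;
* distributed bag of words (DBOW): the document vector alone predicts every
  word of the document.

``embed_documents`` concatenates the two per-document vectors (DM || DBOW).
Training and inference are plain single-threaded numpy, so runs are
bit-reproducible for a fixed seed. Gradients are applied per document
(mini-batched over the document's positions), which keeps small corpora
fast without changing the qualitative geometry of the embedding space.
"""

from __future__ import annotations

import heapq
from collections import Counter
from dataclasses import dataclass, field

import joblib
import numpy as np

from ..errors import TrainingError
from .bow import tokenize
from .matrix import FeatureMatrix

__all__ = ["EmbeddingParams", "EmbeddingModel", "train_embedding",
           "embed_documents"]


@dataclass
class EmbeddingParams:
    dim_dm: int = 25
    dim_dbow: int = 25
    window: int = 4
    epochs: int = 30
    infer_epochs: int = 20
    min_count: int = 2
    alpha: float = 0.05
    min_alpha: float = 0.0005
    seed: int = 0
    mode: str = "both"  # "both" | "dm" | "dbow"

    def __post_init__(self):
        if self.mode not in ("both", "dm", "dbow"):
            raise ValueError(f"unknown embedding mode {self.mode!r}")


def _build_huffman(freqs: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Huffman codes/points per word id; points index inner nodes 0..V-2."""
    V = len(freqs)
    heap = [(int(f), i, None, None) for i, f in enumerate(freqs)]
    heapq.heapify(heap)
    next_id = V
    parents: dict[int, tuple[int, int]] = {}  # child -> (parent, bit)
    while len(heap) > 1:
        f1, n1, _, _ = heapq.heappop(heap)
        f2, n2, _, _ = heapq.heappop(heap)
        parents[n1] = (next_id, 0)
        parents[n2] = (next_id, 1)
        heapq.heappush(heap, (f1 + f2, next_id, None, None))
        next_id += 1
    root = heap[0][1]
    codes, points = [], []
    for w in range(V):
        code, path = [], []
        node = w
        while node != root:
            parent, bit = parents[node]
            code.append(bit)
            path.append(parent - V)  # inner-node index
            node = parent
        codes.append(np.array(code[::-1], dtype=np.int8))
        points.append(np.array(path[::-1], dtype=np.int64))
    return codes, points


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -8.0, 8.0)))


class _SubModel:
    """One paragraph-vector sub-model (DM or DBOW) with HS output layer."""

    def __init__(self, dim: int, n_words: int, n_inner: int,
                 rng: np.random.Generator, dm: bool):
        self.dim = dim
        self.dm = dm
        scale = 0.5 / dim
        self.word_vecs = rng.uniform(-scale, scale, (n_words, dim)) if dm else None
        self.node_vecs = np.zeros((max(n_inner, 1), dim))

    def new_doc_vec(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(-0.5 / self.dim, 0.5 / self.dim, self.dim)

    def _hs_terms(self, word_ids, codes, points):
        L = max((len(points[w]) for w in word_ids), default=0)
        T = len(word_ids)
        P = np.zeros((T, L), dtype=np.int64)
        B = np.zeros((T, L), dtype=np.float64)
        M = np.zeros((T, L), dtype=np.float64)
        for t, w in enumerate(word_ids):
            k = len(points[w])
            P[t, :k] = points[w]
            B[t, :k] = codes[w]
            M[t, :k] = 1.0
        return P, B, M

    def update_doc(self, doc_vec, word_ids, codes, points, alpha, window,
                   train_weights=True):
        """One pass over a document; mutates doc_vec (and, when training,
        the shared weights). Returns nothing."""
        T = len(word_ids)
        if T == 0:
            return
        P, B, M = self._hs_terms(word_ids, codes, points)
        if not self.dm:
            # DBOW: doc vector predicts each word
            nodes = self.node_vecs[P]                      # (T, L, d)
            f = _sigmoid(np.einsum("tld,d->tl", nodes, doc_vec))
            g = alpha * M * (1.0 - B - f)                  # (T, L)
            grad_doc = np.einsum("tl,tld->d", g, nodes)
            if train_weights:
                np.add.at(self.node_vecs, P, g[:, :, None] * doc_vec)
            doc_vec += grad_doc
            return
        # DM: (doc vector + context word sum) / (1 + context size)
        W = np.asarray(word_ids, dtype=np.int64)
        V = self.word_vecs[W]                              # (T, d)
        csum = np.cumsum(np.vstack([np.zeros(self.dim), V]), axis=0)
        lo = np.maximum(np.arange(T) - window, 0)
        hi = np.minimum(np.arange(T) + window + 1, T)
        ctx_sum = csum[hi] - csum[lo] - V
        ctx_n = (hi - lo - 1).astype(float)
        denom = (ctx_n + 1.0)[:, None]
        x = (ctx_sum + doc_vec) / denom                    # (T, d)
        nodes = self.node_vecs[P]
        f = _sigmoid(np.einsum("tld,td->tl", nodes, x))
        g = alpha * M * (1.0 - B - f)
        gx = np.einsum("tl,tld->td", g, nodes) / denom     # grad into inputs
        if train_weights:
            np.add.at(self.node_vecs, P, g[:, :, None] * x[:, None, :])
        doc_vec += gx.sum(axis=0)
        if train_weights:
            # each word receives the summed input-gradients of the windows
            # it participated in — same sliding-window structure as ctx_sum
            gsum = np.cumsum(np.vstack([np.zeros(self.dim), gx]), axis=0)
            word_grad = gsum[hi] - gsum[lo] - gx
            np.add.at(self.word_vecs, W, word_grad)


@dataclass
class EmbeddingModel:
    """Trained DM+DBOW paragraph-vector model."""

    params: EmbeddingParams
    vocab: dict[str, int]
    codes: list[np.ndarray]
    points: list[np.ndarray]
    dm: _SubModel | None
    dbow: _SubModel | None
    doc_vecs_dm: np.ndarray | None
    doc_vecs_dbow: np.ndarray | None
    doc_ids: list[str] = field(default_factory=list)

    @property
    def vector_size(self) -> int:
        size = 0
        if self.dm is not None:
            size += self.params.dim_dm
        if self.dbow is not None:
            size += self.params.dim_dbow
        return size

    def _word_ids(self, text: str) -> list[int]:
        return [self.vocab[t] for t in tokenize(text) if t in self.vocab]

    def infer(self, text: str) -> np.ndarray:
        """Deterministically infer a vector for new text (frozen weights)."""
        word_ids = self._word_ids(text)
        rng = np.random.default_rng(self.params.seed + 7)
        parts = []
        for sub in (self.dm, self.dbow):
            if sub is None:
                continue
            vec = sub.new_doc_vec(rng)
            alphas = np.linspace(self.params.alpha, self.params.min_alpha,
                                 self.params.infer_epochs)
            for a in alphas:
                sub.update_doc(vec, word_ids, self.codes, self.points, a,
                               self.params.window, train_weights=False)
            parts.append(vec)
        return np.concatenate(parts) if parts else np.zeros(0)

    def training_vector(self, doc_index: int) -> np.ndarray:
        parts = []
        if self.dm is not None:
            parts.append(self.doc_vecs_dm[doc_index])
        if self.dbow is not None:
            parts.append(self.doc_vecs_dbow[doc_index])
        return np.concatenate(parts)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "EmbeddingModel":
        return joblib.load(path)


def train_embedding(docs: list[str], params: EmbeddingParams | None = None,
                    doc_ids: list[str] | None = None) -> EmbeddingModel:
    """Train DM and DBOW sub-models on a document list.

    Requires >= 10 documents and a non-empty post-min_count vocabulary.
    Deterministic for a fixed seed (single-threaded numpy).
    """
    params = params or EmbeddingParams()
    if len(docs) < 10:
        raise TrainingError(
            f"embedding training needs >=10 documents, got {len(docs)}")
    tokenized = [tokenize(d) for d in docs]
    freq = Counter(t for toks in tokenized for t in toks)
    kept = sorted(t for t, c in freq.items() if c >= params.min_count)
    if not kept:
        raise TrainingError("no token meets min_count; corpus too small")
    vocab = {t: i for i, t in enumerate(kept)}
    counts = np.array([freq[t] for t in kept], dtype=np.int64)
    codes, points = _build_huffman(counts)
    n_inner = max(len(kept) - 1, 1)

    rng = np.random.default_rng(params.seed)
    dm = dbow = None
    doc_vecs_dm = doc_vecs_dbow = None
    if params.mode in ("both", "dm"):
        dm = _SubModel(params.dim_dm, len(kept), n_inner, rng, dm=True)
        doc_vecs_dm = np.vstack([dm.new_doc_vec(rng) for _ in docs])
    if params.mode in ("both", "dbow"):
        dbow = _SubModel(params.dim_dbow, len(kept), n_inner, rng, dm=False)
        doc_vecs_dbow = np.vstack([dbow.new_doc_vec(rng) for _ in docs])

    word_ids = [[vocab[t] for t in toks if t in vocab] for toks in tokenized]
    alphas = np.linspace(params.alpha, params.min_alpha, params.epochs)
    order_rng = np.random.default_rng(params.seed + 1)
    for alpha in alphas:
        for d in order_rng.permutation(len(docs)):
            if dm is not None:
                dm.update_doc(doc_vecs_dm[d], word_ids[d], codes, points,
                              alpha, params.window)
            if dbow is not None:
                dbow.update_doc(doc_vecs_dbow[d], word_ids[d], codes, points,
                                alpha, params.window)

    ids = list(doc_ids) if doc_ids is not None else [str(i) for i in range(len(docs))]
    return EmbeddingModel(params=params, vocab=vocab, codes=codes,
                          points=points, dm=dm, dbow=dbow,
                          doc_vecs_dm=doc_vecs_dm, doc_vecs_dbow=doc_vecs_dbow,
                          doc_ids=ids)


def embed_documents(model: EmbeddingModel, docs: list[str],
                    row_ids: list[str] | None = None) -> FeatureMatrix:
    """Infer a (DM || DBOW) vector per document; deterministic per model."""
    X = np.vstack([model.infer(d) for d in docs]) if docs else \
        np.zeros((0, model.vector_size))
    ids = list(row_ids) if row_ids is not None else [str(i) for i in range(len(docs))]
    cols = [f"emb_{i}" for i in range(model.vector_size)]
    return FeatureMatrix(row_ids=ids, columns=cols, X=X, tag="EMB")
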