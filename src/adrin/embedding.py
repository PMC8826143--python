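"""Skip-gram word embeddings and cosine-similarity queries.

Two models back the identification pipeline: a *unigram* model over
single word tokens (vocabulary = words occurring at least twice) and a
*bigram* model in which frequently co-occurring adjacent word pairs
(more than five times, after stopword removal) are merged into phrase
tokens before training.  Both use skip-gram with negative sampling,
200-dimensional vectors, a 5-word window and 5 epochs by default.

The trainer is implemented directly (numba-compiled inner loop) rather
than through an external embedding library; single-worker training with
a fixed seed is bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from numba import njit

__all__ = [
    "EmbeddingConfig",
    "VectorStore",
    "ThresholdCurve",
    "cosine_similarity",
    "most_similar",
    "matches_above_threshold",
    "calibrate_threshold",
    "train_unigram",
    "train_bigram",
    "detect_phrases",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters of the skip-gram models.

    ``unigram_min_count=2`` implements the "occurred more than once"
    vocabulary rule; ``bigram_pair_min_count=6`` the "co-occurred more
    than five times" phrase rule.  ``negative``, ``sample`` and the
    learning-rate schedule cover parameters the method leaves at common
    word2vec defaults; they are recorded here so a run is reproducible
    from its config alone.
    """

    vector_dim: int = 200
    window: int = 5
    epochs: int = 5
    unigram_min_count: int = 2
    bigram_pair_min_count: int = 6
    seed: int = 0
    negative: int = 5
    sample: float = 1e-3
    alpha: float = 0.025
    min_alpha: float = 1e-4
    architecture: str = "skip-gram"

    def __post_init__(self) -> None:
        if self.vector_dim < 2:
            raise ValueError("vector_dim must be >= 2")
        for name in ("window", "epochs", "unigram_min_count",
                     "bigram_pair_min_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.architecture != "skip-gram":
            raise ValueError("only the skip-gram architecture is supported")


def cosine_similarity(v, w) -> float:
    """cos(v, w) = v·w / (|v||w|); raises on zero-norm input."""
    v = np.asarray(v, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0.0 or nw == 0.0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    return float(np.dot(v, w) / (nv * nw))


class VectorStore:
    """Vocabulary -> vector table with cosine-similarity queries."""

    def __init__(self, tokens: Sequence[str], vectors: np.ndarray):
        vectors = np.asarray(vectors, dtype=np.float32)
        if vectors.ndim != 2 or vectors.shape[0] != len(tokens):
            raise ValueError("vectors must be a (len(tokens), dim) matrix")
        if len(set(tokens)) != len(tokens):
            raise ValueError("duplicate tokens in vector store")
        if not np.all(np.isfinite(vectors)):
            raise ValueError("vectors must be finite")
        norms = np.linalg.norm(vectors, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero vectors are not allowed in a store")
        self.tokens: list[str] = list(tokens)
        self.vectors: np.ndarray = vectors
        self._index = {t: i for i, t in enumerate(self.tokens)}
        self._unit = vectors / norms[:, None]

    # -- basic container protocol -------------------------------------
    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self._index[token]]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None

    def unit_vector(self, token: str) -> np.ndarray:
        return self._unit[self._index[token]]

    def similarity(self, a: str, b: str) -> float:
        """Cosine similarity between two in-vocabulary tokens.

        Unit-safe: a token with itself is exactly 1.0.
        """
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            missing = a if ia is None else b
            raise KeyError(f"token {missing!r} not in vocabulary")
        if ia == ib:
            return 1.0
        return float(np.dot(self._unit[ia], self._unit[ib]))

    def all_similarities(self, token: str) -> np.ndarray:
        """Cosine of ``token`` against the whole vocabulary (float64)."""
        i = self._index.get(token)
        if i is None:
            raise KeyError(f"token {token!r} not in vocabulary")
        sims = self._unit.astype(np.float64) @ self._unit[i].astype(np.float64)
        sims[i] = 1.0
        return sims

    # -- word2vec text format -----------------------------------------
    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.tokens)} {self.dim}\n")
            for tok, vec in zip(self.tokens, self.vectors):
                fh.write(tok + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")

    @classmethod
    def load(cls, path) -> "VectorStore":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(
                    f"{path}: line 1: expected header 'V D', got "
                    f"{' '.join(header)!r}"
                )
            n, d = int(header[0]), int(header[1])
            tokens: list[str] = []
            vectors = np.empty((n, d), dtype=np.float32)
            for row in range(n):
                line = fh.readline()
                if not line:
                    raise ValueError(
                        f"{path}: line {row + 2}: unexpected end of file"
                    )
                parts = line.rstrip("\n").split(" ")
                if len(parts) != d + 1:
                    raise ValueError(
                        f"{path}: line {row + 2}: expected token + {d} "
                        f"floats, got {len(parts) - 1} values"
                    )
                tokens.append(parts[0])
                vectors[row] = [float(x) for x in parts[1:]]
        return cls(tokens, vectors)


def most_similar(
    store: VectorStore, term: str, k: int = 10
) -> list[tuple[str, float]]:
    """Top-``k`` vocabulary tokens by cosine to ``term`` (term excluded).

    Ties are broken lexicographically; ``k`` beyond the vocabulary size
    returns the full ranking.
    """
    sims = store.all_similarities(term)
    order = sorted(
        (i for i, t in enumerate(store.tokens) if t != term),
        key=lambda i: (-sims[i], store.tokens[i]),
    )
    return [(store.tokens[i], float(sims[i])) for i in order[:k]]


def matches_above_threshold(store: VectorStore, token: str, search_terms):
    """Best search term strictly above its own threshold, or ``None``.

    Search terms absent from the store's vocabulary are skipped (a
    lexicon may be broader than a small trained vocabulary).  Among the
    terms whose similarity to ``token`` strictly exceeds their per-term
    threshold, the pair with maximal similarity wins; equal similarities
    fall back to lexicographic term order.
    """
    if token not in store:
        raise KeyError(f"token {token!r} not in vocabulary")
    best: Optional[tuple[float, str]] = None
    for st in search_terms:
        if st.term not in store:
            continue
        sim = store.similarity(token, st.term)
        if sim > st.threshold:
            key = (-sim, st.term)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return best[1], -best[0]


@dataclass(frozen=True)
class ThresholdCurve:
    """Match counts of one term over a grid of candidate thresholds."""

    term: str
    grid: tuple[float, ...]
    match_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if list(self.grid) != sorted(self.grid):
            raise ValueError("grid must be sorted ascending")
        if any(
            b > a
            for a, b in zip(self.match_counts, self.match_counts[1:])
        ):
            raise ValueError("match_counts must be non-increasing")


def calibrate_threshold(
    store: VectorStore, term: str, grid: Sequence[float]
) -> ThresholdCurve:
    """Grid-search curve: how many vocabulary words sit at or above each
    candidate threshold (the term itself excluded).

    The curve (plotted against the grid) is the visual aid for choosing
    a per-term threshold: a knee where the count stops collapsing marks
    the transition from close variants to unrelated words.
    """
    sims = store.all_similarities(term)
    mask = np.array([t != term for t in store.tokens])
    counts = tuple(int(np.sum(sims[mask] >= g)) for g in grid)
    return ThresholdCurve(term=term, grid=tuple(grid), match_counts=counts)


# ---------------------------------------------------------------------
# Skip-gram training (negative sampling)
# ---------------------------------------------------------------------

_EXP_TABLE_SIZE = 1000
_MAX_EXP = 6.0
_EXP_TABLE = 1.0 / (
    1.0
    + np.exp(
        -(
            (np.arange(_EXP_TABLE_SIZE, dtype=np.float64) / _EXP_TABLE_SIZE)
            * 2
            - 1
        )
        * _MAX_EXP
    )
).astype(np.float64)
_EXP_TABLE = _EXP_TABLE.astype(np.float32)

_NEG_TABLE_SIZE = 1 << 20


@njit(cache=False)
def _sgns_train(
    data,           # int32[:] token ids, all sentences concatenated
    offsets,        # int64[:] sentence offsets, len n_sent+1
    W,              # float32[:, :] input vectors (the embeddings)
    C,              # float32[:, :] output vectors
    neg_table,      # int32[:] negative-sampling table
    keep_prob,      # float32[:] per-word subsampling keep probability
    exp_table,      # float32[:] sigmoid table
    epochs, window, negative, alpha, min_alpha, seed,
):
    dim = W.shape[1]
    total = np.int64(epochs) * np.int64(data.shape[0])
    processed = np.int64(0)
    lr = alpha
    state = np.uint64(seed * 2654435761 + 1)
    sent = np.empty(data.shape[0], dtype=np.int32)
    grad = np.empty(dim, dtype=np.float32)
    neg_mask = np.int64(neg_table.shape[0] - 1)

    for _epoch in range(epochs):
        for s in range(offsets.shape[0] - 1):
            # subsample frequent words (fresh draw every epoch)
            m = 0
            for j in range(offsets[s], offsets[s + 1]):
                processed += 1
                w = data[j]
                if keep_prob[w] < 1.0:
                    state = state * np.uint64(6364136223846793005) + np.uint64(
                        1442695040888963407
                    )
                    r = np.float32(
                        np.uint32(state >> np.uint64(33))
                    ) / np.float32(2147483648.0)
                    if r >= keep_prob[w]:
                        continue
                sent[m] = w
                m += 1
            frac = processed / total
            lr = alpha - (alpha - min_alpha) * frac
            if lr < min_alpha:
                lr = min_alpha
            for i in range(m):
                center = sent[i]
                state = state * np.uint64(6364136223846793005) + np.uint64(
                    1442695040888963407
                )
                b = 1 + np.int64(state >> np.uint64(33)) % window
                lo = i - b
                if lo < 0:
                    lo = 0
                hi = i + b + 1
                if hi > m:
                    hi = m
                for k in range(lo, hi):
                    if k == i:
                        continue
                    context = sent[k]
                    # one positive + `negative` sampled updates
                    for d in range(dim):
                        grad[d] = 0.0
                    for nidx in range(negative + 1):
                        if nidx == 0:
                            target = context
                            label = np.float32(1.0)
                        else:
                            state = state * np.uint64(
                                6364136223846793005
                            ) + np.uint64(1442695040888963407)
                            target = neg_table[
                                np.int64(state >> np.uint64(33)) & neg_mask
                            ]
                            if target == context:
                                continue
                            label = np.float32(0.0)
                        dot = np.float32(0.0)
                        for d in range(dim):
                            dot += W[center, d] * C[target, d]
                        if dot > _MAX_EXP:
                            pred = np.float32(1.0)
                        elif dot < -_MAX_EXP:
                            pred = np.float32(0.0)
                        else:
                            pred = exp_table[
                                np.int64(
                                    (dot + _MAX_EXP)
                                    * (_EXP_TABLE_SIZE / (2 * _MAX_EXP))
                                )
                            ]
                        g = (label - pred) * np.float32(lr)
                        for d in range(dim):
                            grad[d] += g * C[target, d]
                            C[target, d] += g * W[center, d]
                    for d in range(dim):
                        W[center, d] += grad[d]


def _build_vocab(
    sentences: list[list[str]], min_count: int
) -> tuple[list[str], dict[str, int], np.ndarray]:
    freq: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            freq[tok] = freq.get(tok, 0) + 1
    vocab = sorted(t for t, c in freq.items() if c >= min_count)
    index = {t: i for i, t in enumerate(vocab)}
    counts = np.array([freq[t] for t in vocab], dtype=np.int64)
    return vocab, index, counts


def _train(sentences: list[list[str]], cfg: EmbeddingConfig,
           min_count: int) -> VectorStore:
    vocab, index, counts = _build_vocab(sentences, min_count)
    if not vocab:
        raise ValueError(
            "no token reaches the minimum corpus frequency; "
            "corpus too small to train on"
        )

    encoded: list[np.ndarray] = []
    for sent in sentences:
        ids = [index[t] for t in sent if t in index]
        if ids:
            encoded.append(np.array(ids, dtype=np.int32))
    data = (
        np.concatenate(encoded) if encoded else np.empty(0, dtype=np.int32)
    )
    offsets = np.zeros(len(encoded) + 1, dtype=np.int64)
    np.cumsum([len(e) for e in encoded], out=offsets[1:])

    # negative-sampling table, unigram^{3/4}
    pow_freq = counts.astype(np.float64) ** 0.75
    cum = np.cumsum(pow_freq / pow_freq.sum())
    positions = (np.arange(_NEG_TABLE_SIZE) + 0.5) / _NEG_TABLE_SIZE
    neg_table = np.searchsorted(cum, positions).astype(np.int32)

    # subsampling keep probabilities (word2vec formula, clipped to 1)
    if cfg.sample > 0:
        f = counts / counts.sum()
        ratio = cfg.sample / f
        keep = np.sqrt(ratio) + ratio
        keep_prob = np.minimum(keep, 1.0).astype(np.float32)
    else:
        keep_prob = np.ones(len(vocab), dtype=np.float32)

    rng = np.random.default_rng(cfg.seed)
    W = (
        (rng.random((len(vocab), cfg.vector_dim), dtype=np.float32) - 0.5)
        / cfg.vector_dim
    )
    C = np.zeros((len(vocab), cfg.vector_dim), dtype=np.float32)

    _sgns_train(
        data, offsets, W, C, neg_table, keep_prob, _EXP_TABLE,
        cfg.epochs, cfg.window, cfg.negative,
        np.float32(cfg.alpha), np.float32(cfg.min_alpha),
        cfg.seed,
    )
    # guard against any degenerate all-zero row (never updated + unlucky
    # init is impossible since init is nonzero, but norms stay finite)
    return VectorStore(vocab, W)


def _as_sentences(corpus) -> list[list[str]]:
    sentences: list[list[str]] = []
    for note in corpus:
        toks = list(note.tokens) if hasattr(note, "tokens") else list(note)
        if toks:
            sentences.append([str(t) for t in toks])
    return sentences


def train_unigram(corpus, cfg: EmbeddingConfig = EmbeddingConfig()) -> VectorStore:
    """Train the unigram skip-gram model over processed notes.

    The vocabulary keeps every token with corpus frequency >= 2 (by
    default).  Each note is one window-bounded training sentence.
    Deterministic for a fixed ``cfg.seed`` (single-threaded).
    """
    sentences = _as_sentences(corpus)
    if not sentences:
        raise ValueError("cannot train on an empty corpus")
    return _train(sentences, cfg, cfg.unigram_min_count)


def detect_phrases(
    sentences: list[list[str]], min_pair_count: int
) -> set[tuple[str, str]]:
    """Adjacent pairs whose co-occurrence count reaches ``min_pair_count``."""
    pair_counts: dict[tuple[str, str], int] = {}
    for sent in sentences:
        for a, b in zip(sent, sent[1:]):
            pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    return {p for p, c in pair_counts.items() if c >= min_pair_count}


def merge_phrases(
    sent: list[str], phrases: set[tuple[str, str]]
) -> list[str]:
    """Greedy left-to-right merge of detected phrases into ``a_b`` tokens."""
    out: list[str] = []
    i = 0
    while i < len(sent):
        if i + 1 < len(sent) and (sent[i], sent[i + 1]) in phrases:
            out.append(sent[i] + "_" + sent[i + 1])
            i += 2
        else:
            out.append(sent[i])
            i += 1
    return out


def train_bigram(
    corpus,
    cfg: EmbeddingConfig = EmbeddingConfig(),
    stopwords: Iterable[str] = (),
) -> VectorStore:
    """Train the phrase-augmented skip-gram model.

    Stopwords are removed from the token streams first; adjacent pairs
    that then co-occur more than five times (>= ``bigram_pair_min_count``)
    become single ``a_b`` phrase tokens, and skip-gram is trained over
    the mixed unigram/phrase stream.
    """
    stopset = frozenset(stopwords)
    sentences = [
        [t for t in sent if t not in stopset]
        for sent in _as_sentences(corpus)
    ]
    sentences = [s for s in sentences if s]
    if not sentences:
        raise ValueError("cannot train on an empty corpus")
    phrases = detect_phrases(sentences, cfg.bigram_pair_min_count)
    merged = [merge_phrases(s, phrases) for s in sentences]
    return _train(merged, cfg, cfg.unigram_min_count)
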