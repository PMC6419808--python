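"""The vector-k-mers model.

A shallow network (CBOW with hierarchical softmax) is trained separately
on the sentence corpora of each class, yielding two geometric spaces of
k-mer vectors: V_regulatory and V_random. A new sequence is scored in
each space by the mean log-probability of every token given its local
context (a composite likelihood over sliding windows within each of the
k sentences), and the two composite likelihoods are inverted through
Bayes' rule with a uniform class prior to yield the posterior probability
that the sequence is regulatory.

The spaces double as interpretable objects: cosine neighbourhoods group
k-mers that occur in interchangeable local contexts, and window/corpus
centroids support alignment-free similarity ranking across genomes.
"""

from __future__ import annotations

import json
import zlib
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _word2vec as w2v
from .seqio import Sentence, SequenceRecord, tokenize_bag, tokenize_sentences

__all__ = [
    "EmbeddingSpace",
    "ClassPosterior",
    "train_embedding",
    "sentence_loglik",
    "classify_sequence",
    "classify_records",
    "vec_profile",
    "nearest_kmers",
    "centroid_similarity",
    "corpus_centroid",
    "ranklist_dissimilarity",
]

REGULATORY, RANDOM = "regulatory", "random"


class EmbeddingSpace:
    """Token vectors plus the hierarchical-softmax likelihood machinery."""

    def __init__(
        self,
        tokens: Sequence[str],
        counts: np.ndarray,
        syn0: np.ndarray,
        syn1: np.ndarray,
        k: int,
        window: int,
        epochs: int,
        seed: int,
    ):
        self.tokens = tuple(tokens)
        self.index = {t: i for i, t in enumerate(self.tokens)}
        self.counts = np.asarray(counts, dtype=np.int64)
        self.syn0 = syn0
        self.syn1 = syn1
        self.k = k
        self.window = window
        self.epochs = epochs
        self.seed = seed
        self.points, self.codes, self.path_len = w2v.build_huffman(self.counts)

    # -- basic access -------------------------------------------------
    @property
    def dim(self) -> int:
        return self.syn0.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __len__(self) -> int:
        return len(self.tokens)

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.syn0[self.index[token]]
        except KeyError:
            raise KeyError(f"token {token!r} not in embedding space") from None

    def centroid(self, tokens: Iterable[str]) -> np.ndarray:
        """Mean vector of the known tokens in a window."""
        rows = [self.index[t] for t in tokens if t in self.index]
        if not rows:
            raise ValueError("no known tokens in window")
        return self.syn0[rows].mean(axis=0)

    # -- likelihoods ---------------------------------------------------
    def _sentence_ids(self, tokens: Sequence[str]) -> np.ndarray:
        return np.asarray(
            [self.index[t] for t in tokens if t in self.index], dtype=np.int64
        )

    def sentence_logliks(self, sentences: Sequence[Sentence]) -> np.ndarray:
        """Mean window log-likelihood per sentence; NaN where undefined
        (fewer than 2 in-vocabulary tokens)."""
        ids_parts: list[np.ndarray] = []
        offsets = [0]
        for sent in sentences:
            toks = sent.tokens if isinstance(sent, Sentence) else tuple(sent)
            ids = self._sentence_ids(toks)
            if len(ids) < 2:
                ids = np.empty(0, dtype=np.int64)  # scores NaN
            ids_parts.append(ids)
            offsets.append(offsets[-1] + len(ids))
        flat = (
            np.concatenate(ids_parts) if ids_parts else np.empty(0, dtype=np.int64)
        )
        return w2v.score_sentences(
            flat,
            np.asarray(offsets, dtype=np.int64),
            self.syn0,
            self.syn1,
            self.points,
            self.codes,
            self.path_len,
            self.window,
        )

    def log_prob(self, target: str, context: Sequence[str]) -> float:
        """log P(target | explicit context tokens); exact HS normalization
        means exp of this sums to 1 over the vocabulary."""
        if target not in self.index:
            raise KeyError(f"unknown target token {target!r}")
        ctx = self._sentence_ids(context)
        return w2v.hs_log_prob(
            self.index[target], ctx, self.syn0, self.syn1,
            self.points, self.codes, self.path_len,
        )

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        config = {
            "k": self.k, "window": self.window, "epochs": self.epochs,
            "seed": self.seed, "dim": self.dim, "format_version": 1,
        }
        np.savez_compressed(
            path,
            config=json.dumps(config),
            tokens=np.array(self.tokens),
            counts=self.counts,
            syn0=self.syn0,
            syn1=self.syn1,
        )

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingSpace":
        with np.load(path, allow_pickle=False) as archive:
            config = json.loads(str(archive["config"]))
            return cls(
                tokens=[str(t) for t in archive["tokens"]],
                counts=archive["counts"],
                syn0=archive["syn0"],
                syn1=archive["syn1"],
                k=config["k"],
                window=config["window"],
                epochs=config["epochs"],
                seed=config["seed"],
            )

    def export_word_vectors(self, path: str | Path) -> None:
        """Plain word2vec text format (header line, then token + floats)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.tokens)} {self.dim}\n")
            for i, t in enumerate(self.tokens):
                vec = " ".join(f"{x:.6f}" for x in self.syn0[i])
                fh.write(f"{t} {vec}\n")


def _seeded_init(tokens: Sequence[str], d: int, seed: int) -> np.ndarray:
    """Per-token hash-seeded uniform init in [-0.5/d, 0.5/d).

    Seeding each vector from (token, seed) rather than from the matrix
    position means a token shared by the regulatory and random corpora
    starts from the same point in both spaces; likelihood differences
    between the spaces then reflect learned co-occurrence structure, not
    initialization noise.
    """
    syn0 = np.empty((len(tokens), d), dtype=np.float64)
    for i, t in enumerate(tokens):
        token_seed = zlib.crc32(f"{t}|{seed}".encode()) & 0x7FFFFFFF
        syn0[i] = np.random.default_rng(token_seed).random(d)
    return (syn0 - 0.5) / d


def _corpus_from(records: Sequence, k: int) -> list[tuple[str, ...]]:
    """Sentence corpus from records, raw sequences or ready-made sentences."""
    corpus: list[tuple[str, ...]] = []
    for item in records:
        if isinstance(item, SequenceRecord):
            corpus.extend(s.tokens for s in tokenize_sentences(item.seq, k))
        elif isinstance(item, str):
            corpus.extend(s.tokens for s in tokenize_sentences(item, k))
        elif isinstance(item, Sentence):
            corpus.append(item.tokens)
        else:
            corpus.append(tuple(item))
    return corpus


def train_embedding(
    records: Sequence,
    k: int = 8,
    d: int = 300,
    window: int = 5,
    epochs: int = 30,
    seed: int = 0,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
) -> EmbeddingSpace:
    """Train one embedding space on a class corpus.

    Accepts sequence records, raw sequences, or pre-tokenized sentences.
    All tokens are kept (min_count = 0). Training is in-order and
    single-threaded, so identical (corpus, seed, parameters) give
    identical vectors.
    """
    corpus = _corpus_from(records, k)
    counts = Counter(t for sent in corpus for t in sent)
    if not counts:
        raise ValueError("empty training corpus")
    tokens = sorted(counts, key=lambda t: (-counts[t], t))
    index = {t: i for i, t in enumerate(tokens)}
    count_arr = np.asarray([counts[t] for t in tokens], dtype=np.int64)

    syn0 = _seeded_init(tokens, d, seed)
    syn1 = np.zeros((max(len(tokens) - 1, 1), d), dtype=np.float64)

    ids_parts = [np.asarray([index[t] for t in sent], dtype=np.int64) for sent in corpus]
    offsets = np.zeros(len(ids_parts) + 1, dtype=np.int64)
    np.cumsum([len(p) for p in ids_parts], out=offsets[1:])
    flat = np.concatenate(ids_parts)

    points, codes, path_len = w2v.build_huffman(count_arr)
    w2v.train_cbow_hs(
        flat, offsets, syn0, syn1, points, codes, path_len,
        window, epochs, alpha, min_alpha,
    )
    return EmbeddingSpace(
        tokens=tokens, counts=count_arr, syn0=syn0, syn1=syn1,
        k=k, window=window, epochs=epochs, seed=seed,
    )


def sentence_loglik(space: EmbeddingSpace, sentence: Sentence | Sequence[str]) -> float:
    """Mean sliding-window log-likelihood of one sentence; NaN flags an
    undefined likelihood (fewer than 2 in-vocabulary tokens)."""
    toks = sentence.tokens if isinstance(sentence, Sentence) else tuple(sentence)
    return float(space.sentence_logliks([Sentence(tokens=toks, offset=0)])[0])


@dataclass(frozen=True)
class ClassPosterior:
    """Bayes-inverted class probabilities for one sequence."""

    p_regulatory: float
    p_random: float
    loglik_regulatory: float
    loglik_random: float

    def __post_init__(self) -> None:
        assert abs(self.p_regulatory + self.p_random - 1.0) < 1e-9


def _posterior_from_logliks(l_reg: float, l_rand: float) -> ClassPosterior:
    # uniform prior 1/C with C = 2; log-sum-exp for stability
    log_prior = np.log(0.5)
    scores = np.array([l_reg + log_prior, l_rand + log_prior])
    m = scores.max()
    p = np.exp(scores - m)
    p /= p.sum()
    return ClassPosterior(
        p_regulatory=float(p[0]),
        p_random=float(p[1]),
        loglik_regulatory=l_reg,
        loglik_random=l_rand,
    )


def classify_sequence(
    spaces: Mapping[str, EmbeddingSpace], seq: str, k: int | None = None
) -> ClassPosterior:
    """Posterior P(regulatory | sequence) via composite-likelihood Bayes
    inversion over the two spaces.

    The sequence is broken into its k sentences; each space assigns every
    sentence a mean window log-likelihood; per-class scores are the means
    over sentences defined in both spaces.
    """
    reg, rand = spaces[REGULATORY], spaces[RANDOM]
    if reg.k != rand.k:
        raise ValueError("the two spaces were trained with different k")
    k = reg.k if k is None else k
    sentences = tokenize_sentences(seq, k)
    ll_reg = reg.sentence_logliks(sentences)
    ll_rand = rand.sentence_logliks(sentences)
    valid = ~(np.isnan(ll_reg) | np.isnan(ll_rand))
    if not valid.any():
        raise ValueError("no sentence scoreable in both spaces")
    return _posterior_from_logliks(
        float(ll_reg[valid].mean()), float(ll_rand[valid].mean())
    )


def classify_records(
    spaces: Mapping[str, EmbeddingSpace], records: Sequence, k: int | None = None
) -> np.ndarray:
    """P(regulatory) for each record; NaN where no sentence is scoreable."""
    out = np.empty(len(records))
    for i, rec in enumerate(records):
        seq = rec.seq if isinstance(rec, SequenceRecord) else rec
        try:
            out[i] = classify_sequence(spaces, seq, k).p_regulatory
        except ValueError:
            out[i] = np.nan
    return out


def vec_profile(
    spaces: Mapping[str, EmbeddingSpace], seq: str, k: int | None = None, group: int = 3
) -> np.ndarray:
    """Per-base regulatory-probability track.

    Every 1-bp-stride window of length group*k (co-occurrence of
    ``group`` adjacent k-mers) is classified; each base reports the mean
    posterior over the windows covering it.
    """
    k = spaces[REGULATORY].k if k is None else k
    span = group * k
    if len(seq) < span:
        raise ValueError(f"sequence shorter than group*k = {span}")
    n_windows = len(seq) - span + 1
    probs = np.full(n_windows, np.nan)
    for i in range(n_windows):
        try:
            probs[i] = classify_sequence(spaces, seq[i : i + span], k).p_regulatory
        except ValueError:
            pass
    track = np.zeros(len(seq))
    cover = np.zeros(len(seq))
    for i in range(n_windows):
        if not np.isnan(probs[i]):
            track[i : i + span] += probs[i]
            cover[i : i + span] += 1.0
    cover[cover == 0] = np.nan
    return track / cover


def nearest_kmers(
    space: EmbeddingSpace, token: str, topN: int = 5
) -> list[tuple[str, float]]:
    """Top-N tokens by cosine similarity to ``token`` (query excluded,
    ties broken lexicographically)."""
    q = space.vector(token)
    norms = np.linalg.norm(space.syn0, axis=1)
    qn = np.linalg.norm(q)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = (space.syn0 @ q) / (norms * qn)
    sims = np.nan_to_num(sims, nan=-1.0)
    order = sorted(
        (i for i in range(len(space)) if space.tokens[i] != token),
        key=lambda i: (-sims[i], space.tokens[i]),
    )
    return [(space.tokens[i], float(sims[i])) for i in order[:topN]]


def centroid_similarity(
    space: EmbeddingSpace,
    window_tokens: Iterable[str],
    reference_centroid: np.ndarray,
) -> float:
    """Cosine distance in [0, 2] between a window's token centroid and a
    reference centroid (0 = identical direction)."""
    c = space.centroid(window_tokens)
    denom = np.linalg.norm(c) * np.linalg.norm(reference_centroid)
    if denom == 0:
        raise ValueError("zero-norm centroid")
    return float(1.0 - (c @ reference_centroid) / denom)


def corpus_centroid(
    space: EmbeddingSpace, records: Sequence, k: int | None = None
) -> np.ndarray:
    """Occurrence-weighted mean k-mer vector of a set of sequences — the
    reference point for cross-genome similarity ranking."""
    k = space.k if k is None else k
    all_tokens: list[str] = []
    for rec in records:
        seq = rec.seq if isinstance(rec, SequenceRecord) else rec
        all_tokens.extend(tokenize_bag(seq, k))
    return space.centroid(all_tokens)


def ranklist_dissimilarity(
    listA: Sequence[str], listB: Sequence[str], topN: int = 10
) -> float:
    """Jaccard dissimilarity of the truncated neighbour lists: 0 when the
    top-N sets coincide, 1 when disjoint."""
    if not listA or not listB:
        raise ValueError("empty ranked list")
    a, b = set(listA[:topN]), set(listB[:topN])
    return 1.0 - len(a & b) / len(a | b)
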