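"""CBOW word2vec with hierarchical softmax, for k-mer token corpora.

Single-threaded, seeded and fully deterministic: the corpus is traversed
in order with a fixed (non-shrinking) context window and the learning rate
decays linearly per processed token. The hierarchical softmax factorizes
P(target | context) along a Huffman tree over token frequencies, so
probabilities over the vocabulary sum to one by construction; the same
tree supplies the composite-likelihood score used for classification.

Hot loops are numba-compiled; everything operates on integer token ids.
"""

from __future__ import annotations

import heapq

import numpy as np
from numba import njit

__all__ = [
    "build_huffman",
    "train_cbow_hs",
    "score_sentences",
    "hs_log_prob",
]


def build_huffman(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Huffman coding of the vocabulary by token frequency.

    Returns (points, codes, path_len): for leaf (token) i, points[i, :L]
    are the inner-node indices from the root down to the leaf's parent and
    codes[i, :L] the corresponding branch bits. Ties broken by insertion
    id for determinism. A single-token vocabulary gets an empty path
    (its probability is 1).
    """
    V = len(counts)
    if V == 0:
        raise ValueError("empty vocabulary")
    if V == 1:
        return (
            np.zeros((1, 0), dtype=np.int32),
            np.zeros((1, 0), dtype=np.int8),
            np.zeros(1, dtype=np.int32),
        )
    parent = np.zeros(2 * V - 1, dtype=np.int64)
    branch = np.zeros(2 * V - 1, dtype=np.int8)
    heap: list[tuple[int, int]] = [(int(c), i) for i, c in enumerate(counts)]
    heapq.heapify(heap)
    next_id = V
    while len(heap) > 1:
        c1, n1 = heapq.heappop(heap)
        c2, n2 = heapq.heappop(heap)
        parent[n1] = next_id
        parent[n2] = next_id
        branch[n2] = 1
        heapq.heappush(heap, (c1 + c2, next_id))
        next_id += 1
    root = 2 * V - 2

    paths: list[list[int]] = []
    codes_l: list[list[int]] = []
    for leaf in range(V):
        code: list[int] = []
        pts: list[int] = []
        node = leaf
        while node != root:
            code.append(int(branch[node]))
            node = int(parent[node])
            pts.append(node - V)  # inner nodes indexed 0..V-2
        paths.append(pts[::-1])
        codes_l.append(code[::-1])

    max_len = max(len(p) for p in paths)
    points = np.zeros((V, max_len), dtype=np.int32)
    codes = np.zeros((V, max_len), dtype=np.int8)
    path_len = np.zeros(V, dtype=np.int32)
    for i, (pts, code) in enumerate(zip(paths, codes_l)):
        path_len[i] = len(pts)
        points[i, : len(pts)] = pts
        codes[i, : len(code)] = code
    return points, codes, path_len


@njit(cache=True, fastmath=False)
def _log_sigmoid(x: float) -> float:
    if x >= 0.0:
        return -np.log1p(np.exp(-x))
    return x - np.log1p(np.exp(x))


@njit(cache=True)
def train_cbow_hs(
    ids: np.ndarray,
    sent_offsets: np.ndarray,
    syn0: np.ndarray,
    syn1: np.ndarray,
    points: np.ndarray,
    codes: np.ndarray,
    path_len: np.ndarray,
    window: int,
    epochs: int,
    alpha0: float,
    min_alpha: float,
) -> None:
    """In-place SGD training of input (syn0) and inner-node (syn1) vectors.

    ``ids`` is the whole corpus flattened; ``sent_offsets`` delimits
    sentences (contexts never cross sentence boundaries). CBOW: the mean
    of the context vectors predicts the target through its Huffman path.
    """
    d = syn0.shape[1]
    n_tokens = len(ids)
    total = epochs * n_tokens
    processed = 0
    neu1 = np.zeros(d)
    neu1e = np.zeros(d)
    for _ in range(epochs):
        for s in range(len(sent_offsets) - 1):
            lo = sent_offsets[s]
            hi = sent_offsets[s + 1]
            for pos in range(lo, hi):
                alpha = alpha0 - (alpha0 - min_alpha) * processed / total
                if alpha < min_alpha:
                    alpha = min_alpha
                processed += 1
                target = ids[pos]
                c_lo = pos - window
                if c_lo < lo:
                    c_lo = lo
                c_hi = pos + window + 1
                if c_hi > hi:
                    c_hi = hi
                cn = 0
                for j in range(d):
                    neu1[j] = 0.0
                    neu1e[j] = 0.0
                for c in range(c_lo, c_hi):
                    if c == pos:
                        continue
                    w = ids[c]
                    for j in range(d):
                        neu1[j] += syn0[w, j]
                    cn += 1
                if cn == 0:
                    continue
                inv = 1.0 / cn
                for j in range(d):
                    neu1[j] *= inv
                for p in range(path_len[target]):
                    node = points[target, p]
                    dot = 0.0
                    for j in range(d):
                        dot += neu1[j] * syn1[node, j]
                    f = 1.0 / (1.0 + np.exp(-dot))
                    g = (1.0 - codes[target, p] - f) * alpha
                    for j in range(d):
                        neu1e[j] += g * syn1[node, j]
                    for j in range(d):
                        syn1[node, j] += g * neu1[j]
                for c in range(c_lo, c_hi):
                    if c == pos:
                        continue
                    w = ids[c]
                    for j in range(d):
                        syn0[w, j] += neu1e[j]


@njit(cache=True)
def _window_log_prob(
    ids: np.ndarray,
    pos: int,
    lo: int,
    hi: int,
    syn0: np.ndarray,
    syn1: np.ndarray,
    points: np.ndarray,
    codes: np.ndarray,
    path_len: np.ndarray,
    window: int,
    neu1: np.ndarray,
) -> float:
    """log P(ids[pos] | context) under hierarchical softmax; NaN if the
    target has no context tokens."""
    d = syn0.shape[1]
    c_lo = pos - window
    if c_lo < lo:
        c_lo = lo
    c_hi = pos + window + 1
    if c_hi > hi:
        c_hi = hi
    cn = 0
    for j in range(d):
        neu1[j] = 0.0
    for c in range(c_lo, c_hi):
        if c == pos:
            continue
        for j in range(d):
            neu1[j] += syn0[ids[c], j]
        cn += 1
    if cn == 0:
        return np.nan
    inv = 1.0 / cn
    for j in range(d):
        neu1[j] *= inv
    target = ids[pos]
    lp = 0.0
    for p in range(path_len[target]):
        node = points[target, p]
        dot = 0.0
        for j in range(d):
            dot += neu1[j] * syn1[node, j]
        sign = 1.0 - 2.0 * codes[target, p]
        lp += _log_sigmoid(sign * dot)
    return lp


@njit(cache=True)
def score_sentences(
    ids: np.ndarray,
    sent_offsets: np.ndarray,
    syn0: np.ndarray,
    syn1: np.ndarray,
    points: np.ndarray,
    codes: np.ndarray,
    path_len: np.ndarray,
    window: int,
) -> np.ndarray:
    """Mean sliding-window target log-probability per sentence.

    Sentences whose every position lacks context (fewer than 2 tokens)
    score NaN, flagging an undefined likelihood.
    """
    n_sent = len(sent_offsets) - 1
    out = np.full(n_sent, np.nan)
    d = syn0.shape[1]
    neu1 = np.zeros(d)
    for s in range(n_sent):
        lo = sent_offsets[s]
        hi = sent_offsets[s + 1]
        total = 0.0
        cnt = 0
        for pos in range(lo, hi):
            lp = _window_log_prob(
                ids, pos, lo, hi, syn0, syn1, points, codes, path_len, window, neu1
            )
            if not np.isnan(lp):
                total += lp
                cnt += 1
        if cnt > 0:
            out[s] = total / cnt
    return out


def hs_log_prob(
    target_id: int,
    context_ids: np.ndarray,
    syn0: np.ndarray,
    syn1: np.ndarray,
    points: np.ndarray,
    codes: np.ndarray,
    path_len: np.ndarray,
) -> float:
    """log P(target | context) for an explicit context (pure-python path,
    used for normalization checks and ad-hoc queries)."""
    if len(context_ids) == 0:
        raise ValueError("empty context")
    h = syn0[np.asarray(context_ids)].mean(axis=0)
    lp = 0.0
    for p in range(path_len[target_id]):
        node = points[target_id, p]
        dot = float(h @ syn1[node])
        sign = 1.0 - 2.0 * float(codes[target_id, p])
        lp += float(-np.log1p(np.exp(-sign * dot))) if sign * dot >= 0 else float(
            sign * dot - np.log1p(np.exp(sign * dot))
        )
    return lp
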