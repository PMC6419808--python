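"""The bag-of-k-mers classifier.

Each sequence becomes a sparse vector of TF*IDF-weighted canonical k-mer
frequencies; an L2-regularized logistic regression separates regulatory
from control sequences. Because features are individual k-mers, the fitted
beta coefficients read directly as per-k-mer enrichment scores: large
positive scores mark words enriched in regulatory regions, large negative
ones words enriched in the background.

Two TF*IDF conventions are supported:

* ``convention="sklearn"`` (default) — smoothed idf with the +1 addend and
  L2 row normalization, i.e. tf * (ln((1+|S|)/(1+df)) + 1), rows scaled to
  unit norm;
* ``convention="raw"`` — the plain product tf * ln((1+|S|)/(df+1)) with no
  normalization.

Training document frequencies are frozen into the model so holdout and
genome-scan data are transformed exactly as the training set was.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .complexity import shannon_entropy
from .seqio import SequenceRecord, gc_content, tokenize_bag

__all__ = [
    "VocabularyIndex",
    "build_vocabulary",
    "count_matrix",
    "tfidf_transform",
    "BagModel",
    "fit_bag_classifier",
    "bag_profile",
]

DEFAULT_C_GRID = tuple(10.0 ** e for e in range(-3, 4))

REGULATORY, CONTROL = 1, 0


class VocabularyIndex:
    """Ordered, bijective token -> column mapping (sorted for stability)."""

    def __init__(self, tokens: Iterable[str], k: int, filtered: bool = False):
        self.tokens: tuple[str, ...] = tuple(sorted(set(tokens)))
        self.index: dict[str, int] = {t: i for i, t in enumerate(self.tokens)}
        self.k = k
        self.filtered = filtered
        if any(len(t) != k for t in self.tokens):
            raise ValueError("all vocabulary tokens must have length k")

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index


def build_vocabulary(
    token_lists: Sequence[Sequence[str]],
    k: int,
    allowed: set[str] | None = None,
) -> VocabularyIndex:
    """Vocabulary of observed tokens, optionally restricted to ``allowed``
    (the complexity-filtered set)."""
    seen: set[str] = set()
    for toks in token_lists:
        seen.update(toks)
    if allowed is not None:
        seen &= allowed
    if not seen:
        raise ValueError("empty vocabulary")
    return VocabularyIndex(seen, k=k, filtered=allowed is not None)


def count_matrix(
    token_lists: Sequence[Sequence[str]], vocab: VocabularyIndex
) -> sp.csr_matrix:
    """Sparse raw token counts, rows = sequences, columns = vocabulary."""
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    for toks in token_lists:
        row: dict[int, int] = {}
        for t in toks:
            j = vocab.index.get(t)
            if j is not None:
                row[j] = row.get(j, 0) + 1
        indices.extend(row.keys())
        data.extend(row.values())
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data, dtype=np.float64), indices, indptr),
        shape=(len(token_lists), len(vocab)),
    )


def tfidf_transform(
    token_lists: Sequence[Sequence[str]],
    vocab: VocabularyIndex,
    convention: str = "sklearn",
    frozen_df: np.ndarray | None = None,
    frozen_n_docs: int | None = None,
) -> tuple[sp.csr_matrix, np.ndarray, int]:
    """TF*IDF weight matrix plus the document frequencies used.

    When ``frozen_df``/``frozen_n_docs`` are given (holdout mode), idf is
    computed from the training corpus statistics instead of the data being
    transformed.
    """
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    if convention not in ("sklearn", "raw"):
        raise ValueError(f"unknown TF*IDF convention {convention!r}")
    counts = count_matrix(token_lists, vocab)
    if frozen_df is not None:
        df = np.asarray(frozen_df, dtype=np.float64)
        n_docs = int(frozen_n_docs)
    else:
        df = np.asarray((counts > 0).sum(axis=0)).ravel().astype(np.float64)
        n_docs = counts.shape[0]
    idf = np.log((1.0 + n_docs) / (df + 1.0))
    if convention == "sklearn":
        idf = idf + 1.0
    X = counts.multiply(idf).tocsr()
    if convention == "sklearn":
        norms = sp.linalg.norm(X, axis=1)
        norms[norms == 0] = 1.0
        X = sp.diags(1.0 / norms) @ X
        X = sp.csr_matrix(X)
    return X, df, n_docs


@dataclass
class BagModel:
    """Trained bag-of-k-mers classifier with frozen corpus statistics."""

    vocab: VocabularyIndex
    beta: np.ndarray
    intercept: float
    C: float
    convention: str
    df: np.ndarray
    n_docs: int
    cv_results: pd.DataFrame | None = None

    @property
    def k(self) -> int:
        return self.vocab.k

    def _records_to_tokens(self, records: Sequence) -> list[list[str]]:
        out = []
        for rec in records:
            seq = rec.seq if isinstance(rec, SequenceRecord) else rec
            out.append(tokenize_bag(seq, self.k))
        return out

    def transform(self, records: Sequence) -> sp.csr_matrix:
        token_lists = self._records_to_tokens(records)
        X, _, _ = tfidf_transform(
            token_lists, self.vocab, convention=self.convention,
            frozen_df=self.df, frozen_n_docs=self.n_docs,
        )
        return X

    def decision_function(self, records: Sequence) -> np.ndarray:
        X = self.transform(records)
        return np.asarray(X @ self.beta).ravel() + self.intercept

    def predict_proba(self, records: Sequence) -> np.ndarray:
        """P(regulatory) per record; P(control) is the complement."""
        z = self.decision_function(records)
        return 1.0 / (1.0 + np.exp(-z))

    def kmer_score_table(self) -> pd.DataFrame:
        """Scored vocabulary: token, beta, entropy, GC — sorted by beta
        descending. The interpretable output of the model."""
        rows = [
            {
                "token": t,
                "beta": float(self.beta[i]),
                "entropy": shannon_entropy(t),
                "gc": gc_content(t),
            }
            for i, t in enumerate(self.vocab.tokens)
        ]
        table = pd.DataFrame(rows).sort_values(
            "beta", ascending=False, kind="mergesort", ignore_index=True
        )
        return table

    def save(self, path: str | Path) -> None:
        config = {
            "k": self.k,
            "filtered": self.vocab.filtered,
            "C": self.C,
            "convention": self.convention,
            "intercept": self.intercept,
            "n_docs": self.n_docs,
            "format_version": 1,
        }
        np.savez_compressed(
            path,
            config=json.dumps(config),
            tokens=np.array(self.vocab.tokens),
            beta=self.beta,
            df=self.df,
        )

    @classmethod
    def load(cls, path: str | Path) -> "BagModel":
        with np.load(path, allow_pickle=False) as archive:
            config = json.loads(str(archive["config"]))
            tokens = [str(t) for t in archive["tokens"]]
            beta = archive["beta"]
            df = archive["df"]
        vocab = VocabularyIndex(tokens, k=config["k"], filtered=config["filtered"])
        return cls(
            vocab=vocab,
            beta=beta,
            intercept=config["intercept"],
            C=config["C"],
            convention=config["convention"],
            df=df,
            n_docs=config["n_docs"],
        )


def fit_bag_classifier(
    records: Sequence[SequenceRecord],
    labels: Sequence[int] | None = None,
    k: int = 8,
    allowed_vocab: set[str] | None = None,
    convention: str = "sklearn",
    folds: int = 5,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
) -> BagModel:
    """Fit the TF*IDF + logistic model with cross-validated regularization.

    The inverse regularization strength C is chosen by ``folds``-fold
    stratified CV grid search on accuracy, then the model is refit on the
    full training set. Labels default to the records' region labels
    (regulatory=1, control=0).
    """
    if labels is None:
        labels = [REGULATORY if r.region.label == "regulatory" else CONTROL for r in records]
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    token_lists = [
        tokenize_bag(rec.seq if isinstance(rec, SequenceRecord) else rec, k)
        for rec in records
    ]
    vocab = build_vocabulary(token_lists, k=k, allowed=allowed_vocab)
    X, df, n_docs = tfidf_transform(token_lists, vocab, convention=convention)

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        LogisticRegression(solver="liblinear", random_state=seed),  # L2 penalty
        param_grid={"C": list(C_grid)},
        scoring="accuracy",
        cv=cv,
        n_jobs=1,
    )
    search.fit(X, y)
    best: LogisticRegression = search.best_estimator_
    return BagModel(
        vocab=vocab,
        beta=best.coef_.ravel().copy(),
        intercept=float(best.intercept_[0]),
        C=float(search.best_params_["C"]),
        convention=convention,
        df=df,
        n_docs=n_docs,
        cv_results=pd.DataFrame(search.cv_results_),
    )


def bag_profile(model: BagModel, seq: str, k: int | None = None) -> np.ndarray:
    """Per-base k-mer score track along ``seq``.

    Every k-window at 1-bp stride gets the beta of its canonical token
    (0 when the token is outside the — possibly filtered — vocabulary or
    the window contains N); each base reports the mean over the windows
    covering it. Track length equals the input length.
    """
    k = model.k if k is None else k
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    seq = seq.upper()
    n_windows = len(seq) - k + 1
    window_scores = np.zeros(n_windows)
    from .seqio import canonical_token

    for i in range(n_windows):
        window = seq[i : i + k]
        if set(window) <= set("ACGT"):
            j = model.vocab.index.get(canonical_token(window))
            if j is not None:
                window_scores[i] = model.beta[j]
    track = np.zeros(len(seq))
    cover = np.zeros(len(seq))
    for i in range(n_windows):
        track[i : i + k] += window_scores[i]
        cover[i : i + k] += 1.0
    return track / cover
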