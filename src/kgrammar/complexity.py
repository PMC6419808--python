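"""Shannon-entropy k-mer complexity and low-complexity vocabulary filtering.

Repeat-rich genomes flood k-mer counts with homopolymeric and short-period
words that carry little regulatory information. Complexity of a k-mer is
measured as the Shannon entropy of its within-k-mer symbol frequencies
(0 bits for a homopolymer, 2 bits for a uniform mix of A/C/G/T). A
threshold can be derived empirically from the entropy distribution of
transcription-factor motif consensus sequences — real binding sites are
rarely low-complexity — and the vocabulary is then pruned below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import SequenceError

__all__ = [
    "ComplexityThreshold",
    "shannon_entropy",
    "derive_entropy_threshold",
    "filter_vocabulary",
    "read_consensus_list",
    "DEFAULT_THRESHOLD_BITS",
]

#: Documented fallback cut-off (bits) for k=8 when no consensus collection
#: is supplied; below this sit homopolymers and two-letter repeats.
DEFAULT_THRESHOLD_BITS = 1.3

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class ComplexityThreshold:
    k: int
    threshold_bits: float
    source: str = "default"  # {"derived", "default"}

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold_bits <= 2.0 + 1e-12):
            raise ValueError("entropy threshold must lie in [0, 2] bits")


def shannon_entropy(kmer: str) -> float:
    """Entropy (bits) of the symbol composition of a k-mer, in [0, 2].

    Uses within-k-mer frequencies over the 4-letter alphabet with the
    0*log(0) := 0 convention. Invariant under reverse complement, since
    complementation only permutes symbols.
    """
    kmer = kmer.upper()
    if not kmer:
        raise SequenceError("empty k-mer")
    if not set(kmer) <= _ACGT:
        raise SequenceError(f"k-mer contains non-ACGT symbol: {kmer!r}")
    n = len(kmer)
    h = 0.0
    for sym in "ACGT":
        c = kmer.count(sym)
        if c:
            p = c / n
            h -= p * math.log2(p)
    return h


def derive_entropy_threshold(
    consensus_seqs: Sequence[str], k: int, percentile: float = 5.0
) -> ComplexityThreshold:
    """Empirical complexity cut-off from motif consensus sequences.

    Every length-k window of every consensus sequence contributes its
    entropy (sequences shorter than k contribute their full-length
    entropy); the threshold is the given percentile of that distribution,
    so that all but the least complex real binding-site words survive
    filtering.
    """
    if not consensus_seqs:
        raise ValueError("empty consensus collection")
    entropies: list[float] = []
    for seq in consensus_seqs:
        seq = seq.upper()
        if len(seq) <= k:
            entropies.append(shannon_entropy(seq))
        else:
            entropies.extend(
                shannon_entropy(seq[i : i + k]) for i in range(len(seq) - k + 1)
            )
    thr = float(np.percentile(entropies, percentile))
    return ComplexityThreshold(k=k, threshold_bits=thr, source="derived")


def filter_vocabulary(
    vocab: Iterable[str], thr: ComplexityThreshold | float
) -> set[str]:
    """Drop tokens with entropy strictly below the threshold.

    A threshold of 0 is a no-op (the "full" vocabulary); the result is the
    "filtered" vocabulary. Idempotent by construction.
    """
    bits = thr.threshold_bits if isinstance(thr, ComplexityThreshold) else float(thr)
    return {t for t in vocab if shannon_entropy(t) >= bits}


def read_consensus_list(path: str | Path) -> list[str]:
    """One consensus sequence per line; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.upper())
    return out
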