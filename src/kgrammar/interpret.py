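"""Vocabulary-level interpretation of trained models.

The scored vocabulary (token -> beta) is dissected by its distribution
tails (top/bottom 1% concentrate the informative words), G+C composition,
positional preferences relative to an anchor (TSS or peak midpoint),
enrichment of externally supplied motif hits (hypergeometric test with
Bonferroni correction), sequence similarity (edit distance) and per-base
meta-profiles across aligned regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import hypergeom

from .seqio import canonical_token, gc_content

__all__ = [
    "vocab_tails",
    "positional_density",
    "EnrichmentResult",
    "motif_enrichment",
    "edit_distance",
    "meta_profile",
    "pwm_bitscore_threshold",
]


def pwm_bitscore_threshold(odds: float = 10_000) -> float:
    """Bit-score cut-off log2(odds) for calling a PWM hit positive.

    The conventional gold standard scores a site positive when its odds
    of being drawn from the motif rather than background exceed
    ``odds``:1, i.e. log2(10000) ~ 13.28 bits.
    """
    return math.log2(odds)


def vocab_tails(
    scored: pd.DataFrame, pct: float = 0.01
) -> dict[str, pd.DataFrame]:
    """Partition a scored vocabulary into top/bottom tails and remainder.

    ``scored`` is the kmer_score_table output (token, beta, ...). Tails
    hold ceil(pct * |vocab|) tokens each by beta; per-group G+C content is
    attached so compositional biases of the extremes can be compared.
    """
    if not (0.0 < pct < 0.5):
        raise ValueError("pct must lie in (0, 0.5)")
    if len(scored) < 3:
        raise ValueError("need at least 3 tokens to form tails")
    n_tail = math.ceil(pct * len(scored))
    by_beta = scored.sort_values("beta", ascending=False, kind="mergesort")
    groups = {
        "top": by_beta.iloc[:n_tail].copy(),
        "bottom": by_beta.iloc[len(by_beta) - n_tail :].copy(),
        "remainder": by_beta.iloc[n_tail : len(by_beta) - n_tail].copy(),
    }
    for frame in groups.values():
        if "gc" not in frame.columns:
            frame["gc"] = [gc_content(t) for t in frame["token"]]
    return groups


def positional_density(
    tokens: Sequence[str],
    records: Sequence,
    anchor_offset: int | None = None,
    smooth_bp: float = 5.0,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Density of token-set occurrences by position relative to an anchor.

    Occurrences are counted on both strands via canonical matching at
    every window start across records of uniform length, binned at 1 bp,
    optionally Gaussian-smoothed, and normalized to integrate to 1
    (``normalize=False`` returns the raw per-position counts). Returns
    (positions, density) where positions are bp offsets relative to the
    anchor (record midpoint when ``anchor_offset`` is None).
    """
    if not tokens:
        raise ValueError("empty token set")
    token_set = {canonical_token(t) for t in tokens}
    k = len(next(iter(token_set)))
    if any(len(t) != k for t in token_set):
        raise ValueError("all tokens must share one length")
    lengths = {len(r.seq if hasattr(r, "seq") else r) for r in records}
    if len(lengths) != 1:
        raise ValueError("records must have uniform length")
    L = lengths.pop()
    if k > L:
        raise ValueError("token longer than records")
    counts = np.zeros(L - k + 1)
    for rec in records:
        seq = (rec.seq if hasattr(rec, "seq") else rec).upper()
        for i in range(L - k + 1):
            window = seq[i : i + k]
            if set(window) <= set("ACGT") and canonical_token(window) in token_set:
                counts[i] += 1.0
    if smooth_bp > 0:
        counts = gaussian_filter1d(counts, sigma=smooth_bp)
    if normalize:
        total = counts.sum()
        density = counts / total if total > 0 else counts
    else:
        density = counts
    offset = L // 2 if anchor_offset is None else anchor_offset
    positions = np.arange(L - k + 1) - offset
    return positions, density


@dataclass(frozen=True)
class EnrichmentResult:
    """Motif-hit enrichment of a token subset against the vocabulary.

    N: vocabulary size; n: subset (e.g. top 1%) size; M: tokens with a
    significant motif hit; m: subset tokens with a hit. enrichment is the
    ratio of hit rates (m/n)/(M/N); p_value is the hypergeometric upper
    tail P(X >= m).
    """

    N: int
    n: int
    M: int
    m: int
    enrichment: float
    p_value: float
    alpha_corrected: float

    def __post_init__(self) -> None:
        if not (self.m <= min(self.n, self.M) and self.n <= self.N and self.M <= self.N):
            raise ValueError("inconsistent counts for enrichment")


def motif_enrichment(
    top_tokens: Sequence[str],
    all_tokens: Sequence[str],
    hit_table: Mapping[str, bool],
    alpha: float = 0.05,
    n_tests: int = 1,
) -> EnrichmentResult:
    """Enrichment of motif hits in the top-scored tokens.

    ``hit_table`` maps token -> has-significant-motif-hit, produced by an
    external motif comparison (e.g. TOMTOM at p < 0.001); tokens absent
    from the table count as non-hits. ``alpha_corrected`` is the
    Bonferroni-adjusted significance level for ``n_tests`` parallel
    enrichment tests.
    """
    top = set(top_tokens)
    universe = set(all_tokens)
    if not top <= universe:
        raise ValueError("top tokens must be a subset of the vocabulary")
    N = len(universe)
    n = len(top)
    M = sum(1 for t in universe if hit_table.get(t, False))
    m = sum(1 for t in top if hit_table.get(t, False))
    enrichment = 0.0 if m == 0 else (m / n) / (M / N)
    p = float(hypergeom.sf(m - 1, N, M, n)) if M > 0 else 1.0
    return EnrichmentResult(
        N=N, n=n, M=M, m=m,
        enrichment=enrichment, p_value=p,
        alpha_corrected=alpha / max(n_tests, 1),
    )


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance."""
    if not a or not b:
        raise ValueError("edit_distance requires nonempty strings")
    return int(edlib.align(a, b, task="distance", mode="NW")["editDistance"])


def meta_profile(tracks: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Positionwise mean and standard deviation over aligned per-base
    tracks (e.g. bag_profile outputs across peak regions)."""
    if not len(tracks):
        raise ValueError("no tracks supplied")
    lengths = {len(t) for t in tracks}
    if len(lengths) != 1:
        raise ValueError("tracks must have equal length")
    stack = np.vstack([np.asarray(t, dtype=float) for t in tracks])
    return stack.mean(axis=0), stack.std(axis=0)
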