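"""Genome access, window extraction and k-mer tokenization.

Sequences are classified from two token views of the same DNA:

* a *bag* stream — every overlapping k-mer at 1-bp stride, collapsed with
  its reverse complement into a canonical token, order discarded;
* *sentences* — k phase-shifted non-overlapping tokenizations (offsets
  0..k-1), which preserve adjacency and feed the embedding model.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = frozenset("ACGTN")
_ACGT = frozenset("ACGT")

__all__ = [
    "GenomicRegion",
    "SequenceRecord",
    "Sentence",
    "Genome",
    "reverse_complement",
    "canonical_token",
    "tokenize_bag",
    "tokenize_sentences",
    "gc_content",
    "extract_region_sequences",
    "read_bed",
    "write_bed",
    "write_fasta",
    "read_fasta",
]


class SequenceError(ValueError):
    """Raised for malformed DNA input (bad symbols, impossible lengths)."""


@dataclass(frozen=True)
class GenomicRegion:
    """An interval on a named sequence; the unit of training and prediction.

    ``anchor`` is the biological reference point the window was built
    around (a peak midpoint or a TSS); ``label`` distinguishes regulatory
    regions from their matched controls.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str | None = None
    anchor: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SequenceRecord:
    region: GenomicRegion
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.region):
            raise ValueError(
                f"sequence length {len(self.seq)} != region length {len(self.region)}"
            )


@dataclass(frozen=True)
class Sentence:
    """One frame of the non-overlapping tokenization (offset in 0..k-1)."""

    tokens: tuple[str, ...]
    offset: int


class Genome:
    """Random-access genome: chromosome name -> uppercase sequence.

    Backed either by an in-memory dict (synthetic data, tests) or by an
    indexed FASTA via pyfaidx.
    """

    def __init__(self, chroms: Mapping[str, str]):
        self._chroms = {name: seq.upper() for name, seq in chroms.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def keys(self):
        return self._chroms.keys()

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def __getitem__(self, chrom: str) -> str:
        return self._chroms[chrom]

    def length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._chroms[chrom]
        if start < 0 or end > len(seq):
            raise IndexError(
                f"window [{start}, {end}) outside {chrom} (length {len(seq)})"
            )
        return seq[start:end]

    def fetch_region(self, region: GenomicRegion) -> SequenceRecord:
        seq = self.fetch(region.chrom, region.start, region.end)
        if region.strand == "-":
            seq = reverse_complement(seq)
        return SequenceRecord(region=region, seq=seq)


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement, reversed; N maps to N."""
    if not set(seq.upper()) <= _VALID:
        bad = set(seq.upper()) - _VALID
        raise SequenceError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_token(kmer: str) -> str:
    """Collapse a k-mer with its reverse complement: lexicographic minimum.

    Makes tokens strand-symmetric so each double-stranded word is counted
    once. k-mers containing N are rejected (callers skip those windows).
    """
    kmer = kmer.upper()
    if not set(kmer) <= _ACGT:
        raise SequenceError(f"k-mer contains non-ACGT symbol: {kmer!r}")
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def tokenize_bag(seq: str, k: int) -> list[str]:
    """All (L-k)+1 overlapping k-mers as canonical tokens, in order.

    Windows containing a non-ACGT symbol are skipped rather than imputed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = seq.upper()
    if len(seq) < k:
        raise SequenceError(f"sequence length {len(seq)} < k={k}: empty token stream")
    out: list[str] = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if set(window) <= _ACGT:
            out.append(canonical_token(window))
    return out


def tokenize_sentences(seq: str, k: int) -> list[Sentence]:
    """The k phase-shifted non-overlapping tokenizations of ``seq``.

    Sentence at offset j takes canonical tokens at positions j, j+k,
    j+2k, ...; trailing partial windows are dropped, as are windows
    containing N. Requires length >= 2k so at least one sentence has a
    co-occurring pair.
    """
    seq = seq.upper()
    if len(seq) < 2 * k:
        raise SequenceError(
            f"sequence length {len(seq)} < 2k={2 * k}: no token co-occurrence possible"
        )
    sentences = []
    for j in range(k):
        toks = []
        for i in range(j, len(seq) - k + 1, k):
            window = seq[i : i + k]
            if set(window) <= _ACGT:
                toks.append(canonical_token(window))
        sentences.append(Sentence(tokens=tuple(toks), offset=j))
    return sentences


def gc_content(seq: str) -> float:
    """Fraction (G+C)/(A+C+G+T); N excluded from the denominator."""
    seq = seq.upper()
    if not seq:
        raise SequenceError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise SequenceError("gc_content undefined: no A/C/G/T symbols")
    return gc / (gc + at)


def extract_region_sequences(
    genome: Genome,
    anchors: Iterable[GenomicRegion],
    mode: str = "midpoint300",
    window: int = 300,
) -> list[SequenceRecord]:
    """Extract fixed windows around anchor points.

    ``midpoint300``: [anchor-w/2, anchor+w/2), symmetric around a peak
    midpoint. ``tss``: [anchor-250, anchor+50) on the anchor's strand —
    the core-promoter window; minus-strand windows are reverse-
    complemented so the downstream TATA convention is preserved.
    Windows running off a chromosome end are dropped with a warning.
    """
    if mode not in ("midpoint300", "tss"):
        raise ValueError(f"unknown extraction mode {mode!r}")
    records = []
    for a in anchors:
        pos = a.anchor if a.anchor is not None else (a.start + a.end) // 2
        if mode == "midpoint300":
            start, end = pos - window // 2, pos + window - window // 2
        else:  # tss
            if a.strand == "-":
                start, end = pos - 50, pos + 250
            else:
                start, end = pos - 250, pos + 50
        if start < 0 or end > genome.length(a.chrom):
            logger.warning("dropping out-of-bounds window %s:[%d,%d)", a.chrom, start, end)
            continue
        region = GenomicRegion(
            chrom=a.chrom, start=start, end=end,
            strand=a.strand, label=a.label, anchor=pos,
        )
        records.append(genome.fetch_region(region))
    return records


# ---------------------------------------------------------------------------
# Plain-text interchange: BED and FASTA

def read_bed(path: str | Path, label: str | None = None) -> list[GenomicRegion]:
    """Read BED3/BED6 (0-based half-open) into regions."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) >= 6 else "."
            regions.append(
                GenomicRegion(chrom=chrom, start=start, end=end, strand=strand, label=label)
            )
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = r.label or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.region.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA reader returning name -> sequence (uppercased)."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line.upper())
    return {n: "".join(parts) for n, parts in seqs.items()}
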