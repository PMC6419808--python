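"""Seeded synthetic data with the statistical structure the models assume.

Real training data are 300-bp windows around open-chromatin/ChIP peak
midpoints or TSSs, paired with G+C-matched random regions, inside a
repeat-rich genome. The generators here emulate exactly that:

* regulatory sequences = i.i.d. background with a handful of planted,
  mutated motif instances (both strands) and optionally poly(dA:dT)
  tracts at fixed offsets;
* control sequences = background matched to each regulatory partner's
  realized G+C content;
* genome pairs = a source chromosome with planted regulatory windows,
  low-complexity repeat tracts and coding-mask intervals, plus a mutated
  (substitutions + small indels) target whose true homologous
  coordinates are tracked through the edits — the cross-genome transfer
  scenario.

Everything is bit-reproducible under (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import Genome, GenomicRegion, SequenceRecord, reverse_complement

__all__ = [
    "MotifSet",
    "make_motif_set",
    "simulate_dataset",
    "split_by_label",
    "GenomePair",
    "simulate_genome_pair",
]

BASES = np.array(list("ACGT"))


def _draw_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return BASES[rng.choice(4, size=length, p=p)]


@dataclass(frozen=True)
class MotifSet:
    """Consensus sequences plus a per-position substitution sampler."""

    consensus: tuple[str, ...]
    mutation_rate: float = 0.1

    def sample_instance(self, idx: int, rng: np.random.Generator) -> str:
        """One motif occurrence: consensus with i.i.d. substitutions."""
        out = list(self.consensus[idx])
        for i, base in enumerate(out):
            if rng.random() < self.mutation_rate:
                out[i] = rng.choice([b for b in "ACGT" if b != base])
        return "".join(out)


def make_motif_set(
    n_motifs: int = 2,
    length_range: tuple[int, int] = (8, 12),
    gc_bias: float = 0.5,
    mutation_rate: float = 0.1,
    seed: int = 0,
) -> MotifSet:
    """Random TFBS-like consensus sequences (reproducible under seed).

    ``gc_bias`` is the per-position probability of G or C; 1.0 gives
    all-G/C consensus.
    """
    if n_motifs < 1:
        raise ValueError("need at least one motif")
    rng = np.random.default_rng(seed)
    consensus = []
    for _ in range(n_motifs):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        consensus.append("".join(_draw_background(rng, length, gc_bias)))
    return MotifSet(consensus=tuple(consensus), mutation_rate=mutation_rate)


def _plant(
    seq: np.ndarray,
    instance: str,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    max_tries: int = 50,
) -> bool:
    """Insert an instance (random strand) at a random free position."""
    m = len(instance)
    if m > len(seq):
        raise ValueError("motif longer than sequence")
    if rng.random() < 0.5:
        instance = reverse_complement(instance)
    for _ in range(max_tries):
        pos = int(rng.integers(0, len(seq) - m + 1))
        if all(pos + m <= s or pos >= e for s, e in occupied):
            seq[pos : pos + m] = list(instance)
            occupied.append((pos, pos + m))
            return True
    return False


def simulate_dataset(
    n_per_class: int = 500,
    length: int = 300,
    motifs: MotifSet | None = None,
    copies_per_seq: tuple[int, int] = (1, 3),
    at_tract: tuple[int, int] | None = None,
    background_gc: float = 0.47,
    seed: int = 0,
    n_control: int | None = None,
) -> list[SequenceRecord]:
    """Labeled regulatory/control sequence set with planted motifs.

    Each regulatory sequence carries, for every motif in ``motifs``, a
    ``copies_per_seq`` (inclusive range) number of instances on random
    strands at non-overlapping positions; ``at_tract=(offset, length)`` additionally
    plants a poly(dA:dT) tract at a fixed offset (the structural
    low-complexity feature flanking bound regions). Each control is
    i.i.d. background matched to the realized G+C of its regulatory
    partner. ``n_control`` may exceed ``n_per_class`` (extra controls are
    matched to partners cyclically) to build unbalanced holdouts.
    """
    rng = np.random.default_rng(seed)
    if motifs is None:
        motifs = make_motif_set(seed=int(rng.integers(2**31)))
    if n_control is None:
        n_control = n_per_class
    if any(len(c) > length for c in motifs.consensus):
        raise ValueError("motif longer than sequence length")

    records: list[SequenceRecord] = []
    reg_gc: list[float] = []
    for i in range(n_per_class):
        seq = _draw_background(rng, length, background_gc)
        occupied: list[tuple[int, int]] = []
        if at_tract is not None:
            off, tract_len = at_tract
            base = "A" if rng.random() < 0.5 else "T"
            seq[off : off + tract_len] = base
            occupied.append((off, off + tract_len))
        for idx in range(len(motifs.consensus)):
            n_copies = int(rng.integers(copies_per_seq[0], copies_per_seq[1] + 1))
            for _ in range(n_copies):
                _plant(seq, motifs.sample_instance(idx, rng), rng, occupied)
        text = "".join(seq)
        gc = (text.count("G") + text.count("C")) / length
        reg_gc.append(gc)
        region = GenomicRegion(
            chrom=f"reg_{i}", start=0, end=length, label="regulatory", anchor=length // 2
        )
        records.append(SequenceRecord(region=region, seq=text))

    for i in range(n_control):
        gc = reg_gc[i % n_per_class]
        text = "".join(_draw_background(rng, length, gc))
        region = GenomicRegion(
            chrom=f"ctrl_{i}", start=0, end=length, label="control", anchor=length // 2
        )
        records.append(SequenceRecord(region=region, seq=text))
    return records


def split_by_label(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """(regulatory, control) partition of a labeled record list."""
    reg = [r for r in records if r.region.label == "regulatory"]
    ctrl = [r for r in records if r.region.label == "control"]
    return reg, ctrl


@dataclass
class GenomePair:
    """A source genome with annotations and its diverged target."""

    source: Genome
    target: Genome
    regulatory: list[GenomicRegion]
    repeats: list[GenomicRegion]
    coding: list[GenomicRegion]
    hits: list[GenomicRegion] = field(default_factory=list)
    motifs: MotifSet | None = None


_REPEAT_UNITS = ("A", "T", "AT", "AG", "CT", "AAT", "AGG")


def simulate_genome_pair(
    chrom_length: int = 500_000,
    n_regulatory: int = 100,
    repeat_fraction: float = 0.2,
    coding_fraction: float = 0.05,
    divergence: float = 0.02,
    window: int = 300,
    motifs: MotifSet | None = None,
    copies_per_region: tuple[int, int] = (1, 3),
    background_gc: float = 0.47,
    seed: int = 0,
    chrom: str = "chrS",
) -> GenomePair:
    """Source/target genome pair for the annotation-transfer scenario.

    The source chromosome carries ``n_regulatory`` planted regulatory
    windows (one per equal-sized slot, so loci are well separated as
    alignment hits are), low-complexity repeat tracts covering
    ``repeat_fraction`` of the sequence, and coding-mask intervals. The
    target is the source with i.i.d. substitutions at rate ``divergence``
    and sparse 1-3 bp indels; the regulatory windows' coordinates mapped
    through the edits are returned as ground-truth hits.
    """
    rng = np.random.default_rng(seed)
    if motifs is None:
        motifs = make_motif_set(seed=int(rng.integers(2**31)))
    slot = chrom_length // n_regulatory
    if slot < window + 200:
        raise ValueError(
            f"cannot pack {n_regulatory} windows of {window} bp into {chrom_length} bp"
        )
    if repeat_fraction + n_regulatory * window / chrom_length > 0.98:
        raise ValueError("repeat_fraction leaves no room for regulatory windows")

    seq = _draw_background(rng, chrom_length, background_gc)

    # regulatory windows: one per slot at a random offset
    reg_regions: list[GenomicRegion] = []
    for i in range(n_regulatory):
        lo = i * slot + 100
        hi = (i + 1) * slot - window - 100
        start = int(rng.integers(lo, hi + 1))
        occupied: list[tuple[int, int]] = []
        sub = seq[start : start + window]
        for idx in range(len(motifs.consensus)):
            n_copies = int(rng.integers(copies_per_region[0], copies_per_region[1] + 1))
            for _ in range(n_copies):
                _plant(sub, motifs.sample_instance(idx, rng), rng, occupied)
        seq[start : start + window] = sub
        reg_regions.append(
            GenomicRegion(chrom=chrom, start=start, end=start + window,
                          label="regulatory", anchor=start + window // 2)
        )

    # repeat tracts in the gaps between regulatory windows
    forbidden = [(r.start - 100, r.end + 100) for r in reg_regions]
    repeat_target = int(repeat_fraction * chrom_length)
    repeats: list[GenomicRegion] = []
    covered = 0
    mean_tract = 900.0
    frac_free = max(1e-6, 1.0 - n_regulatory * (window + 200) / chrom_length)
    p = min(0.999, repeat_fraction / frac_free)
    mean_spacer = max(1.0, mean_tract * (1 - p) / p) if p > 0 else np.inf
    pos = 0
    while p > 0 and pos < chrom_length and covered < repeat_target:
        pos += int(rng.exponential(mean_spacer)) + 1
        tract_len = int(rng.integers(300, 1500))
        end = min(pos + tract_len, chrom_length)
        if end <= pos:
            break
        if any(pos < fe and fs < end for fs, fe in forbidden):
            pos = end
            continue
        unit = _REPEAT_UNITS[int(rng.integers(0, len(_REPEAT_UNITS)))]
        tract = (unit * ((end - pos) // len(unit) + 1))[: end - pos]
        seq[pos:end] = list(tract)
        repeats.append(GenomicRegion(chrom=chrom, start=pos, end=end, label="repeat"))
        covered += end - pos
        pos = end

    # coding-mask intervals (content irrelevant; masking tests only)
    coding: list[GenomicRegion] = []
    coding_target = int(coding_fraction * chrom_length)
    covered = 0
    exclusion = forbidden + [(r.start, r.end) for r in repeats]
    for _ in range(10_000):
        if covered >= coding_target:
            break
        start = int(rng.integers(0, chrom_length - 1000))
        end = start + int(rng.integers(500, 1000))
        if end > chrom_length or any(start < fe and fs < end for fs, fe in exclusion):
            continue
        coding.append(GenomicRegion(chrom=chrom, start=start, end=end, label="coding"))
        exclusion.append((start, end))
        covered += end - start

    source = Genome({chrom: "".join(seq)})

    # diverged target with coordinate mapping at regulatory boundaries
    indel_rate = divergence * 0.05
    starts = {r.start: i for i, r in enumerate(reg_regions)}
    ends = {r.end: i for i, r in enumerate(reg_regions)}
    hit_start = [0] * n_regulatory
    hit_end = [0] * n_regulatory
    target_parts: list[str] = []
    t_pos = 0
    i = 0
    while i < chrom_length:
        if i in starts:
            hit_start[starts[i]] = t_pos
        if i in ends:
            hit_end[ends[i]] = t_pos
        r = rng.random()
        if r < indel_rate:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                i += size
                continue
            ins = "".join(_draw_background(rng, size, background_gc))
            target_parts.append(ins)
            t_pos += size
            continue
        base = seq[i]
        if rng.random() < divergence:
            base = rng.choice([b for b in "ACGT" if b != base])
        target_parts.append(base)
        t_pos += 1
        i += 1
    if chrom_length in ends:
        hit_end[ends[chrom_length]] = t_pos
    target = Genome({chrom: "".join(target_parts)})

    hits = [
        GenomicRegion(chrom=chrom, start=hs, end=he, label="hit")
        for hs, he in zip(hit_start, hit_end)
        if he > hs
    ]
    return GenomePair(
        source=source, target=target,
        regulatory=reg_regions, repeats=repeats, coding=coding,
        hits=hits, motifs=motifs,
    )
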