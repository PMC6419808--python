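"""Selection of matched control regions and train/holdout assembly.

Background signal for the biochemical assays is not available, so each
regulatory region is paired with a randomly chosen control of the same
length that (i) matches its G+C content within a tolerance, (ii) overlaps
neither regulatory regions nor previously chosen controls, and (iii) when
possible lies within a local vicinity (default 100 kb) so the pair shares
the broad genomic neighbourhood; the vicinity constraint is relaxed to the
whole chromosome when the neighbourhood is exhausted.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from sklearn.model_selection import train_test_split

from .seqio import Genome, GenomicRegion, SequenceRecord, gc_content

__all__ = [
    "UnmatchedTargetError",
    "ExclusionIndex",
    "select_control_region",
    "select_controls",
    "make_splits",
    "assemble_holdout",
]


class UnmatchedTargetError(RuntimeError):
    """No acceptable control exists for a target region."""


class ExclusionIndex:
    """Interval index of regions a control must not overlap."""

    def __init__(self, regions: Iterable[GenomicRegion] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for r in regions:
            self.add(r)

    def add(self, region: GenomicRegion) -> None:
        self._trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end
        )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))


def _try_window(
    genome: Genome,
    chrom: str,
    start: int,
    length: int,
    target_gc: float,
    gc_tolerance: float,
    exclusions: ExclusionIndex,
) -> GenomicRegion | None:
    end = start + length
    if start < 0 or end > genome.length(chrom):
        return None
    if exclusions.overlaps(chrom, start, end):
        return None
    seq = genome.fetch(chrom, start, end)
    if "N" in seq:
        return None
    if abs(gc_content(seq) - target_gc) > gc_tolerance:
        return None
    return GenomicRegion(chrom=chrom, start=start, end=end, strand=".", label="control")


def select_control_region(
    target: GenomicRegion,
    genome: Genome,
    exclusions: ExclusionIndex,
    gc_tolerance: float = 0.02,
    vicinity_bp: int = 100_000,
    max_attempts: int = 10_000,
    rng: np.random.Generator | None = None,
) -> GenomicRegion:
    """Draw one G+C- and locality-matched control for ``target``.

    Candidate windows of the target's length are drawn uniformly at
    random, first within +/- ``vicinity_bp`` of the target, then anywhere
    on the chromosome. Raises :class:`UnmatchedTargetError` when both
    phases fail.
    """
    rng = rng if rng is not None else np.random.default_rng()
    length = len(target)
    target_gc = gc_content(genome.fetch(target.chrom, target.start, target.end))
    chrom_len = genome.length(target.chrom)

    lo = max(0, target.start - vicinity_bp)
    hi = min(chrom_len - length, target.end + vicinity_bp)
    phases = []
    if hi >= lo:
        phases.append((lo, hi))
    if chrom_len - length >= 0:
        phases.append((0, chrom_len - length))

    for plo, phi in phases:
        for _ in range(max_attempts):
            start = int(rng.integers(plo, phi + 1))
            cand = _try_window(
                genome, target.chrom, start, length, target_gc, gc_tolerance, exclusions
            )
            if cand is not None:
                return cand
    raise UnmatchedTargetError(
        f"no control found for {target.name} (GC {target_gc:.3f} "
        f"+/- {gc_tolerance}) on {target.chrom}"
    )


def select_controls(
    targets: Sequence[GenomicRegion],
    genome: Genome,
    gc_tolerance: float = 0.02,
    vicinity_bp: int = 100_000,
    n_per_target: int = 1,
    extra_exclusions: Iterable[GenomicRegion] = (),
    rng: np.random.Generator | None = None,
    skip_unmatched: bool = True,
) -> list[GenomicRegion]:
    """Pair every target with ``n_per_target`` controls.

    The exclusion set holds all targets, any extra intervals supplied
    (e.g. the full regulatory catalogue) and every control already
    chosen, so controls never overlap each other. Unmatched targets are
    skipped with their names collected in the raised error unless
    ``skip_unmatched``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    exclusions = ExclusionIndex(list(targets) + list(extra_exclusions))
    controls: list[GenomicRegion] = []
    unmatched: list[str] = []
    for target in targets:
        for _ in range(n_per_target):
            try:
                ctrl = select_control_region(
                    target, genome, exclusions,
                    gc_tolerance=gc_tolerance, vicinity_bp=vicinity_bp, rng=rng,
                )
            except UnmatchedTargetError:
                unmatched.append(target.name)
                break
            exclusions.add(ctrl)
            controls.append(ctrl)
    if unmatched and not skip_unmatched:
        raise UnmatchedTargetError(
            f"{len(unmatched)} targets without controls: {unmatched[:5]}..."
        )
    return controls


def make_splits(
    records: Sequence[SequenceRecord],
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Label-stratified, seeded train/holdout split."""
    if not (0.0 < holdout_fraction < 1.0):
        raise ValueError("holdout_fraction must lie in (0, 1)")
    labels = [rec.region.label for rec in records]
    train, holdout = train_test_split(
        list(records),
        test_size=holdout_fraction,
        stratify=labels,
        random_state=seed,
    )
    return train, holdout


def assemble_holdout(
    regulatory: Sequence[SequenceRecord],
    controls: Sequence[SequenceRecord],
    ratio: int = 1,
    rng: np.random.Generator | None = None,
) -> list[SequenceRecord]:
    """Evaluation set with ``ratio`` controls per regulatory region.

    ratio 1 gives the balanced holdout; ratio 10 the unbalanced one used
    to stress precision. Controls are sampled without replacement.
    """
    if ratio < 1:
        raise ValueError("ratio must be a positive integer")
    needed = ratio * len(regulatory)
    if needed > len(controls):
        raise ValueError(
            f"insufficient controls: need {needed}, have {len(controls)} "
            f"(shortfall {needed - len(controls)})"
        )
    rng = rng if rng is not None else np.random.default_rng()
    idx = rng.choice(len(controls), size=needed, replace=False)
    return list(regulatory) + [controls[i] for i in idx]
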