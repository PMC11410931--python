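"""Core domain types and interval arithmetic.

All coordinates are 0-based half-open (BED convention). GFF3 input is
converted on read. Overlap means at least one shared base on the same
chromosome; strand is ignored for overlap tests, since peaks are unstranded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "Genome",
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "RepeatFeature",
    "overlaps",
    "overlap_length",
    "merge_within",
    "group_by_chrom",
]


@dataclass(frozen=True)
class Genome:
    """A species label plus an ordered list of (chromosome name, length in bp)."""

    name: str
    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(tuple(c) for c in self.chromosomes))
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome {self.name!r}") from None


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def validate_against(self, genome: Genome) -> None:
        if self.end > genome.length_of(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {genome.length_of(self.chrom)}"
            )


@dataclass(frozen=True)
class Peak:
    """A peak with a summit, narrowPeak style.

    ``summit`` is the offset in bp from ``interval.start`` (narrowPeak column
    10 semantics); ``summit_pos`` gives the absolute coordinate.
    """

    interval: GenomicInterval
    peak_id: str
    summit: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.summit < len(self.interval)):
            raise ValueError(
                f"peak {self.peak_id!r}: summit offset {self.summit} outside "
                f"[0, {len(self.interval)})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def summit_pos(self) -> int:
        """Absolute summit coordinate."""
        return self.interval.start + self.summit

    def shifted(self, delta: int) -> "Peak":
        iv = self.interval
        return replace(
            self, interval=GenomicInterval(iv.chrom, iv.start + delta, iv.end + delta, iv.strand)
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS and non-overlapping exons.

    TSS is ``interval.start`` for + strand genes and ``interval.end - 1``
    for - strand genes (the first transcribed base).
    """

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        for e in exons:
            if e.chrom != self.interval.chrom or e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id!r}: exon {e} outside gene interval")
        for a, b in itertools.pairwise(exons):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id!r}: overlapping exons")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class RepeatFeature:
    """A repeat element annotated with its family label (e.g. LTR/Gypsy)."""

    interval: GenomicInterval
    family: str

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("repeat family label must be non-empty")


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share >= 1 bp on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases (0 if disjoint or on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def group_by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def merge_within(intervals: Sequence[GenomicInterval], max_gap: int) -> list[GenomicInterval]:
    """Merge intervals separated by a gap strictly smaller than ``max_gap``.

    Overlapping or abutting intervals (gap <= 0) are always merged. Intervals
    on different chromosomes are never merged. The output is sorted by
    (chrom, start) and non-overlapping; total covered bases never decrease.
    A gap of exactly ``max_gap`` is NOT merged (strict "less than").
    """
    merged: list[GenomicInterval] = []
    by_chrom = group_by_chrom(intervals)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end < max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged
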