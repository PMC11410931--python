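"""Cross-species conservation calls for accessible-chromatin peaks.

The protocol projects each source peak into a recipient genome twice through
a whole-genome alignment: the full peak region (RGN) and a 51 bp window
around the summit (SUM). Fragmented RGN projections are cleaned (fragments
under 20 bp discarded, then fragments separated by under 100 bp merged per
chromosome); a peak whose cleaned RGN fragments overlap its SUM projection
is a "conserved region", upgraded to "conserved peak" when a cleaned,
SUM-supported fragment also overlaps an accessible-chromatin peak called in
the recipient species (any overlap counts as a hit). Per-species calls over
the three recipient species aggregate to high / partial / not conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._overlapops import MergedIndex
from .classify import ENHANCER, K4_ONLY, PROMOTER, UNCHARACTERIZED
from .contingency import ContingencyResult, chi2_stat, cramers_v, pearson_chi2
from .core import GenomicInterval, Peak, merge_within, overlaps

CONSERVED_PEAK = "conserved_peak"
CONSERVED_REGION = "conserved_region"
NOT_CONSERVED = "not_conserved"
SPECIES_STATUSES = (CONSERVED_PEAK, CONSERVED_REGION, NOT_CONSERVED)

HIGH = "high"
PARTIAL = "partial"
AGGREGATE_CATEGORIES = (HIGH, PARTIAL, NOT_CONSERVED)


@dataclass
class LiftoverFragmentSet:
    """Projection fragments of one source peak in a recipient genome.

    ``kind`` is RGN (the whole peak region) or SUM (the 51 bp summit
    window). Fragments may span several recipient chromosomes or be empty.
    """

    source_peak_id: str
    kind: str
    fragments: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("RGN", "SUM"):
            raise ValueError(f"kind must be RGN or SUM, got {self.kind!r}")


@dataclass(frozen=True)
class SpeciesConservationCall:
    source_peak_id: str
    recipient_species: str
    status: str
    conserved_intervals: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if (self.status == NOT_CONSERVED) != (len(self.conserved_intervals) == 0):
            raise ValueError("conserved_intervals must be empty iff not conserved")


@dataclass(frozen=True)
class ConservationRecord:
    """Per-peak statuses in the three recipient species plus the genus call."""

    peak_id: str
    statuses: Mapping[str, str]
    aggregate: str


@dataclass(frozen=True)
class AlignmentBlock:
    """A gap-free co-linear alignment block (src and dst of equal length)."""

    src: GenomicInterval
    dst: GenomicInterval
    dst_strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.src) != len(self.dst):
            raise ValueError("alignment block src and dst must have equal length")
        if self.dst_strand not in ("+", "-"):
            raise ValueError("dst_strand must be + or -")


def summit_window(peak: Peak, half_width: int = 25, chrom_length: int | None = None) -> GenomicInterval:
    """The summit +/- ``half_width`` window (51 bp by default), end-clipped.

    The window is centered on the summit base; at chromosome ends it shrinks
    (never grows past the ends), so its width is at most 2*half_width + 1.
    """
    pos = peak.summit_pos
    start = max(0, pos - half_width)
    end = pos + half_width + 1
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(peak.chrom, start, end)


def clean_fragments(
    rgn: LiftoverFragmentSet, min_len: int = 20, max_gap: int = 100
) -> list[GenomicInterval]:
    """Clean fragmented RGN projections: drop short fragments, then merge.

    Fragments shorter than ``min_len`` bp are discarded FIRST; the
    survivors are then merged per chromosome whenever separated by less
    than ``max_gap`` bp. Output sorted by (chrom, start).
    """
    if rgn.kind != "RGN":
        raise ValueError("clean_fragments applies to RGN fragment sets only")
    survivors = [f for f in rgn.fragments if len(f) >= min_len]
    if not survivors:
        return []
    return merge_within(survivors, max_gap)


def call_species_conservation(
    peak: Peak,
    rgn_cleaned: Sequence[GenomicInterval],
    sum_set: LiftoverFragmentSet,
    recipient_atac: Sequence[Peak],
    recipient_species: str = "",
) -> SpeciesConservationCall:
    """Call the conservation status of one peak in one recipient species.

    The cleaned RGN fragments that overlap any SUM fragment are the
    conserved intervals; without any such fragment the peak is not
    conserved. A conserved peak additionally requires >= 1 bp overlap
    between a SUM-supported fragment and a recipient ATAC peak.
    """
    supported = [
        f for f in rgn_cleaned if any(overlaps(f, s) for s in sum_set.fragments)
    ]
    if not supported:
        return SpeciesConservationCall(peak.peak_id, recipient_species, NOT_CONSERVED)
    status = CONSERVED_REGION
    for f in supported:
        if any(overlaps(f, a.interval) for a in recipient_atac):
            status = CONSERVED_PEAK
            break
    return SpeciesConservationCall(
        peak.peak_id, recipient_species, status, tuple(supported)
    )


def aggregate_conservation(calls: Sequence[SpeciesConservationCall]) -> ConservationRecord:
    """Aggregate three per-species calls into the genus-level category.

    high: conserved peak in all three recipients; not conserved: no
    conservation in any recipient; partial: everything else. The three
    categories are exhaustive and mutually exclusive.
    """
    if len(calls) != 3:
        raise ValueError(f"expected calls for exactly 3 recipient species, got {len(calls)}")
    peak_ids = {c.source_peak_id for c in calls}
    if len(peak_ids) != 1:
        raise ValueError("calls refer to different source peaks")
    species = [c.recipient_species for c in calls]
    if len(set(species)) != 3:
        raise ValueError("calls must come from three distinct recipient species")
    statuses = {c.recipient_species: c.status for c in calls}
    if all(s == CONSERVED_PEAK for s in statuses.values()):
        aggregate = HIGH
    elif all(s == NOT_CONSERVED for s in statuses.values()):
        aggregate = NOT_CONSERVED
    else:
        aggregate = PARTIAL
    return ConservationRecord(peak_ids.pop(), statuses, aggregate)


def conserve_peak_set(
    peaks: Sequence[Peak],
    liftovers: Mapping[str, Mapping[str, tuple[LiftoverFragmentSet, LiftoverFragmentSet]]],
    recipient_atac: Mapping[str, Sequence[Peak]],
    min_len: int = 20,
    max_gap: int = 100,
) -> list[ConservationRecord]:
    """Run the full per-peak protocol over three recipient species.

    ``liftovers[species][peak_id]`` holds the (RGN, SUM) fragment sets;
    peaks absent from a species' liftover are not conserved there.
    """
    species = sorted(liftovers)
    if len(species) != 3:
        raise ValueError(f"expected liftovers for exactly 3 species, got {len(species)}")
    atac_index = {
        sp: MergedIndex(p.interval for p in recipient_atac.get(sp, ())) for sp in species
    }
    records = []
    for peak in peaks:
        calls = []
        for sp in species:
            entry = liftovers[sp].get(peak.peak_id)
            if entry is None:
                calls.append(SpeciesConservationCall(peak.peak_id, sp, NOT_CONSERVED))
                continue
            rgn, sum_set = entry
            cleaned = clean_fragments(rgn, min_len=min_len, max_gap=max_gap)
            supported = [
                f for f in cleaned if any(overlaps(f, s) for s in sum_set.fragments)
            ]
            if not supported:
                calls.append(SpeciesConservationCall(peak.peak_id, sp, NOT_CONSERVED))
                continue
            status = CONSERVED_REGION
            idx = atac_index[sp]
            for f in supported:
                if bool(idx.any_hit(f.chrom, np.asarray([f.start]), np.asarray([f.end]))[0]):
                    status = CONSERVED_PEAK
                    break
            calls.append(
                SpeciesConservationCall(peak.peak_id, sp, status, tuple(supported))
            )
        records.append(aggregate_conservation(calls))
    return records


def block_liftover(
    intervals: Sequence[GenomicInterval], alignment_blocks: Sequence[AlignmentBlock]
) -> list[list[GenomicInterval]]:
    """Project intervals through gap-free co-linear alignment blocks.

    Each input interval is intersected with the source side of every block
    and the intersection mapped by the block's offset (with a coordinate
    flip for minus-strand blocks). Per input, fragments are ordered by
    source position. Emulates a liftover tool on toy alignments.
    """
    import bisect

    by_chrom: dict[str, list[AlignmentBlock]] = {}
    for blk in alignment_blocks:
        by_chrom.setdefault(blk.src.chrom, []).append(blk)
    starts: dict[str, list[int]] = {}
    max_len: dict[str, int] = {}
    for chrom, blks in by_chrom.items():
        blks.sort(key=lambda b: b.src.start)
        starts[chrom] = [b.src.start for b in blks]
        max_len[chrom] = max(len(b.src) for b in blks)

    out: list[list[GenomicInterval]] = []
    for iv in intervals:
        frags: list[tuple[int, GenomicInterval]] = []
        blks = by_chrom.get(iv.chrom, ())
        if blks:
            lo = bisect.bisect_left(starts[iv.chrom], iv.start - max_len[iv.chrom])
            hi = bisect.bisect_left(starts[iv.chrom], iv.end)
        else:
            lo = hi = 0
        for blk in blks[lo:hi]:
            s = max(iv.start, blk.src.start)
            e = min(iv.end, blk.src.end)
            if s >= e:
                continue
            if blk.dst_strand == "+":
                d_start = blk.dst.start + (s - blk.src.start)
                d_end = blk.dst.start + (e - blk.src.start)
            else:
                d_start = blk.dst.start + (blk.src.end - e)
                d_end = blk.dst.start + (blk.src.end - s)
            frags.append((s, GenomicInterval(blk.dst.chrom, d_start, d_end)))
        frags.sort(key=lambda t: t[0])
        out.append([f for _, f in frags])
    return out


_CONTINGENCY_CLASSES = (PROMOTER, ENHANCER, UNCHARACTERIZED)


def conservation_contingency_test(
    records: Sequence[ConservationRecord],
    classes: Mapping[str, str],
    n_perm: int = 0,
    seed: int | np.random.Generator | None = None,
    collapse_k4: bool = True,
) -> tuple[ContingencyResult, pd.DataFrame]:
    """Test the association between peak class and conservation category.

    Builds the class x aggregate-category table (3x3 when all levels occur;
    the small K4-only class is folded into uncharacterized by default, as in
    the three-category analyses), computes Pearson chi-squared with the
    analytic p-value and Cramér's V, optionally a permutation p-value by
    shuffling class labels, and runs all pairwise class comparisons (2x3
    tables) with Bonferroni correction as post-hoc tests.

    Returns (overall result, post-hoc DataFrame).
    """
    rows = []
    for rec in records:
        cls = classes.get(rec.peak_id)
        if cls is None:
            raise KeyError(f"peak {rec.peak_id!r} has no class label")
        if collapse_k4 and cls == K4_ONLY:
            cls = UNCHARACTERIZED
        rows.append((cls, rec.aggregate))
    df = pd.DataFrame(rows, columns=["cls", "aggregate"])
    class_levels = [c for c in (_CONTINGENCY_CLASSES if collapse_k4 else (_CONTINGENCY_CLASSES + (K4_ONLY,)))]
    table = pd.crosstab(df["cls"], df["aggregate"]).reindex(
        index=class_levels, columns=list(AGGREGATE_CATEGORIES), fill_value=0
    )
    # drop zero-margin levels
    zero_rows = table.index[table.sum(axis=1) == 0].tolist()
    zero_cols = table.columns[table.sum(axis=0) == 0].tolist()
    if zero_rows or zero_cols:
        warnings.warn(
            f"dropping zero-margin levels: rows {zero_rows}, columns {zero_cols}",
            stacklevel=2,
        )
        table = table.drop(index=zero_rows, columns=zero_cols)

    arr = table.to_numpy(dtype=float)
    chi2, dof, p = pearson_chi2(arr)
    v = cramers_v(arr) if arr.size and min(arr.shape) >= 2 else 0.0
    n = int(arr.sum())

    p_perm = None
    if n_perm > 0 and min(arr.shape) >= 2:
        rng = np.random.default_rng(seed)
        cls_codes = pd.Categorical(df["cls"], categories=table.index).codes
        agg_codes = pd.Categorical(df["aggregate"], categories=table.columns).codes
        n_r, n_c = arr.shape
        row_m = arr.sum(axis=1, keepdims=True)
        col_m = arr.sum(axis=0, keepdims=True)
        expected = row_m @ col_m / n
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(cls_codes)
            t = np.bincount(perm * n_c + agg_codes, minlength=n_r * n_c).reshape(n_r, n_c)
            if chi2_stat(t.astype(float), expected) >= chi2:
                exceed += 1
        p_perm = (1 + exceed) / (n_perm + 1)

    result = ContingencyResult(table, chi2, dof, p, v, n, p_perm)

    posthoc_rows = []
    levels = list(table.index)
    n_pairs = len(levels) * (len(levels) - 1) // 2
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            sub = table.loc[[levels[i], levels[j]]].to_numpy(dtype=float)
            c2, d2, p2 = pearson_chi2(sub)
            posthoc_rows.append(
                {
                    "class_a": levels[i],
                    "class_b": levels[j],
                    "chi2": c2,
                    "df": d2,
                    "p": p2,
                    "p_bonferroni": min(1.0, p2 * n_pairs),
                }
            )
    return result, pd.DataFrame(posthoc_rows)


def conservation_fractions(records: Sequence[ConservationRecord]) -> dict[str, float]:
    """Fractions of high / partial / not conserved (sum to 1)."""
    n = len(records)
    if n == 0:
        raise ValueError("no records")
    counts = {c: 0 for c in AGGREGATE_CATEGORIES}
    for r in records:
        counts[r.aggregate] += 1
    return {c: counts[c] / n for c in AGGREGATE_CATEGORIES}
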