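"""Regulatory classification of ATAC peaks by histone-mark co-occurrence.

ATAC peaks overlapping both H3K4me3 and H3K27ac are putative promoters,
peaks with only H3K27ac are putative enhancers, peaks with only H3K4me3 are
a small separate class, and peaks with neither mark are uncharacterized
accessible chromatin. A permutation test quantifies overlap enrichment
against random length-preserving re-placement, and each peak is assigned a
genomic feature category relative to gene models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from ._overlapops import MergedIndex, interval_arrays
from .core import GeneModel, Genome, Peak

PROMOTER = "putative_promoter"
ENHANCER = "putative_enhancer"
K4_ONLY = "k4_only"
UNCHARACTERIZED = "uncharacterized"
PEAK_CLASSES = (PROMOTER, ENHANCER, K4_ONLY, UNCHARACTERIZED)


@dataclass(frozen=True)
class OverlapPermutationResult:
    """Outcome of the random re-placement overlap enrichment test."""

    observed: int
    perm_mean: float
    perm_sd: float
    z: float | None
    p_empirical: float
    n_perm: int

    def __str__(self) -> str:
        z = "NA" if self.z is None else f"{self.z:.2f}"
        return (
            f"observed overlap: {self.observed}, permuted overlap: "
            f"{self.perm_mean:.1f} (sd {self.perm_sd:.1f}), z = {z}, "
            f"p = {self.p_empirical:.3g} ({self.n_perm} permutations)"
        )


FEATURE_CATEGORIES = (
    "promoter_0_3kb",
    "exon",
    "intron",
    "downstream",
    "distal_intergenic",
)


@dataclass(frozen=True)
class FeatureAnnotation:
    """Single feature category per peak plus the nearest gene and TSS offset."""

    category: str
    nearest_gene_id: str | None
    distance_to_tss: int | None


def _hit_flags(peaks: Sequence[Peak], reference: Sequence[Peak], min_overlap: int) -> np.ndarray:
    """Boolean per peak: overlaps any reference peak by >= min_overlap bp."""
    if min_overlap == 1:
        index = MergedIndex(p.interval for p in reference)
        flags = np.zeros(len(peaks), dtype=bool)
        for i, p in enumerate(peaks):
            flags[i] = bool(index.any_hit(p.chrom, np.asarray([p.start]), np.asarray([p.end]))[0])
        return flags
    trees: dict[str, IntervalTree] = {}
    for r in reference:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    flags = np.zeros(len(peaks), dtype=bool)
    for i, p in enumerate(peaks):
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(p.start, p.end):
            if min(hit.end, p.end) - max(hit.begin, p.start) >= min_overlap:
                flags[i] = True
                break
    return flags


def classify_peaks(
    atac: Sequence[Peak],
    k4: Sequence[Peak],
    k27: Sequence[Peak],
    min_overlap: int = 1,
) -> dict[str, str]:
    """Assign each ATAC peak exactly one regulatory class.

    Returns a mapping peak_id -> class label; the labels partition the
    input set. ``min_overlap`` is the minimum shared bases (default 1 bp,
    i.e. any intersection counts).
    """
    k4_hits = _hit_flags(atac, k4, min_overlap)
    k27_hits = _hit_flags(atac, k27, min_overlap)
    out: dict[str, str] = {}
    for peak, has_k4, has_k27 in zip(atac, k4_hits, k27_hits):
        if has_k4 and has_k27:
            label = PROMOTER
        elif has_k27:
            label = ENHANCER
        elif has_k4:
            label = K4_ONLY
        else:
            label = UNCHARACTERIZED
        out[peak.peak_id] = label
    return out


def class_counts(classes: Mapping[str, str]) -> dict[str, int]:
    counts = {label: 0 for label in PEAK_CLASSES}
    for label in classes.values():
        counts[label] += 1
    return counts


def permute_overlap_test(
    query: Sequence[Peak],
    reference: Sequence[Peak],
    genome: Genome,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    alternative: str = "greater",
) -> OverlapPermutationResult:
    """Test overlap enrichment of query peaks in a reference peak set.

    Each permutation re-places every query peak uniformly at random on its
    own chromosome, preserving its length (overlaps among placed peaks are
    allowed). The observed statistic is the number of query peaks hitting
    at least one reference peak; the empirical p-value uses add-one
    smoothing, one-tailed for enrichment by default ("two-sided" doubles
    the smaller tail, capped at 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(seed)
    index = MergedIndex(p.interval for p in reference)

    observed = 0
    perm_counts = np.zeros(n_perm, dtype=np.int64)
    by_chrom = interval_arrays([p.interval for p in query])
    for chrom, (starts, ends) in by_chrom.items():
        chrom_len = genome.length_of(chrom)
        lengths = ends - starts
        if np.any(lengths > chrom_len):
            raise ValueError(f"query peak longer than chromosome {chrom!r}")
        observed += int(index.any_hit(chrom, starts, ends).sum())
        max_start = chrom_len - lengths  # inclusive
        # vectorized (chunk, n_peaks) batches of random starts
        chunk = max(1, min(n_perm, 2_000_000 // max(1, len(lengths))))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            rand_starts = rng.integers(0, max_start + 1, size=(m, len(lengths)))
            hits = index.any_hit(chrom, rand_starts, rand_starts + lengths)
            perm_counts[done : done + m] += hits.sum(axis=1)
            done += m

    perm_mean = float(perm_counts.mean()) if n_perm else math.nan
    perm_sd = float(perm_counts.std(ddof=0))
    z = None if perm_sd == 0 else (observed - perm_mean) / perm_sd
    p_ge = (1 + int((perm_counts >= observed).sum())) / (n_perm + 1)
    p_le = (1 + int((perm_counts <= observed).sum())) / (n_perm + 1)
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2 * min(p_ge, p_le))
    return OverlapPermutationResult(observed, perm_mean, perm_sd, z, p, n_perm)


def annotate_features(
    peak: Peak,
    genes: Sequence[GeneModel],
    promoter_upstream: int = 3000,
    downstream_extent: int = 3000,
) -> FeatureAnnotation:
    """Assign a peak to one genomic feature category by its summit position.

    Categories in fixed priority: promoter (0-3 kb upstream of a TSS,
    inclusive of the TSS base) > exon > intron > downstream (<= 3 kb past
    the gene end in the direction of transcription) > distal intergenic.
    ``distance_to_tss`` is the signed offset to the nearest TSS, negative
    upstream of the gene, positive downstream/inside.
    """
    if not genes:
        raise ValueError("need at least one gene model")
    pos = peak.summit_pos
    chrom = peak.chrom

    best_gene: GeneModel | None = None
    best_dist: int | None = None
    is_promoter = is_exon = is_intron = is_downstream = False
    for g in genes:
        if g.chrom != chrom:
            continue
        dist = pos - g.tss if g.strand == "+" else g.tss - pos
        if best_dist is None or abs(dist) < abs(best_dist):
            best_gene, best_dist = g, dist
        if -promoter_upstream <= dist <= 0:
            is_promoter = True
        if g.interval.contains(pos):
            if any(e.contains(pos) for e in g.exons):
                is_exon = True
            else:
                is_intron = True
        if g.strand == "+":
            if g.interval.end <= pos < g.interval.end + downstream_extent:
                is_downstream = True
        else:
            if g.interval.start - downstream_extent <= pos < g.interval.start:
                is_downstream = True

    if is_promoter:
        category = "promoter_0_3kb"
    elif is_exon:
        category = "exon"
    elif is_intron:
        category = "intron"
    elif is_downstream:
        category = "downstream"
    else:
        category = "distal_intergenic"
    return FeatureAnnotation(
        category,
        best_gene.gene_id if best_gene is not None else None,
        best_dist,
    )
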