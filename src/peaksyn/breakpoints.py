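"""Repeat-family enrichment in windows flanking synteny breakpoints.

Each syntenic block edge contributes a fixed-width window (10 kb by
default) immediately outside the block, clipped at chromosome ends and
deduplicated when blocks share a breakpoint. Per repeat family, the count
of elements overlapping the window set is contrasted against random
placements of an equivalent set of windows; two-tailed empirical p-values
are FDR-adjusted (Benjamini-Hochberg) over families whose permuted mean
count reaches a minimum (rare families are flagged untested to preserve
power).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._overlapops import count_hits_sorted
from .core import Genome, GenomicInterval, RepeatFeature


@dataclass(frozen=True)
class SyntenyBlock:
    """A pair of reference/query ranges with conserved gene order."""

    block_id: str
    ref: GenomicInterval
    query: GenomicInterval
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be + or -")


@dataclass(frozen=True)
class EnrichmentResult:
    family: str
    observed_count: int
    perm_mean: float
    perm_sd: float
    p_two_tailed: float
    fdr_q: float | None
    tested: bool


def breakpoint_windows(
    blocks: Sequence[SyntenyBlock],
    genome: Genome,
    window: int = 10_000,
    side: str = "ref",
) -> list[GenomicInterval]:
    """Fixed-width windows immediately flanking each block boundary.

    For every block edge, one window of ``window`` bp immediately outside
    the block, clipped at chromosome ends (a block starting at 0 has no
    left window). Identical windows from blocks sharing a breakpoint are
    deduplicated. ``side`` selects the reference or query genome
    coordinates of the blocks.
    """
    if side not in ("ref", "query"):
        raise ValueError("side must be 'ref' or 'query'")
    seen: set[tuple[str, int, int]] = set()
    out: list[GenomicInterval] = []
    for blk in blocks:
        iv = blk.ref if side == "ref" else blk.query
        chrom_len = genome.length_of(iv.chrom)
        for start, end in (
            (iv.start - window, iv.start),
            (iv.end, iv.end + window),
        ):
            start, end = max(0, start), min(chrom_len, end)
            if start >= end:
                continue
            key = (iv.chrom, start, end)
            if key not in seen:
                seen.add(key)
                out.append(GenomicInterval(iv.chrom, start, end))
    out.sort()
    return out


def _window_index(windows: Sequence[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        by.setdefault(w.chrom, []).append((w.start, w.end))
    out = {}
    for chrom, pairs in by.items():
        arr = np.asarray(sorted(pairs), dtype=np.int64)
        out[chrom] = (arr[:, 0], np.maximum.accumulate(arr[:, 1]))
    return out


def _count_by_family(
    index: dict[str, tuple[np.ndarray, np.ndarray]],
    elements: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    n_families: int,
) -> np.ndarray:
    counts = np.zeros(n_families, dtype=np.int64)
    for chrom, (starts, ends, fam) in elements.items():
        if chrom not in index:
            continue
        w_starts, w_maxend = index[chrom]
        hit = count_hits_sorted(w_starts, w_maxend, starts, ends)
        if hit.any():
            counts += np.bincount(fam[hit], minlength=n_families)
    return counts


def permutation_enrichment(
    windows: Sequence[GenomicInterval],
    repeats: Sequence[RepeatFeature],
    genome: Genome,
    n_iter: int = 1000,
    min_mean: float = 10.0,
    seed: int | np.random.Generator | None = None,
) -> list[EnrichmentResult]:
    """Two-tailed randomization test of repeat content in breakpoint windows.

    Observed statistic per family: number of elements overlapping >= 1
    window (each element counted once against the window set). Every
    iteration re-places the same number of windows, with the same lengths,
    uniformly at random — each window lands on a chromosome chosen with
    probability proportional to its length (among chromosomes long enough
    to hold it) and overlap among placed windows is allowed. p-values use
    the doubling convention with add-one smoothing; families whose
    permuted mean count falls below ``min_mean`` are reported untested and
    excluded from the Benjamini-Hochberg adjustment.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    families = sorted({r.family for r in repeats})
    fam_code = {f: i for i, f in enumerate(families)}
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for r in repeats:
        by_chrom.setdefault(r.interval.chrom, []).append(
            (r.interval.start, r.interval.end, fam_code[r.family])
        )
    elements = {}
    for chrom, rows in by_chrom.items():
        arr = np.asarray(rows, dtype=np.int64)
        elements[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])

    observed = _count_by_family(_window_index(windows), elements, len(families))

    chroms = [c for c, _ in genome.chromosomes]
    lengths = np.asarray([l for _, l in genome.chromosomes], dtype=np.int64)
    win_lengths = np.asarray([len(w) for w in windows], dtype=np.int64)
    if len(win_lengths) and win_lengths.max() > lengths.max():
        raise ValueError("window longer than every chromosome")

    perm_counts = np.zeros((n_iter, len(families)), dtype=np.int64)
    for it in range(n_iter):
        placed: dict[str, list[tuple[int, int]]] = {}
        for w_len in win_lengths:
            ok = lengths >= w_len
            probs = lengths * ok / (lengths * ok).sum()
            ci = rng.choice(len(chroms), p=probs)
            start = int(rng.integers(0, lengths[ci] - w_len + 1))
            placed.setdefault(chroms[ci], []).append((start, start + int(w_len)))
        index = {}
        for chrom, pairs in placed.items():
            arr = np.asarray(sorted(pairs), dtype=np.int64)
            index[chrom] = (arr[:, 0], np.maximum.accumulate(arr[:, 1]))
        perm_counts[it] = _count_by_family(index, elements, len(families))

    perm_mean = perm_counts.mean(axis=0)
    perm_sd = perm_counts.std(axis=0, ddof=0)
    p_hi = (1 + (perm_counts >= observed[None, :]).sum(axis=0)) / (n_iter + 1)
    p_lo = (1 + (perm_counts <= observed[None, :]).sum(axis=0)) / (n_iter + 1)
    p_two = np.minimum(1.0, 2 * np.minimum(p_hi, p_lo))
    tested = perm_mean >= min_mean

    qvals: dict[int, float] = {}
    if tested.any():
        _, q, _, _ = multipletests(p_two[tested], method="fdr_bh")
        for idx, qi in zip(np.flatnonzero(tested), q):
            qvals[int(idx)] = float(qi)

    return [
        EnrichmentResult(
            family=f,
            observed_count=int(observed[i]),
            perm_mean=float(perm_mean[i]),
            perm_sd=float(perm_sd[i]),
            p_two_tailed=float(p_two[i]),
            fdr_q=qvals.get(i),
            tested=bool(tested[i]),
        )
        for i, f in enumerate(families)
    ]


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": [r.family for r in results],
            "observed_count": [r.observed_count for r in results],
            "perm_mean": [r.perm_mean for r in results],
            "perm_sd": [r.perm_sd for r in results],
            "p_two_tailed": [r.p_two_tailed for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "tested": [r.tested for r in results],
        }
    )
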