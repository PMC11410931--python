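"""Vectorized interval-overlap primitives shared by the permutation tests.

References are reduced per chromosome to a sorted, merged union so that
"does interval [s, e) hit anything" becomes two searchsorted lookups. Used
internally; the public overlap semantics live in :mod:`peaksyn.core`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .core import GenomicInterval, merge_within


class MergedIndex:
    """Per-chromosome merged reference intervals with O(log n) hit queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for iv in merge_within(list(intervals), max_gap=0):
            self._starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[attr-defined]
            self._ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[attr-defined]
        for chrom in self._starts:
            self._starts[chrom] = np.asarray(self._starts[chrom], dtype=np.int64)
            self._ends[chrom] = np.asarray(self._ends[chrom], dtype=np.int64)

    def any_hit(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean array: does [start_i, end_i) overlap any reference interval.

        ``starts``/``ends`` may be of any shape (broadcast together).
        """
        ref_starts = self._starts.get(chrom)
        if ref_starts is None:
            return np.zeros(np.broadcast(starts, ends).shape, dtype=bool)
        ref_ends = self._ends[chrom]
        # refs with start < end_i form the prefix [0, idx); since merged refs
        # have increasing ends, the max end of that prefix is ref_ends[idx-1]
        idx = np.searchsorted(ref_starts, ends, side="left")
        hit = idx > 0
        hit &= np.where(hit, ref_ends[np.maximum(idx - 1, 0)], 0) > starts
        return hit


def count_hits_sorted(
    win_starts: np.ndarray,
    win_prefix_max_end: np.ndarray,
    q_starts: np.ndarray,
    q_ends: np.ndarray,
) -> np.ndarray:
    """Boolean per query: overlaps any of a start-sorted window set.

    ``win_prefix_max_end`` is the running maximum of window ends in start
    order, which handles windows of varying length.
    """
    idx = np.searchsorted(win_starts, q_ends, side="left")
    hit = idx > 0
    hit &= np.where(hit, win_prefix_max_end[np.maximum(idx - 1, 0)], 0) > q_starts
    return hit


def interval_arrays(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Group intervals into per-chromosome (starts, ends) int64 arrays."""
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by.items():
        arr = np.asarray(pairs, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out
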