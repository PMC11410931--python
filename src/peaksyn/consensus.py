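"""Replicate-consensus peak building.

A consensus peak is emitted for every maximal single-linkage cluster of
overlapping replicate peaks supported by at least ``min_entries`` distinct
biological replicates. The consensus interval spans the supporting peaks and
the consensus summit is the floored mean of the supporting summit positions.
The per-species consensus merges conditions by adding condition-specific
peaks (no wild-type overlap) to the wild-type set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import GenomicInterval, Peak
from ._overlapops import MergedIndex
import numpy as np


@dataclass
class ReplicateSet:
    """Peak calls from >= 1 biological replicates of one condition."""

    condition: str
    replicates: list[list[Peak]]

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class ConsensusPeak(Peak):
    """A consensus peak annotated with its replicate support."""

    n_support: int = 0


def consensus(replicates: ReplicateSet, min_entries: int = 3) -> list[Peak]:
    """Build the replicate-consensus peak set of one condition.

    Peaks from all replicates are pooled and clustered by single-linkage
    overlap within each chromosome. Clusters supported by >= ``min_entries``
    distinct replicates yield one consensus peak each: interval = span from
    min(start) to max(end) of the cluster, summit = floor of the mean
    absolute summit position. When more than ``min_entries`` replicates
    support a cluster, all supporting summits enter the average.
    """
    n_rep = len(replicates.replicates)
    if min_entries > n_rep:
        raise ValueError(f"min_entries={min_entries} exceeds replicate count {n_rep}")
    tagged: list[tuple[Peak, int]] = []
    for rep_idx, peaks in enumerate(replicates.replicates):
        tagged.extend((p, rep_idx) for p in peaks)
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))

    out: list[Peak] = []
    cluster: list[tuple[Peak, int]] = []
    cluster_end = -1
    cluster_chrom = None

    def flush() -> None:
        if not cluster:
            return
        support = {rep for _, rep in cluster}
        if len(support) >= min_entries:
            start = min(p.start for p, _ in cluster)
            end = max(p.end for p, _ in cluster)
            summit_abs = int(np.floor(np.mean([p.summit_pos for p, _ in cluster])))
            scores = [p.score for p, _ in cluster if p.score is not None]
            out.append(
                ConsensusPeak(
                    interval=GenomicInterval(cluster_chrom, start, end),
                    peak_id=f"{cluster_chrom}:{start}-{end}",
                    summit=summit_abs - start,
                    score=float(np.mean(scores)) if scores else None,
                    n_support=len(support),
                )
            )

    for peak, rep in tagged:
        if cluster and peak.chrom == cluster_chrom and peak.start < cluster_end:
            cluster.append((peak, rep))
            cluster_end = max(cluster_end, peak.end)
        else:
            flush()
            cluster = [(peak, rep)]
            cluster_chrom = peak.chrom
            cluster_end = peak.end
    flush()
    out.sort(key=lambda p: (p.chrom, p.start, p.end))
    return out


def merge_conditions(wt_consensus: Sequence[Peak], other_consensus: Sequence[Peak]) -> list[Peak]:
    """Species consensus: wild-type peaks plus condition-specific extras.

    A peak from the other condition is added only if it overlaps no
    wild-type peak (>= 1 bp overlap counts as a conflict; wild-type
    coordinates take precedence).
    """
    index = MergedIndex(p.interval for p in wt_consensus)
    out = list(wt_consensus)
    for p in other_consensus:
        hit = index.any_hit(p.chrom, np.asarray([p.start]), np.asarray([p.end]))
        if not bool(hit[0]):
            out.append(p)
    out.sort(key=lambda p: (p.chrom, p.start, p.end))
    return out
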