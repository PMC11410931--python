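"""Seeded generators for synthetic inputs with known truth labels.

Every stage of the pipeline can be exercised end-to-end without any
download: the generators emit replicate ATAC peak sets with tunable
reproducibility, histone-mark peaks realizing planted class fractions,
per-species alignment blocks that mix genuine ~0.5 kb conserved cores with
sub-20 bp spurious fragments, ortholog tables with tunable synteny
retention, and repeat landscapes with an optional planted enrichment in
breakpoint-flanking windows. All generators are bit-reproducible given
(seed, config) and return truth labels alongside the data, so recovery
tests compare pipeline output against the planted truth.

The default toy genome is four chromosomes of 1-2 Mb — a desk-scale
stand-in for a multi-hundred-Mb assembly. Default class fractions follow
the observed genome-wide proportions of putative promoters, putative
enhancers, K4-only and uncharacterized accessible chromatin; peak lengths
are lognormal with mean around 0.67 kb; conserved cores are normal around
555 bp.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .breakpoints import SyntenyBlock, breakpoint_windows
from .consensus import ReplicateSet
from .conservation import (
    CONSERVED_PEAK,
    CONSERVED_REGION,
    HIGH,
    NOT_CONSERVED,
    PARTIAL,
    AlignmentBlock,
    LiftoverFragmentSet,
    block_liftover,
    summit_window,
)
from .core import Genome, GenomicInterval, Peak, RepeatFeature
from .hconf import TranscriptRecord
from .synteny import OrthologTable

RECIPIENT_SPECIES = ("recipient_1", "recipient_2", "recipient_3")

# genome-wide class proportions of the reference peak universe
_DEFAULT_FRACTIONS = (13759 / 55585, 10645 / 55585, 700 / 55585, 30481 / 55585)


@dataclass
class SimulationConfig:
    """All tunables of the synthetic universe, with study-condition defaults."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (2_000_000, 1_600_000, 1_300_000, 1_000_000)
    n_peaks: int = 2000
    peak_len_log_mean: float = 6.4  # lognormal; median ~600 bp
    peak_len_log_sd: float = 0.35
    peak_len_min: int = 150
    peak_len_max: int = 1800
    n_replicates: int = 4
    reproducibility: float = 0.85  # probability a truth peak is called in a replicate
    jitter_bp: int = 20
    xray_specific_frac: float = 0.1
    # class fractions (promoter, enhancer, k4_only, uncharacterized)
    class_fractions: tuple[float, float, float, float] = _DEFAULT_FRACTIONS
    # conservation
    conservation_q: float = 0.7  # per-species probability of sequence conservation
    recipient_atac_prob: float = 1.0  # P(recipient ATAC peak | conserved core)
    core_len_mean: float = 555.0
    core_len_sd: float = 100.0
    core_len_min: int = 200
    noise_frag_max: int = 19  # spurious liftover fragments are 5..noise_frag_max bp
    # synteny
    n_orthologs: int = 2000
    synteny_retention: float = 0.9
    n_linkage_groups: int = 8
    # breakpoints / repeats
    n_blocks_per_chrom: int = 10
    repeat_families: Mapping[str, float] = field(
        default_factory=lambda: {
            "LTR/Gypsy": 40.0,
            "LINE/R2": 30.0,
            "DNA/TcMar": 25.0,
            "Unknown": 60.0,
        }
    )  # background elements per Mb
    enriched_families: tuple[str, ...] = ()
    enrichment_factor: float = 3.0
    breakpoint_window: int = 10_000
    # transcripts
    n_transcripts: int = 500

    def __post_init__(self) -> None:
        fr = self.class_fractions
        if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("class fractions must be non-negative and sum to 1")
        for name in ("reproducibility", "conservation_q", "recipient_atac_prob",
                     "synteny_retention"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def genome(self) -> Genome:
        return Genome(
            "source",
            tuple((f"chr{i + 1}", l) for i, l in enumerate(self.chrom_lengths)),
        )

    def recipient_genome(self, species: str) -> Genome:
        return Genome(
            species,
            tuple((f"chr{i + 1}", l + 50_000) for i, l in enumerate(self.chrom_lengths)),
        )


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # one independent stream per generator, derived deterministically
    return np.random.default_rng([int(cfg.seed) % (2**31), stream])


@dataclass
class PeakUniverse:
    truth_peaks: list[Peak]
    class_labels: dict[str, str]
    wt: ReplicateSet
    xray: ReplicateSet
    xray_specific: list[Peak]
    k4_peaks: list[Peak]
    k27_peaks: list[Peak]


def gen_peak_universe(cfg: SimulationConfig) -> PeakUniverse:
    """Truth peaks, jittered replicate sets, and class-consistent mark peaks.

    Truth peaks are laid out in disjoint slots so that no two peaks (or
    their flanking mark peaks) touch; each truth peak enters each replicate
    with probability ``reproducibility``, jittered by up to ``jitter_bp``.
    Histone-mark peaks are placed over each truth peak according to its
    planted class (promoter: K4+K27; enhancer: K27; k4_only: K4;
    uncharacterized: none).
    """
    from .classify import ENHANCER, K4_ONLY, PROMOTER, UNCHARACTERIZED

    rng = _rng(cfg, 1)
    genome = cfg.genome
    slot = 2500
    margin = 150
    slots = []
    for chrom, length in genome.chromosomes:
        slots.extend((chrom, s) for s in range(0, length - slot, slot))
    n_total = int(round(cfg.n_peaks * (1 + cfg.xray_specific_frac)))
    if n_total > len(slots):
        raise ValueError(
            f"genome too small for {n_total} non-overlapping peaks "
            f"({len(slots)} slots available)"
        )
    chosen = rng.choice(len(slots), size=n_total, replace=False)
    chosen.sort()

    labels = (PROMOTER, ENHANCER, K4_ONLY, UNCHARACTERIZED)
    peaks: list[Peak] = []
    class_labels: dict[str, str] = {}
    k4_peaks: list[Peak] = []
    k27_peaks: list[Peak] = []
    for idx, slot_i in enumerate(chosen):
        chrom, slot_start = slots[slot_i]
        length = int(np.clip(
            rng.lognormal(cfg.peak_len_log_mean, cfg.peak_len_log_sd),
            cfg.peak_len_min,
            min(cfg.peak_len_max, slot - 2 * margin),
        ))
        start = slot_start + int(rng.integers(margin, slot - margin - length + 1))
        summit = int(rng.integers(length // 4, 3 * length // 4 + 1))
        pid = f"peak_{idx:05d}"
        peak = Peak(GenomicInterval(chrom, start, start + length), pid, summit)
        peaks.append(peak)
        label = labels[rng.choice(4, p=cfg.class_fractions)]
        class_labels[pid] = label
        expand = int(rng.integers(20, 101))
        mark_iv = GenomicInterval(chrom, max(0, start - expand), start + length + expand)
        mlen = len(mark_iv)
        if label in (PROMOTER, K4_ONLY):
            k4_peaks.append(Peak(mark_iv, f"k4_{pid}", mlen // 2))
        if label in (PROMOTER, ENHANCER):
            k27_peaks.append(Peak(mark_iv, f"k27_{pid}", mlen // 2))

    n_xray = n_total - cfg.n_peaks
    truth_peaks = peaks[: cfg.n_peaks] if n_xray == 0 else []
    xray_specific: list[Peak] = []
    if n_xray:
        pick = set(rng.choice(n_total, size=n_xray, replace=False).tolist())
        for i, p in enumerate(peaks):
            (xray_specific if i in pick else truth_peaks).append(p)

    def make_replicates(base: list[Peak]) -> list[list[Peak]]:
        reps = []
        for _ in range(cfg.n_replicates):
            rep = []
            for p in base:
                if rng.random() > cfg.reproducibility:
                    continue
                j1 = int(rng.integers(-cfg.jitter_bp, cfg.jitter_bp + 1))
                j2 = int(rng.integers(-cfg.jitter_bp, cfg.jitter_bp + 1))
                start = max(0, p.start + j1)
                end = max(start + 50, p.end + j2)
                summit = min(max(p.summit_pos - start, 0), end - start - 1)
                rep.append(Peak(GenomicInterval(p.chrom, start, end), p.peak_id, summit))
            reps.append(rep)
        return reps

    wt = ReplicateSet("wt", make_replicates(truth_peaks))
    xray = ReplicateSet("xray", make_replicates(truth_peaks + xray_specific))
    return PeakUniverse(truth_peaks, class_labels, wt, xray, xray_specific, k4_peaks, k27_peaks)


@dataclass
class SpeciesAlignment:
    species: str
    genome: Genome
    blocks: list[AlignmentBlock]
    recipient_atac: list[Peak]
    truth_status: dict[str, str]  # peak_id -> per-species status


@dataclass
class ConservationTruth:
    alignments: dict[str, SpeciesAlignment]
    truth_aggregate: dict[str, str]  # peak_id -> high/partial/not_conserved


def gen_alignment_map(cfg: SimulationConfig, peaks: Sequence[Peak]) -> ConservationTruth:
    """Per-recipient alignment blocks, recipient ATAC peaks and truth calls.

    With probability q per species a peak gets a genuine conserved core: a
    gap-free block of ~``core_len_mean`` bp covering the summit, mapped
    co-linearly (occasionally on the minus strand) into the recipient; the
    core is covered by a recipient ATAC peak with probability
    ``recipient_atac_prob``. Otherwise the peak receives only sub-20 bp
    noise fragments (or nothing), which the cleaning step must discard.
    """
    rng = _rng(cfg, 2)
    shift = 25_000
    alignments: dict[str, SpeciesAlignment] = {}
    for species in RECIPIENT_SPECIES:
        blocks: list[AlignmentBlock] = []
        atac: list[Peak] = []
        status: dict[str, str] = {}
        for p in peaks:
            if rng.random() < cfg.conservation_q:
                core_len = int(max(cfg.core_len_min, rng.normal(cfg.core_len_mean, cfg.core_len_sd)))
                core_len = min(core_len, len(p.interval))
                lo = max(p.start, p.summit_pos - core_len + 1)
                hi = min(p.summit_pos, p.end - core_len)
                core_start = int(rng.integers(lo, hi + 1)) if hi >= lo else p.start
                core = GenomicInterval(p.chrom, core_start, core_start + core_len)
                strand = "-" if rng.random() < 0.2 else "+"
                dst = GenomicInterval(core.chrom, core.start + shift, core.end + shift)
                blocks.append(AlignmentBlock(core, dst, strand))
                if rng.random() < cfg.recipient_atac_prob:
                    a_len = int(rng.integers(300, 701))
                    center = (dst.start + dst.end) // 2
                    a_start = max(0, center - a_len // 2)
                    atac.append(
                        Peak(
                            GenomicInterval(dst.chrom, a_start, a_start + a_len),
                            f"{species}_atac_{p.peak_id}",
                            a_len // 2,
                        )
                    )
                    status[p.peak_id] = CONSERVED_PEAK
                else:
                    status[p.peak_id] = CONSERVED_REGION
            else:
                status[p.peak_id] = NOT_CONSERVED
                for _ in range(int(rng.integers(0, 4))):
                    f_len = int(rng.integers(5, cfg.noise_frag_max + 1))
                    f_start = int(rng.integers(p.start, p.end - f_len + 1))
                    frag = GenomicInterval(p.chrom, f_start, f_start + f_len)
                    dstf = GenomicInterval(p.chrom, f_start + shift, f_start + f_len + shift)
                    blocks.append(AlignmentBlock(frag, dstf, "+"))
        alignments[species] = SpeciesAlignment(
            species, cfg.recipient_genome(species), blocks, atac, status
        )
    aggregate: dict[str, str] = {}
    for p in peaks:
        statuses = [alignments[sp].truth_status[p.peak_id] for sp in RECIPIENT_SPECIES]
        if all(s == CONSERVED_PEAK for s in statuses):
            aggregate[p.peak_id] = HIGH
        elif all(s == NOT_CONSERVED for s in statuses):
            aggregate[p.peak_id] = NOT_CONSERVED
        else:
            aggregate[p.peak_id] = PARTIAL
    return ConservationTruth(alignments, aggregate)


def liftover_fragment_sets(
    peaks: Sequence[Peak],
    blocks: Sequence[AlignmentBlock],
    sum_halfwidth: int = 25,
) -> dict[str, tuple[LiftoverFragmentSet, LiftoverFragmentSet]]:
    """Project every peak (RGN) and its summit window (SUM) through blocks."""
    rgn_frames = block_liftover([p.interval for p in peaks], blocks)
    sum_frames = block_liftover([summit_window(p, sum_halfwidth) for p in peaks], blocks)
    out = {}
    for p, rgn, sm in zip(peaks, rgn_frames, sum_frames):
        out[p.peak_id] = (
            LiftoverFragmentSet(p.peak_id, "RGN", rgn),
            LiftoverFragmentSet(p.peak_id, "SUM", sm),
        )
    return out


def gen_orthologs(
    cfg: SimulationConfig,
) -> tuple[OrthologTable, pd.DataFrame, dict[str, int]]:
    """Ortholog table with retention s, linkage groups, and chrom gene totals.

    A fraction ``synteny_retention`` of orthologs keep the ancestral 1:1
    chromosome mapping; the rest land on a uniformly random chromosome of
    species B. Linkage groups partition the orthologs in contiguous
    ancestral sets (each group descends from one ancestral chromosome).
    Returns (orthologs, linkage-group assignments, per-chromosome gene
    totals for species B).
    """
    rng = _rng(cfg, 3)
    n_chrom = len(cfg.chrom_lengths)
    anc = rng.integers(0, n_chrom, size=cfg.n_orthologs)
    moved = rng.random(cfg.n_orthologs) >= cfg.synteny_retention
    b = np.where(moved, rng.integers(0, n_chrom, size=cfg.n_orthologs), anc)
    table = pd.DataFrame(
        {
            "ortholog_id": [f"og{i:05d}" for i in range(cfg.n_orthologs)],
            "chrom_A": [f"A_chr{i + 1}" for i in anc],
            "chrom_B": [f"B_chr{i + 1}" for i in b],
        }
    )
    # contiguous ancestral gene sets -> linkage groups
    groups_per_chrom = max(1, cfg.n_linkage_groups // n_chrom)
    order = np.argsort(anc, kind="stable")
    group_labels = np.empty(cfg.n_orthologs, dtype=object)
    for chrom_i in range(n_chrom):
        members = order[anc[order] == chrom_i]
        splits = np.array_split(members, groups_per_chrom)
        for j, part in enumerate(splits):
            group_labels[part] = f"ALG_{chrom_i * groups_per_chrom + j + 1:02d}"
    assignments = pd.DataFrame(
        {
            "gene_id": table["ortholog_id"],
            "group": group_labels,
            "chrom": table["chrom_B"],
        }
    )
    totals = assignments.groupby("chrom").size().to_dict()
    # unassigned background genes inflate each chromosome's total
    for i in range(n_chrom):
        chrom = f"B_chr{i + 1}"
        totals[chrom] = int(totals.get(chrom, 0) + rng.integers(200, 400))
    return OrthologTable(table, "species_A", "species_B"), assignments, totals


def gen_synteny_blocks(cfg: SimulationConfig) -> list[SyntenyBlock]:
    """Tile each chromosome with co-linear blocks at random breakpoints."""
    rng = _rng(cfg, 4)
    blocks = []
    bid = 0
    for chrom, length in cfg.genome.chromosomes:
        cuts = np.sort(rng.choice(
            np.arange(50_000, length - 50_000, 1000),
            size=cfg.n_blocks_per_chrom - 1,
            replace=False,
        ))
        bounds = [0, *cuts.tolist(), length]
        for s, e in zip(bounds[:-1], bounds[1:]):
            blocks.append(
                SyntenyBlock(
                    f"block_{bid:04d}",
                    GenomicInterval(chrom, s, e),
                    GenomicInterval(chrom, s, e),
                    "+",
                )
            )
            bid += 1
    return blocks


def gen_repeat_landscape(
    cfg: SimulationConfig, blocks: Sequence[SyntenyBlock]
) -> list[RepeatFeature]:
    """Poisson background repeats, with planted enrichment in true windows.

    Each family gets a uniform background at its configured density
    (elements per Mb); families listed in ``enriched_families``
    additionally receive rate x (e - 1) extra elements inside the true
    breakpoint-flanking windows, so their in-window density is e-fold the
    background. Zero-density families are absent from the output.
    """
    rng = _rng(cfg, 5)
    genome = cfg.genome
    windows = breakpoint_windows(blocks, genome, window=cfg.breakpoint_window)
    win_arr = [(w.chrom, w.start, w.end) for w in windows]
    total_window_bp = sum(e - s for _, s, e in win_arr)
    out: list[RepeatFeature] = []
    for family in sorted(cfg.repeat_families):
        rate = cfg.repeat_families[family]
        if rate <= 0:
            continue
        for chrom, length in genome.chromosomes:
            n = rng.poisson(rate * length / 1e6)
            for _ in range(n):
                e_len = int(rng.integers(100, 1001))
                s = int(rng.integers(0, max(1, length - e_len)))
                out.append(RepeatFeature(GenomicInterval(chrom, s, s + e_len), family))
        if family in cfg.enriched_families and cfg.enrichment_factor > 1 and win_arr:
            n_extra = rng.poisson(rate * (cfg.enrichment_factor - 1) * total_window_bp / 1e6)
            for _ in range(n_extra):
                chrom, ws, we = win_arr[rng.integers(0, len(win_arr))]
                e_len = int(rng.integers(100, 1001))
                s = int(rng.integers(ws, we))
                out.append(RepeatFeature(GenomicInterval(chrom, s, s + e_len), family))
    return out


def gen_transcripts(cfg: SimulationConfig) -> list[TranscriptRecord]:
    """Random transcript metric records spanning all filter branches."""
    rng = _rng(cfg, 6)
    out = []
    for i in range(cfg.n_transcripts):
        repeat_frac = float(rng.beta(1, 4))
        orf = int(rng.choice([int(rng.integers(10, 50)),
                              int(rng.integers(50, 100)),
                              int(rng.integers(100, 2000))],
                             p=[0.15, 0.25, 0.6]))
        tpm = float(rng.lognormal(0.0, 2.0)) if rng.random() < 0.9 else 0.0
        if rng.random() < 0.5:
            ident = float(rng.uniform(40, 100))
            cov = float(rng.uniform(40, 100))
        else:
            ident = cov = None
        out.append(TranscriptRecord(f"tx_{i:05d}", repeat_frac, orf, tpm, ident, cov))
    return out
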