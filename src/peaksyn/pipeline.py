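"""Dataset serialization and the end-to-end pipeline driver.

``write_dataset`` materializes a simulated universe as plain-text files
(narrowPeak / BED / TSV / YAML); ``load_dataset`` reads such a directory
back; ``run_all`` executes every stage on it and writes per-stage outputs
plus a machine-readable ``summary.json``. Reruns with the same config and
seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .breakpoints import SyntenyBlock, breakpoint_windows, enrichment_table, permutation_enrichment
from .classify import class_counts, classify_peaks, permute_overlap_test
from .consensus import ReplicateSet, consensus, merge_conditions
from .conservation import (
    AlignmentBlock,
    conservation_contingency_test,
    conservation_fractions,
    conserve_peak_set,
)
from .core import Genome, GenomicInterval, Peak
from .hconf import decision_frame, records_from_frame
from .simulate import (
    RECIPIENT_SPECIES,
    SimulationConfig,
    gen_alignment_map,
    gen_orthologs,
    gen_peak_universe,
    gen_repeat_landscape,
    gen_synteny_blocks,
    gen_transcripts,
    liftover_fragment_sets,
)
from .synteny import OrthologTable, chi_squared_perm_test, fisher_chromosome_enrichment, n_groups_conserved

logger = logging.getLogger("peaksyn")


@dataclasses.dataclass
class PipelineConfig:
    """Tunables of every stage, defaulting to the study parameters."""

    min_entries: int = 3
    promoter_upstream: int = 3000
    sum_halfwidth: int = 25
    min_frag: int = 20
    max_gap: int = 100
    n_perm_overlap: int = 10_000
    n_perm_synteny: int = 100_000
    n_iter_breakpoints: int = 1000
    min_mean: float = 10.0
    breakpoint_window: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _write_genome(genome: Genome, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in genome.chromosomes:
            fh.write(f"{chrom}\t{length}\n")


def _read_genome(path: Path, name: str) -> Genome:
    df = pd.read_csv(path, sep="\t")
    return Genome(name, tuple(zip(df["chrom"], df["length"].astype(int))))


def write_dataset(cfg: SimulationConfig, outdir: str | os.PathLike) -> Path:
    """Simulate a full universe and write it as a directory of text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        data = dataclasses.asdict(cfg)
        data["repeat_families"] = dict(data["repeat_families"])
        yaml.safe_dump(data, fh, sort_keys=True)

    universe = gen_peak_universe(cfg)
    _write_genome(cfg.genome, out / "genome.tsv")
    for i, rep in enumerate(universe.wt.replicates, start=1):
        pio.write_narrowpeak(rep, out / f"wt_rep{i}.narrowPeak")
    for i, rep in enumerate(universe.xray.replicates, start=1):
        pio.write_narrowpeak(rep, out / f"xray_rep{i}.narrowPeak")
    pio.write_narrowpeak(universe.k4_peaks, out / "k4.narrowPeak")
    pio.write_narrowpeak(universe.k27_peaks, out / "k27.narrowPeak")
    pio.write_narrowpeak(universe.truth_peaks, out / "truth_peaks.narrowPeak")
    pio.write_tsv(
        pd.DataFrame(
            sorted(universe.class_labels.items()), columns=["peak_id", "class"]
        ),
        out / "truth_classes.tsv",
    )

    truth = gen_alignment_map(cfg, universe.truth_peaks)
    for species, aln in truth.alignments.items():
        spdir = out / species
        spdir.mkdir(exist_ok=True)
        _write_genome(aln.genome, spdir / "genome.tsv")
        rows = [
            {
                "src_chrom": b.src.chrom, "src_start": b.src.start, "src_end": b.src.end,
                "dst_chrom": b.dst.chrom, "dst_start": b.dst.start, "dst_end": b.dst.end,
                "dst_strand": b.dst_strand,
            }
            for b in aln.blocks
        ]
        pio.write_tsv(pd.DataFrame(rows), spdir / "alignment_blocks.tsv")
        pio.write_narrowpeak(aln.recipient_atac, spdir / "atac.narrowPeak")
        pio.write_tsv(
            pd.DataFrame(sorted(aln.truth_status.items()), columns=["peak_id", "status"]),
            spdir / "truth_status.tsv",
        )
    pio.write_tsv(
        pd.DataFrame(sorted(truth.truth_aggregate.items()), columns=["peak_id", "aggregate"]),
        out / "truth_conservation.tsv",
    )

    orthologs, assignments, totals = gen_orthologs(cfg)
    pio.write_tsv(orthologs.table, out / "orthologs.tsv")
    pio.write_tsv(assignments, out / "linkage_groups.tsv")
    pio.write_tsv(
        pd.DataFrame(sorted(totals.items()), columns=["chrom", "n_genes"]),
        out / "chrom_totals.tsv",
    )

    blocks = gen_synteny_blocks(cfg)
    pio.write_tsv(
        pd.DataFrame(
            [
                {
                    "block_id": b.block_id,
                    "ref_chrom": b.ref.chrom, "ref_start": b.ref.start, "ref_end": b.ref.end,
                    "query_chrom": b.query.chrom, "query_start": b.query.start,
                    "query_end": b.query.end, "orientation": b.orientation,
                }
                for b in blocks
            ]
        ),
        out / "synteny_blocks.tsv",
    )
    pio.write_repeats(gen_repeat_landscape(cfg, blocks), out / "repeats.bed")

    tx = gen_transcripts(cfg)
    pio.write_tsv(
        pd.DataFrame(
            {
                "transcript_id": [t.transcript_id for t in tx],
                "repeat_overlap_frac": [t.repeat_overlap_frac for t in tx],
                "orf_len_aa": [t.orf_len_aa for t in tx],
                "tpm": [t.tpm for t in tx],
                "blast_identity_pct": [t.blast_identity_pct for t in tx],
                "blast_coverage_pct": [t.blast_coverage_pct for t in tx],
            }
        ),
        out / "transcripts.tsv",
    )
    return out


def read_alignment_blocks(path: str | os.PathLike) -> list[AlignmentBlock]:
    df = pio.read_tsv(path, required=["src_chrom", "src_start", "src_end",
                                      "dst_chrom", "dst_start", "dst_end", "dst_strand"])
    return [
        AlignmentBlock(
            GenomicInterval(r.src_chrom, int(r.src_start), int(r.src_end)),
            GenomicInterval(r.dst_chrom, int(r.dst_start), int(r.dst_end)),
            str(r.dst_strand),
        )
        for r in df.itertuples(index=False)
    ]


def read_synteny_blocks(path: str | os.PathLike) -> list[SyntenyBlock]:
    df = pio.read_tsv(path, required=["block_id", "ref_chrom", "ref_start", "ref_end",
                                      "query_chrom", "query_start", "query_end", "orientation"])
    return [
        SyntenyBlock(
            str(r.block_id),
            GenomicInterval(r.ref_chrom, int(r.ref_start), int(r.ref_end)),
            GenomicInterval(r.query_chrom, int(r.query_start), int(r.query_end)),
            str(r.orientation),
        )
        for r in df.itertuples(index=False)
    ]


def run_all(dataset_dir: str | os.PathLike, outdir: str | os.PathLike,
            config: PipelineConfig | None = None) -> dict:
    """Run every stage on a dataset directory and write outputs + summary.

    Stages: replicate consensus per condition -> species consensus ->
    histone-mark classification and overlap permutation tests ->
    cross-species conservation calls and the class x conservation
    contingency test -> synteny chi-squared / Cramér's V and linkage-group
    enrichment -> breakpoint repeat enrichment -> high-confidence
    transcript filter. Returns the summary dict (also written as JSON).
    """
    cfg = config or PipelineConfig()
    ds = Path(dataset_dir)
    out = Path(outdir)
    if not ds.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {ds}")
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "resolved_config.yaml")
    rng_seed = cfg.seed
    summary: dict = {"seed": rng_seed, "stages": {}}

    logger.info("stage consensus: building replicate consensus")
    genome = _read_genome(ds / "genome.tsv", "source")
    wt_reps = sorted(ds.glob("wt_rep*.narrowPeak"))
    xray_reps = sorted(ds.glob("xray_rep*.narrowPeak"))
    if not wt_reps:
        raise FileNotFoundError(f"no wt replicate narrowPeak files in {ds}")
    wt = consensus(ReplicateSet("wt", [pio.read_peaks(p) for p in wt_reps]), cfg.min_entries)
    species_peaks = wt
    if xray_reps:
        xray = consensus(
            ReplicateSet("xray", [pio.read_peaks(p) for p in xray_reps]), cfg.min_entries
        )
        species_peaks = merge_conditions(wt, xray)
    pio.write_narrowpeak(species_peaks, out / "consensus.narrowPeak")
    summary["stages"]["consensus"] = {
        "n_wt": len(wt),
        "n_species_consensus": len(species_peaks),
    }

    logger.info("stage classify: histone-mark classification")
    k4 = pio.read_peaks(ds / "k4.narrowPeak")
    k27 = pio.read_peaks(ds / "k27.narrowPeak")
    classes = classify_peaks(species_peaks, k4, k27)
    counts = class_counts(classes)
    pio.write_tsv(
        pd.DataFrame(sorted(classes.items()), columns=["peak_id", "class"]),
        out / "classes.tsv",
    )
    perm_k4 = permute_overlap_test(
        species_peaks, k4, genome, n_perm=cfg.n_perm_overlap, seed=rng_seed
    )
    perm_k27 = permute_overlap_test(
        species_peaks, k27, genome, n_perm=cfg.n_perm_overlap, seed=rng_seed + 1
    )
    summary["stages"]["classify"] = {
        "counts": counts,
        "fractions": {k: v / len(species_peaks) for k, v in counts.items()},
        "k4_overlap": dataclasses.asdict(perm_k4),
        "k27_overlap": dataclasses.asdict(perm_k27),
    }

    logger.info("stage conserve: cross-species conservation")
    liftovers = {}
    recipient_atac = {}
    for species in RECIPIENT_SPECIES:
        spdir = ds / species
        if not spdir.is_dir():
            raise FileNotFoundError(f"missing recipient directory {spdir}")
        blocks = read_alignment_blocks(spdir / "alignment_blocks.tsv")
        liftovers[species] = liftover_fragment_sets(
            species_peaks, blocks, sum_halfwidth=cfg.sum_halfwidth
        )
        recipient_atac[species] = pio.read_peaks(spdir / "atac.narrowPeak")
    records = conserve_peak_set(
        species_peaks, liftovers, recipient_atac,
        min_len=cfg.min_frag, max_gap=cfg.max_gap,
    )
    fractions = conservation_fractions(records)
    rows = []
    for rec in records:
        row = {"peak_id": rec.peak_id, "class": classes[rec.peak_id]}
        row.update({f"status_{sp}": rec.statuses[sp] for sp in RECIPIENT_SPECIES})
        row["aggregate"] = rec.aggregate
        rows.append(row)
    pio.write_tsv(pd.DataFrame(rows), out / "conservation.tsv")
    cont, posthoc = conservation_contingency_test(records, classes, seed=rng_seed)
    pio.write_tsv(posthoc, out / "conservation_posthoc.tsv")
    summary["stages"]["conserve"] = {
        "fractions": fractions,
        "chi2": cont.chi2,
        "df": cont.df,
        "p_analytic": cont.p_analytic,
        "cramers_v": cont.cramers_v,
    }

    logger.info("stage synteny: ortholog clustering statistics")
    orthologs = OrthologTable(pio.read_tsv(ds / "orthologs.tsv",
                                           required=["ortholog_id", "chrom_A", "chrom_B"]))
    syn = chi_squared_perm_test(orthologs, n_perm=cfg.n_perm_synteny, seed=rng_seed)
    assignments = pio.read_tsv(ds / "linkage_groups.tsv", required=["gene_id", "group", "chrom"])
    totals_df = pio.read_tsv(ds / "chrom_totals.tsv", required=["chrom", "n_genes"])
    totals = dict(zip(totals_df["chrom"], totals_df["n_genes"].astype(int)))
    enr = fisher_chromosome_enrichment(assignments, totals)
    pio.write_tsv(enr, out / "linkage_group_enrichment.tsv")
    summary["stages"]["synteny"] = {
        "chi2": syn.chi2,
        "df": syn.df,
        "p_analytic": syn.p_analytic,
        "p_perm": syn.p_perm,
        "cramers_v": syn.cramers_v,
        "n_orthologs": syn.n,
        "n_groups_conserved": n_groups_conserved(enr),
        "n_groups_total": int(assignments["group"].nunique()),
    }

    logger.info("stage breakpoints: repeat enrichment at synteny breakpoints")
    blocks = read_synteny_blocks(ds / "synteny_blocks.tsv")
    windows = breakpoint_windows(blocks, genome, window=cfg.breakpoint_window)
    repeats = pio.read_repeats(ds / "repeats.bed")
    enrich = permutation_enrichment(
        windows, repeats, genome,
        n_iter=cfg.n_iter_breakpoints, min_mean=cfg.min_mean, seed=rng_seed,
    )
    pio.write_tsv(enrichment_table(enrich), out / "breakpoint_enrichment.tsv")
    summary["stages"]["breakpoints"] = {
        "n_windows": len(windows),
        "n_families_tested": sum(r.tested for r in enrich),
        "n_significant_q05": sum(
            1 for r in enrich if r.tested and r.fdr_q is not None and r.fdr_q < 0.05
        ),
    }

    logger.info("stage hconf: high-confidence transcript filter")
    tx = records_from_frame(pio.read_tsv(ds / "transcripts.tsv"))
    decisions = decision_frame(tx)
    pio.write_tsv(decisions, out / "hconf.tsv")
    summary["stages"]["hconf"] = {
        "n_input": len(tx),
        "n_kept": int(decisions["kept"].sum()),
        "reasons": decisions.loc[~decisions["kept"], "reason"].value_counts().to_dict(),
    }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
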