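"""Readers and writers for the tab-separated formats the pipeline consumes.

narrowPeak (ENCODE 10-column), BED6/BED3, GFF3 (gene/exon rows only) and
plain TSV tables. All writers emit tab-separated, newline-terminated records;
all coordinates are stored 0-based half-open internally (GFF3 is converted
on read).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd

from .core import GeneModel, GenomicInterval, Peak, RepeatFeature

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "summit",
]


def _auto_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def read_peaks(path: str | os.PathLike, format: str = "narrowPeak") -> list[Peak]:
    """Read peaks from a narrowPeak or BED6 file.

    narrowPeak carries the summit as an offset in column 10 (-1 meaning
    unknown, which falls back to the interval midpoint). BED6 has no summit
    column, so the summit defaults to the interval midpoint. Peaks whose name
    column is missing or "." get a stable "{chrom}:{start}-{end}" identifier;
    identifiers must be unique.
    """
    if format not in ("narrowPeak", "BED6"):
        raise ValueError(f"unknown peak format {format!r}")
    n_cols = 10 if format == "narrowPeak" else 6
    peaks: list[Peak] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < n_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_cols} columns for "
                    f"{format}, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                score = float(fields[4]) if fields[4] not in (".", "") else None
                strand = fields[5] if fields[5] in ("+", "-", ".") else "."
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed record: {exc}") from None
            length = end - start
            if format == "narrowPeak":
                summit = int(fields[9])
                if summit == -1:
                    summit = length // 2
            else:
                summit = length // 2
            if summit >= length:
                raise ValueError(
                    f"{path}: line {lineno}: summit offset {summit} >= peak length {length}"
                )
            if name in (".", ""):
                name = _auto_id(chrom, start, end)
            if name in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate peak ID {name!r}")
            seen.add(name)
            try:
                interval = GenomicInterval(chrom, start, end, strand)
                peaks.append(Peak(interval, name, summit, score))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return peaks


def _sorted_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    return sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.peak_id))


def write_narrowpeak(peaks: Iterable[Peak], path: str | os.PathLike) -> None:
    """Write peaks as ENCODE narrowPeak, sorted by (chrom, start)."""
    with open(path, "w") as fh:
        for p in _sorted_peaks(peaks):
            score = "0" if p.score is None else f"{p.score:g}"
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{score}\t"
                f"{p.interval.strand}\t0\t-1\t-1\t{p.summit}\n"
            )


def write_bed(records: Iterable[Peak | GenomicInterval], path: str | os.PathLike) -> None:
    """Write intervals or peaks as BED6, sorted by (chrom, start)."""
    rows = []
    for r in records:
        if isinstance(r, Peak):
            rows.append((r.chrom, r.start, r.end, r.peak_id, r.score, r.interval.strand))
        else:
            rows.append((r.chrom, r.start, r.end, _auto_id(r.chrom, r.start, r.end), None, r.strand))
    rows.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            s = "0" if score is None else f"{score:g}"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{s}\t{strand}\n")


def read_bed_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read plain intervals from a BED3+ file."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def read_repeats(path: str | os.PathLike) -> list[RepeatFeature]:
    """Read repeat elements from BED with the family label in the name column."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: repeats BED needs a family name column")
            out.append(
                RepeatFeature(GenomicInterval(fields[0], int(fields[1]), int(fields[2])), fields[3])
            )
    return out


def write_repeats(repeats: Iterable[RepeatFeature], path: str | os.PathLike) -> None:
    rows = sorted(repeats, key=lambda r: (r.interval.chrom, r.interval.start, r.family))
    with open(path, "w") as fh:
        for r in rows:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t{r.family}\n")


def read_gff3_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models (gene + exon features) from GFF3.

    GFF3 is 1-based inclusive; coordinates are converted to 0-based half-open.
    Exons are attached to their gene through the Parent attribute chain
    (exon -> mRNA -> gene or exon -> gene directly).
    """
    genes: dict[str, dict] = {}
    parent_of: dict[str, str] = {}
    exon_rows: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = fields[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            start, end = int(start1) - 1, int(end1)
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ValueError(f"{path}: line {lineno}: gene without ID attribute")
                genes[gid] = {
                    "interval": GenomicInterval(chrom, start, end),
                    "strand": strand,
                    "exons": [],
                }
            elif ftype in ("mRNA", "transcript"):
                if "ID" in attr and "Parent" in attr:
                    parent_of[attr["ID"]] = attr["Parent"]
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent is not None:
                    exon_rows.append((parent, GenomicInterval(chrom, start, end)))
    for parent, iv in exon_rows:
        gid = parent_of.get(parent, parent)
        if gid in genes:
            genes[gid]["exons"].append(iv)
    out = []
    for gid, g in genes.items():
        exons = _collapse_exons(g["exons"])
        out.append(GeneModel(gid, g["interval"], g["strand"], tuple(exons)))
    return out


def _collapse_exons(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    # exons of alternative isoforms may overlap; collapse to a flat union
    from .core import merge_within

    if not exons:
        return []
    return merge_within(exons, max_gap=0)


def read_tsv(path: str | os.PathLike, required: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
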