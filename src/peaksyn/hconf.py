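"""High-confidence transcript filter.

A transcript enters the high-confidence set when it is not mostly repeat
(repeat overlap <= 75%) and clears an ORF-length-dependent expression bar:
ORFs of 100 aa or more need only trace expression (>= 0.001 TPM); ORFs of
50-99 aa need either homology support (BLAST >= 75% identity and >= 75%
coverage) with >= 1 TPM, or >= 10 TPM without it. ORFs under 50 aa are
excluded outright. Each rejection carries exactly one reason code with
precedence repeat > orf_too_short > low_expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

REASON_REPEAT = "repeat"
REASON_ORF = "orf_too_short"
REASON_EXPRESSION = "low_expression"


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    repeat_overlap_frac: float
    orf_len_aa: int
    tpm: float
    blast_identity_pct: float | None = None
    blast_coverage_pct: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.repeat_overlap_frac <= 1.0):
            raise ValueError("repeat_overlap_frac must be in [0, 1]")
        if self.orf_len_aa < 0:
            raise ValueError("orf_len_aa must be >= 0")
        if self.tpm < 0:
            raise ValueError("tpm must be >= 0")
        if (self.blast_identity_pct is None) != (self.blast_coverage_pct is None):
            raise ValueError("blast identity and coverage must be both present or both absent")


def has_blast_support(r: TranscriptRecord) -> bool:
    """Homology support: >= 75% identity AND >= 75% coverage (inclusive)."""
    return (
        r.blast_identity_pct is not None
        and r.blast_identity_pct >= 75.0
        and r.blast_coverage_pct >= 75.0
    )


def filter_high_confidence(
    records: Iterable[TranscriptRecord],
    max_repeat_frac: float = 0.75,
    long_orf_aa: int = 100,
    short_orf_aa: int = 50,
    long_orf_min_tpm: float = 0.001,
    short_orf_blast_min_tpm: float = 1.0,
    short_orf_noblast_min_tpm: float = 10.0,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Partition transcripts into the high-confidence set and reasoned rejections.

    Returns (kept records, transcript_id -> reason code for every
    rejection). More-than-75% repeat overlap is strict (exactly 0.75
    survives); all expression/length thresholds are inclusive.
    """
    kept: list[TranscriptRecord] = []
    reasons: dict[str, str] = {}
    for r in records:
        if r.repeat_overlap_frac > max_repeat_frac:
            reasons[r.transcript_id] = REASON_REPEAT
        elif r.orf_len_aa < short_orf_aa:
            reasons[r.transcript_id] = REASON_ORF
        elif r.orf_len_aa >= long_orf_aa:
            if r.tpm >= long_orf_min_tpm:
                kept.append(r)
            else:
                reasons[r.transcript_id] = REASON_EXPRESSION
        else:  # short ORF, 50-99 aa
            bar = short_orf_blast_min_tpm if has_blast_support(r) else short_orf_noblast_min_tpm
            if r.tpm >= bar:
                kept.append(r)
            else:
                reasons[r.transcript_id] = REASON_EXPRESSION
    return kept, reasons


def records_from_frame(df: pd.DataFrame) -> list[TranscriptRecord]:
    """Build records from a TSV-backed DataFrame (NaN = absent BLAST hit)."""
    required = {"transcript_id", "repeat_overlap_frac", "orf_len_aa", "tpm"}
    if not required <= set(df.columns):
        raise ValueError(f"transcript table needs columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        ident = getattr(row, "blast_identity_pct", None)
        cov = getattr(row, "blast_coverage_pct", None)
        ident = None if ident is None or pd.isna(ident) else float(ident)
        cov = None if cov is None or pd.isna(cov) else float(cov)
        out.append(
            TranscriptRecord(
                transcript_id=str(row.transcript_id),
                repeat_overlap_frac=float(row.repeat_overlap_frac),
                orf_len_aa=int(row.orf_len_aa),
                tpm=float(row.tpm),
                blast_identity_pct=ident,
                blast_coverage_pct=cov,
            )
        )
    return out


def decision_frame(records: Sequence[TranscriptRecord]) -> pd.DataFrame:
    """Per-transcript decision table: kept flag plus the rejection reason."""
    kept, reasons = filter_high_confidence(records)
    kept_ids = {r.transcript_id for r in kept}
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "kept": [r.transcript_id in kept_ids for r in records],
            "reason": [reasons.get(r.transcript_id, "") for r in records],
        }
    )
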