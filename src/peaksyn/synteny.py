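"""Macrosynteny statistics from ortholog chromosome assignments.

Single-copy ortholog pairs place each gene on one chromosome in each of two
species; synteny conservation shows up as clustering in the chromosome x
chromosome contingency table. Significance comes from Pearson chi-squared
(analytic and by permutation of one species' chromosome labels) and effect
size from Cramér's V. Ancestral-linkage-group retention is tested per
(group, chromosome) pair with one-tailed Fisher exact tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .contingency import ContingencyResult, chi2_stat, cramers_v, pearson_chi2

__all__ = [
    "OrthologTable",
    "build_contingency",
    "chi_squared_perm_test",
    "cramers_v",
    "fisher_chromosome_enrichment",
    "dotplot_table",
]


@dataclass
class OrthologTable:
    """Pairwise single-copy orthologs with chromosome-of-residence per species."""

    table: pd.DataFrame  # columns: ortholog_id, chrom_A, chrom_B
    species_a: str = "A"
    species_b: str = "B"

    def __post_init__(self) -> None:
        required = {"ortholog_id", "chrom_A", "chrom_B"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ortholog table missing columns {sorted(missing)}")
        if self.table["ortholog_id"].duplicated().any():
            raise ValueError("ortholog table must have one row per ortholog pair")

    def __len__(self) -> int:
        return len(self.table)


def build_contingency(
    orthologs: OrthologTable, exclude_unplaced: bool = True
) -> pd.DataFrame:
    """Count orthologs per (chrom_A, chrom_B) combination.

    Genes on unplaced scaffolds (chromosome labels starting with
    "scaffold", "unplaced" or "ctg") are excluded by default; the
    comparison is chromosome-scale.
    """
    df = orthologs.table
    if len(df) < 1:
        raise ValueError("need at least one ortholog")
    if exclude_unplaced:
        unplaced = ("scaffold", "unplaced", "ctg")
        keep = ~(
            df["chrom_A"].astype(str).str.lower().str.startswith(unplaced)
            | df["chrom_B"].astype(str).str.lower().str.startswith(unplaced)
        )
        df = df[keep]
    return pd.crosstab(df["chrom_A"], df["chrom_B"])


def chi_squared_perm_test(
    orthologs: OrthologTable,
    n_perm: int = 100_000,
    seed: int | np.random.Generator | None = None,
    exclude_unplaced: bool = True,
) -> ContingencyResult:
    """Chi-squared test of ortholog clustering with a permutation null.

    The null — orthologs randomly distributed across chromosomes — is
    simulated by shuffling the chrom_B column of the ortholog list, which
    preserves both chromosome margins exactly. p_perm uses add-one
    smoothing and is deterministic given the seed.
    """
    table = build_contingency(orthologs, exclude_unplaced=exclude_unplaced)
    arr = table.to_numpy(dtype=float)
    n = int(arr.sum())
    if n < 2:
        raise ValueError("need at least two orthologs")
    chi2, dof, p = pearson_chi2(arr)
    if min(arr.shape) < 2:
        return ContingencyResult(table, 0.0, 0, 1.0, 0.0, n, p_perm=None)
    v = cramers_v(arr)

    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        df = orthologs.table
        a = pd.Categorical(df["chrom_A"], categories=table.index).codes
        b = pd.Categorical(df["chrom_B"], categories=table.columns).codes
        mask = (a >= 0) & (b >= 0)  # rows excluded from the table
        a, b = a[mask].astype(np.int64), b[mask].astype(np.int64)
        n_r, n_c = arr.shape
        expected = arr.sum(axis=1, keepdims=True) @ arr.sum(axis=0, keepdims=True) / n
        exceed = 0
        for _ in range(n_perm):
            perm_b = rng.permutation(b)
            t = np.bincount(a * n_c + perm_b, minlength=n_r * n_c).reshape(n_r, n_c)
            if chi2_stat(t.astype(float), expected) >= chi2 - 1e-9:
                exceed += 1
        p_perm = (1 + exceed) / (n_perm + 1)
    return ContingencyResult(table, chi2, dof, p, v, n, p_perm)


def fisher_chromosome_enrichment(
    assignments: pd.DataFrame,
    chrom_gene_totals: Mapping[str, int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (linkage group, chromosome) enrichment by one-tailed Fisher exact.

    ``assignments`` has columns gene_id, group, chrom (each gene in at most
    one group). For every group x chromosome pair the 2x2 table
    [[in-group on-chrom, in-group off-chrom],
     [out-group on-chrom, out-group off-chrom]] is tested one-tailed for
    enrichment; p-values are Bonferroni-adjusted over all tested pairs. A
    group is considered retained ("conserved") when enriched on at least
    one chromosome at the adjusted ``alpha``.
    """
    required = {"gene_id", "group", "chrom"}
    if not required <= set(assignments.columns):
        raise ValueError(f"assignments need columns {sorted(required)}")
    if assignments["gene_id"].duplicated().any():
        raise ValueError("each gene may appear in at most one group")
    total_genes = int(sum(chrom_gene_totals.values()))
    counts = assignments.groupby(["group", "chrom"]).size()
    group_sizes = assignments.groupby("group").size()
    for chrom, on_chrom in assignments.groupby("chrom").size().items():
        if chrom not in chrom_gene_totals:
            raise ValueError(f"no gene total for chromosome {chrom!r}")
        if chrom_gene_totals[chrom] < on_chrom:
            raise ValueError(f"chromosome {chrom!r} total below assigned gene count")

    rows = []
    for group, g_size in group_sizes.items():
        if g_size == 0:
            warnings.warn(f"skipping empty group {group!r}", stacklevel=2)
            continue
        for chrom, chrom_total in chrom_gene_totals.items():
            a = int(counts.get((group, chrom), 0))
            b = int(g_size - a)
            c = chrom_total - a
            d = (total_genes - g_size) - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append(
                {"group": group, "chrom": chrom, "in_group_on_chrom": a,
                 "odds_ratio": odds, "p": p}
            )
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_adjusted"] = np.minimum(1.0, out["p"] * m)
    out["enriched"] = out["p_adjusted"] < alpha
    return out


def n_groups_conserved(enrichment: pd.DataFrame) -> int:
    """Number of linkage groups enriched on at least one chromosome."""
    return int(enrichment.groupby("group")["enriched"].any().sum())


def dotplot_table(orthologs: OrthologTable) -> pd.DataFrame:
    """Ortholog dotplot export: integer chromosome indices per axis.

    Rows: ortholog_id, x_index (species A chromosome rank), y_index
    (species B chromosome rank), chrom_A, chrom_B — enough to draw a
    macrosynteny dotplot without re-deriving chromosome orderings.
    """
    df = orthologs.table.copy()
    a_levels = sorted(df["chrom_A"].unique())
    b_levels = sorted(df["chrom_B"].unique())
    df["x_index"] = df["chrom_A"].map({c: i for i, c in enumerate(a_levels)})
    df["y_index"] = df["chrom_B"].map({c: i for i, c in enumerate(b_levels)})
    return df[["ortholog_id", "x_index", "y_index", "chrom_A", "chrom_B"]]
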