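"""Shared contingency-table machinery: Pearson chi-squared and Cramér's V."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyResult:
    """A contingency table with chi-squared, analytic/permutation p and effect size."""

    table: pd.DataFrame
    chi2: float
    df: int
    p_analytic: float
    cramers_v: float
    n: int
    p_perm: float | None = None

    def __str__(self) -> str:
        perm = "" if self.p_perm is None else f", permutation p = {self.p_perm:.3g}"
        return (
            f"Chi-squared = {self.chi2:.1f}, df = {self.df}, "
            f"p-value = {self.p_analytic:.3g}{perm}, Cramer's V = {self.cramers_v:.3f} "
            f"(n = {self.n})"
        )


def pearson_chi2(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared without continuity correction.

    Degenerate tables (one row or one column, or empty) return
    (0.0, 0, 1.0).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2 or table.sum() == 0:
        return 0.0, 0, 1.0
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def cramers_v(table: np.ndarray | pd.DataFrame) -> float:
    """Cramér's V = sqrt(chi2 / (n * (min(r, c) - 1))), in [0, 1].

    0 at exact independence, 1 at perfect association. The classic
    uncorrected statistic.
    """
    arr = np.asarray(table, dtype=float)
    n = arr.sum()
    if n < 1:
        raise ValueError("table must contain at least one observation")
    if arr.ndim != 2 or min(arr.shape) < 2:
        return 0.0
    chi2, _, _ = pearson_chi2(arr)
    k = min(arr.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))


def chi2_stat(table: np.ndarray, expected: np.ndarray) -> float:
    """Raw Pearson statistic for a precomputed expected table (cells > 0)."""
    mask = expected > 0
    diff = table[mask] - expected[mask]
    return float((diff * diff / expected[mask]).sum())
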