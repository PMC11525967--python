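"""Comparison statistics and viability tabulations.

Group comparisons mirror common practice for this kind of data: an unpaired
two-tailed t-test with Welch correction for time-to-corpse distributions, and
a two-tailed Mann-Whitney (rank-sum) test for per-cell copy numbers.  The
Mann-Whitney p-value is exact (full enumeration) for small tie-free samples
(n1 + n2 ≤ 12) and a tie-corrected normal approximation otherwise; the method
actually used is recorded in the result label.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "welch_t_test",
    "mann_whitney",
    "viability_summary",
]

EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class ComparisonResult:
    """Statistic, two-sided p-value and bookkeeping for one comparison."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value must lie in [0, 1]")


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Unpaired two-tailed t-test with Welch correction.

    Uses the Welch statistic with Welch–Satterthwaite degrees of freedom.
    Two samples with zero pooled standard error are handled explicitly:
    equal means give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    se2 = a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
    if se2 == 0.0:
        equal = a.mean() == b.mean()
        return ComparisonResult(
            0.0 if equal else math.inf,
            1.0 if equal else 0.0,
            len(a), len(b),
            "Welch t-test (degenerate: zero variance)",
        )
    res = sps.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        float(res.statistic), float(res.pvalue), len(a), len(b),
        f"Welch t-test (df={float(res.df):.2f})",
    )


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Two-tailed Mann-Whitney U test.

    Exact two-sided p by enumeration of rank assignments when
    n1 + n2 ≤ 12 and the pooled data are tie-free; otherwise a normal
    approximation with mid-ranks, tie-corrected variance and continuity
    correction.  When every pooled value is identical, U equals its null mean
    n1·n2/2 and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0.0:
        return ComparisonResult(
            len(a) * len(b) / 2.0, 1.0, len(a), len(b),
            "Mann-Whitney (degenerate: all values tied)",
        )
    if not has_ties and len(pooled) <= EXACT_MW_MAX_N:
        method, label = "exact", "Mann-Whitney (exact enumeration)"
    else:
        method, label = "asymptotic", "Mann-Whitney (tie-corrected normal approximation)"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        float(res.statistic), float(min(res.pvalue, 1.0)), len(a), len(b), label
    )


def viability_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype embryonic lethality and brood size, mean ± SD over adults.

    ``table`` rows are single adults with columns ``eggs_laid``,
    ``dead_eggs``, ``hatched`` and optionally ``genotype``.  Per adult,
    lethality = 100·dead/(dead + hatched); brood size is the eggs laid.
    Adults with zero scored eggs are excluded with a warning.
    """
    required = {"eggs_laid", "dead_eggs", "hatched"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"viability table missing columns {sorted(missing)}")
    if len(table) < 1:
        raise ValueError("viability table needs at least one adult")
    bad = table["dead_eggs"] + table["hatched"] > table["eggs_laid"]
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} adult(s) have dead + hatched > eggs laid"
        )
    df = table.copy()
    if "genotype" not in df.columns:
        df["genotype"] = "all"
    scored = df["dead_eggs"] + df["hatched"]
    if (scored == 0).any():
        warnings.warn(
            f"excluding {int((scored == 0).sum())} adult(s) with zero scored "
            "eggs from the lethality average",
            stacklevel=2,
        )
    df["lethality_pct"] = np.where(
        scored > 0, 100.0 * df["dead_eggs"] / scored.replace(0, np.nan), np.nan
    )
    rows = []
    for genotype, g in df.groupby("genotype", sort=False):
        leth = g["lethality_pct"].dropna()
        rows.append({
            "genotype": genotype,
            "n_adults": len(g),
            "lethality_mean_pct": float(leth.mean()) if len(leth) else math.nan,
            "lethality_sd_pct": float(leth.std(ddof=1)) if len(leth) > 1 else 0.0,
            "brood_mean": float(g["eggs_laid"].mean()),
            "brood_sd": float(g["eggs_laid"].std(ddof=1)) if len(g) > 1 else 0.0,
        })
    return pd.DataFrame(rows)
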