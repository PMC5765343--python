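"""Sperm-storage and fertility arithmetic.

Summaries of stored-sperm counts are reported per genotype, organ
(seminal receptacle, spermatheca, uterus, seminal vesicle) and
timepoint as mean +/- SE with the number of females dissected.  This
module reproduces the derived quantities built on those summaries:
percentage decrease in stored sperm between timepoints, fertilization
proportions with confidence intervals, and rank-based comparisons of
raw per-female counts with Bonferroni-corrected significance tiers.

Percentages are displayed with round-half-up at a caller-chosen number
of decimals (default one, trailing zeros trimmed), while full-precision
values stay available for computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .rank_stats import RankTestResult, mann_whitney_exact

__all__ = [
    "StorageCounts",
    "ProportionResult",
    "CountComparison",
    "percent_decrease",
    "percent_retained",
    "proportion",
    "storage_table",
    "compare_counts",
    "format_percent",
]

ORGANS = ("seminal_receptacle", "spermatheca", "uterus", "seminal_vesicle")


@dataclass(frozen=True)
class StorageCounts:
    """One cell of a stored-sperm summary table: mean +/- SE (N)."""

    genotype: str
    organ: str
    timepoint: str
    mean: float
    se: float
    n_females: int

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(f"organ must be one of {ORGANS}, got {self.organ!r}")
        if self.mean < 0 or self.se < 0:
            raise ValueError("mean and se must be >= 0")
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")


@dataclass(frozen=True)
class ProportionResult:
    successes: int
    total: int
    percentage: float
    ci_lower: float
    ci_upper: float
    ci_level: float
    ci_method: str

    @property
    def display(self) -> str:
        return format_percent(self.percentage)


@dataclass(frozen=True)
class CountComparison:
    result: RankTestResult
    p_adjusted: float
    k_tests: int
    tier: str  # "NS", "*", or "**"


def format_percent(value: float, decimals: int = 1) -> str:
    """Round half up to ``decimals`` and trim trailing zeros ('88' not '88.0')."""
    quant = Decimal(1).scaleb(-decimals)
    rounded = Decimal(repr(float(value))).quantize(quant, rounding=ROUND_HALF_UP)
    text = format(rounded, "f")
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return text


def percent_decrease(mean_early: float, mean_late: float) -> float:
    """Percentage drop from the early to the late timepoint: 100 (1 - late/early)."""
    if mean_early <= 0:
        raise ValueError("mean_early must be positive (undefined baseline)")
    if mean_late < 0:
        raise ValueError("mean_late must be >= 0")
    return 100.0 * (1.0 - mean_late / mean_early)


def percent_retained(mean_early: float, mean_late: float) -> float:
    """Complement of :func:`percent_decrease`: 100 * late/early."""
    if mean_early <= 0:
        raise ValueError("mean_early must be positive (undefined baseline)")
    if mean_late < 0:
        raise ValueError("mean_late must be >= 0")
    return 100.0 * mean_late / mean_early


def proportion(
    successes: int, total: int, ci_level: float = 0.95, method: str = "wilson"
) -> ProportionResult:
    """Success percentage with a Wilson score (or Clopper-Pearson) interval."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= successes <= total:
        raise ValueError("successes must lie in [0, total]")
    if method not in ("wilson", "clopper-pearson"):
        raise ValueError("method must be 'wilson' or 'clopper-pearson'")
    sm_method = "wilson" if method == "wilson" else "beta"
    lo, hi = proportion_confint(successes, total, alpha=1.0 - ci_level, method=sm_method)
    pct = 100.0 * successes / total
    # guard against sub-ulp excursions of the closed-form bounds
    lo = min(float(np.clip(100.0 * lo, 0.0, 100.0)), pct)
    hi = max(float(np.clip(100.0 * hi, 0.0, 100.0)), pct)
    return ProportionResult(
        successes=int(successes),
        total=int(total),
        percentage=pct,
        ci_lower=lo,
        ci_upper=hi,
        ci_level=ci_level,
        ci_method=method,
    )


def storage_table(
    records: Sequence[StorageCounts],
    timepoint_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Wide summary by (genotype, organ): one column set per timepoint.

    Columns per timepoint are ``mean``, ``se``, ``n`` plus a formatted
    ``display`` cell 'mean +/- se (N)'.  When a (genotype, organ) pair
    has both the first and last timepoint, ``decrease_pct`` holds the
    percentage drop from first to last.  The output is invariant to
    record order; duplicate (genotype, organ, timepoint) keys are an
    error.
    """
    if not records:
        raise ValueError("no records")
    keys = [(r.genotype, r.organ, r.timepoint) for r in records]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (genotype, organ, timepoint) records: {dupes}")
    if timepoint_order is None:
        timepoint_order = sorted({r.timepoint for r in records})
    else:
        timepoint_order = list(timepoint_order)
    by_key = {(r.genotype, r.organ, r.timepoint): r for r in records}
    index = sorted({(r.genotype, r.organ) for r in records})
    rows = []
    for genotype, organ in index:
        row: dict = {"genotype": genotype, "organ": organ}
        for tp in timepoint_order:
            rec = by_key.get((genotype, organ, tp))
            if rec is None:
                row[f"{tp}_mean"] = np.nan
                row[f"{tp}_se"] = np.nan
                row[f"{tp}_n"] = np.nan
                row[f"{tp}_display"] = ""
            else:
                row[f"{tp}_mean"] = rec.mean
                row[f"{tp}_se"] = rec.se
                row[f"{tp}_n"] = rec.n_females
                row[f"{tp}_display"] = (
                    f"{format_percent(rec.mean, 1)} ± "
                    f"{format_percent(rec.se, 1)} ({rec.n_females})"
                )
        first = by_key.get((genotype, organ, timepoint_order[0]))
        last = by_key.get((genotype, organ, timepoint_order[-1]))
        if len(timepoint_order) > 1 and first is not None and last is not None:
            row["decrease_pct"] = percent_decrease(first.mean, last.mean)
        elif len(timepoint_order) > 1:
            row["decrease_pct"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def compare_counts(
    group_a: Sequence[int],
    group_b: Sequence[int],
    adjust: str = "bonferroni",
    k_tests: int = 1,
    seed: int | None = 0,
) -> CountComparison:
    """Exact rank test on two per-female count vectors with a Bonferroni
    family of ``k_tests`` comparisons; tiers: ** adjusted p < 0.01,
    * adjusted p < 0.05, NS otherwise."""
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both count vectors must be nonempty")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be nonnegative")
    if k_tests < 1:
        raise ValueError("k_tests must be >= 1")
    if adjust not in ("none", "bonferroni"):
        raise ValueError("adjust must be 'none' or 'bonferroni'")
    result = mann_whitney_exact(a, b, seed=seed)
    p_adj = result.p_value if adjust == "none" else min(1.0, k_tests * result.p_value)
    tier = "**" if p_adj < 0.01 else "*" if p_adj < 0.05 else "NS"
    return CountComparison(result=result, p_adjusted=p_adj, k_tests=k_tests, tier=tier)
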