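"""Nonparametric test battery for small-sample group comparisons.

Implements the exact two-sided Wilcoxon-Mann-Whitney test (combinatorial
null distribution of U, doubled smaller tail), the tie-corrected
Kruskal-Wallis omnibus test, Dunn's post hoc z comparisons with a
compact letter display, Bonferroni and Holm (sequential Bonferroni)
p-value adjustment, and the Pearson chi-square contingency test.

Conventions
-----------
* The reported two-sample statistic W is the first group's U, i.e. its
  rank sum minus n1(n1+1)/2, computed with midranks when values tie.
* Two-sided p-values double the smaller tail probability and cap at 1.
* With ties the exact p comes from complete enumeration of the
  C(N, n1) group assignments of the observed pooled values when that is
  affordable, otherwise from seeded Monte-Carlo permutation (flagged as
  non-exact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSamples",
    "RankTestResult",
    "PairwiseComparisons",
    "exact_u_distribution",
    "mann_whitney_exact",
    "samples_realizing_u",
    "kruskal_wallis",
    "dunn_posthoc",
    "compact_letter_display",
    "adjust_pvalues",
    "chisq_contingency",
]

#: largest n1*n2 for which the exact U pmf is computed by default
DEFAULT_EXACT_CAP = 400
#: largest number of group assignments enumerated exhaustively with ties
DEFAULT_ENUMERATION_CAP = 2_000_000
DEFAULT_MC_PERMUTATIONS = 100_000


@dataclass
class GroupSamples:
    """Labelled measurement groups for omnibus and post hoc tests."""

    labels: list[str]
    values: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values must have equal length")
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        for lab, v in zip(self.labels, self.values):
            if v.ndim != 1 or len(v) == 0:
                raise ValueError(f"group {lab!r} must be a nonempty 1-D sample")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("group labels must be unique")

    @classmethod
    def from_dict(cls, groups: dict) -> "GroupSamples":
        return cls(labels=list(groups), values=[np.asarray(v) for v in groups.values()])

    @classmethod
    def from_long(
        cls, df: pd.DataFrame, group_col: str = "group", value_col: str = "value"
    ) -> "GroupSamples":
        labels = list(dict.fromkeys(df[group_col]))
        return cls(
            labels=[str(g) for g in labels],
            values=[df.loc[df[group_col] == g, value_col].to_numpy(float) for g in labels],
        )

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.values)


@dataclass(frozen=True)
class RankTestResult:
    statistic_name: str
    statistic_value: float
    p_value: float
    df: int | None = None
    exact: bool = False
    tie_corrected: bool = False
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class PairwiseComparisons:
    """All-pairs Dunn comparisons plus the letter display."""

    pairs: list[tuple[str, str]]
    z: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    alpha: float
    adjust: str
    letters: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_a": [a for a, _ in self.pairs],
                "group_b": [b for _, b in self.pairs],
                "z": self.z,
                "p_raw": self.p_raw,
                "p_adjusted": self.p_adjusted,
                "significant": self.significant,
            }
        )


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Integer counts of label arrangements per U value, 0..n1*n2.

    The generating function of U is the Gaussian binomial coefficient
    [n1+n2 choose n1]_q; build it by exact polynomial multiplication and
    division so every count is an exact integer.
    """

    def polymul(a: list[int], b: list[int]) -> list[int]:
        r = [0] * (len(a) + len(b) - 1)
        for i, x in enumerate(a):
            for j, y in enumerate(b):
                r[i + j] += x * y
        return r

    num = [1]
    for k in range(n2 + 1, n1 + n2 + 1):
        num = polymul(num, [1] * k)
    den = [1]
    for k in range(1, n1 + 1):
        den = polymul(den, [1] * k)
    quot = [0] * (len(num) - len(den) + 1)
    rem = num[:]
    for i in range(len(quot)):
        quot[i] = rem[i] // den[0]
        for j, d in enumerate(den):
            rem[i + j] -= quot[i] * d
    return tuple(quot)


@lru_cache(maxsize=8)
def _assignment_indices(n_total: int, n1: int) -> np.ndarray:
    """All C(n_total, n1) index sets of the first group, as an array."""
    n_assignments = math.comb(n_total, n1)
    return np.fromiter(
        (i for comb in combinations(range(n_total), n1) for i in comb),
        dtype=np.intp,
        count=n_assignments * n1,
    ).reshape(n_assignments, n1)


def exact_u_distribution(
    n1: int, n2: int, cap: int = DEFAULT_EXACT_CAP
) -> np.ndarray:
    """Exact null pmf of the Mann-Whitney U statistic (no ties).

    Returns an array of length n1*n2 + 1 with P(U = u); the counts are
    computed exactly, so the pmf sums to 1 and is symmetric about
    n1*n2/2.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if n1 * n2 > cap:
        raise ValueError(
            f"n1*n2 = {n1 * n2} exceeds the exact cap {cap}; "
            "use the asymptotic normal approximation instead"
        )
    counts = _u_counts(n1, n2)
    total = math.comb(n1 + n2, n1)
    return np.array([c / total for c in counts])


def _doubled_tail_p(cdf_le: float, cdf_ge: float) -> float:
    return min(1.0, 2.0 * min(cdf_le, cdf_ge))


def _u_from_ranks(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_exact(
    x: Sequence[float],
    y: Sequence[float],
    cap: int = DEFAULT_EXACT_CAP,
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
    mc_permutations: int = DEFAULT_MC_PERMUTATIONS,
    seed: int | None = 0,
) -> RankTestResult:
    """Exact two-sided Wilcoxon-Mann-Whitney test.

    W is the first sample's U from midranks.  Without ties the p-value
    comes from the combinatorial null distribution of U; with ties it
    comes from complete enumeration over the observed pooled values (or
    seeded Monte-Carlo permutation past ``enumeration_cap``, flagged
    ``exact=False``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = _u_from_ranks(ranks[:n1], n1)
    has_ties = len(np.unique(pooled)) < len(pooled)

    if not has_ties:
        if n1 * n2 <= cap:
            pmf = exact_u_distribution(n1, n2, cap=cap)
            wi = int(round(w))
            p = _doubled_tail_p(pmf[: wi + 1].sum(), pmf[wi:].sum())
            return RankTestResult(
                "W", w, p, exact=True, tie_corrected=False, method="exact-no-ties"
            )
        mu = n1 * n2 / 2.0
        sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        z = (w - mu) / sd
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        return RankTestResult(
            "W", w, p, exact=False, tie_corrected=False, method="normal-approximation"
        )

    n_assignments = math.comb(n1 + n2, n1)
    eps = 1e-9
    if n_assignments <= enumeration_cap:
        idx = _assignment_indices(n1 + n2, n1)
        us = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        p = _doubled_tail_p(
            float((us <= w + eps).mean()), float((us >= w - eps).mean())
        )
        return RankTestResult(
            "W", w, p, exact=True, tie_corrected=True, method="exact-enumeration-ties"
        )

    rng = np.random.default_rng(seed)
    count_le = count_ge = 0
    for _ in range(mc_permutations):
        perm = rng.permutation(ranks)
        u = perm[:n1].sum() - n1 * (n1 + 1) / 2.0
        count_le += u <= w + eps
        count_ge += u >= w - eps
    p = _doubled_tail_p(count_le / mc_permutations, count_ge / mc_permutations)
    return RankTestResult(
        "W", w, p, exact=False, tie_corrected=True, method="monte-carlo-ties"
    )


def samples_realizing_u(n1: int, n2: int, u: int) -> tuple[np.ndarray, np.ndarray]:
    """Construct tie-free samples whose first-group U equals ``u``.

    Useful for exercising the test at a published (W, n1, n2) triple:
    the p-value of a tie-free rank test depends on the data only through
    these three numbers.
    """
    if not 0 <= u <= n1 * n2:
        raise ValueError(f"u must lie in [0, {n1 * n2}]")
    counts = []
    remaining = u
    for _ in range(n1):
        c = min(n2, remaining)
        counts.append(c)
        remaining -= c
    y = np.array([10.0 * (j + 1) for j in range(n2)])
    # x_i sits strictly between the c-th and (c+1)-th y value
    x = np.array([10.0 * c + 5.0 + 0.001 * i for i, c in enumerate(counts)])
    return x, y


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tied-value groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: GroupSamples) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square upper-tail p."""
    if groups.k < 2:
        raise ValueError("at least 2 groups are required")
    n_total = groups.n_total
    if n_total < 3:
        raise ValueError("at least 3 observations are required")
    pooled = np.concatenate(groups.values)
    ranks = sps.rankdata(pooled)
    h = 0.0
    offset = 0
    for v in groups.values:
        r = ranks[offset : offset + len(v)]
        h += len(v) * (r.mean() - (n_total + 1) / 2.0) ** 2
        offset += len(v)
    h *= 12.0 / (n_total * (n_total + 1))
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    tie_corrected = correction < 1.0
    if correction <= 0.0:
        # all values identical: no rank variation at all
        return RankTestResult(
            "H", 0.0, 1.0, df=groups.k - 1, exact=False, tie_corrected=True,
            method="kruskal-wallis",
        )
    h /= correction
    p = float(sps.chi2.sf(h, groups.k - 1))
    return RankTestResult(
        "H", h, p, df=groups.k - 1, exact=False, tie_corrected=tie_corrected,
        method="kruskal-wallis",
    )


def adjust_pvalues(p: Sequence[float], method: str = "holm") -> np.ndarray:
    """Bonferroni or Holm (sequential Bonferroni) adjustment.

    Input order is preserved; Holm enforces monotonicity of the
    step-down adjusted values.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "holm":
        order = np.argsort(p, kind="stable")
        adjusted = np.empty(m)
        running_max = 0.0
        for rank, i in enumerate(order):
            running_max = max(running_max, (m - rank) * p[i])
            adjusted[i] = min(1.0, running_max)
        return adjusted
    raise ValueError(f"unknown adjustment method {method!r}")


def dunn_posthoc(
    groups: GroupSamples, alpha: float = 0.05, adjust: str = "none"
) -> PairwiseComparisons:
    """Dunn's post hoc rank comparisons after a Kruskal-Wallis test.

    For each pair (a, b) the statistic is

        z = (Rbar_a - Rbar_b) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_a + 1/n_b)]

    with T the tie term sum(t^3 - t), and a two-sided normal p-value.
    By default the raw p-values are compared against ``alpha``; pass
    ``adjust='bonferroni'`` or ``'holm'`` to correct for multiplicity.
    """
    if groups.k < 2:
        raise ValueError("at least 2 groups are required")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n_total = groups.n_total
    pooled = np.concatenate(groups.values)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    sizes = {}
    offset = 0
    for lab, v in zip(groups.labels, groups.values):
        mean_ranks[lab] = ranks[offset : offset + len(v)].mean()
        sizes[lab] = len(v)
        offset += len(v)
    variance_core = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (
        12.0 * (n_total - 1)
    )
    pairs = list(combinations(groups.labels, 2))
    z = np.empty(len(pairs))
    for i, (a, b) in enumerate(pairs):
        se = math.sqrt(variance_core * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z[i] = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
    p_raw = 2.0 * sps.norm.sf(np.abs(z))
    p_adj = adjust_pvalues(p_raw, method=adjust)
    significant = p_adj < alpha
    letters = compact_letter_display(groups.labels, pairs, significant)
    return PairwiseComparisons(
        pairs=pairs,
        z=z,
        p_raw=p_raw,
        p_adjusted=p_adj,
        significant=significant,
        alpha=alpha,
        adjust=adjust,
        letters=letters,
    )


def compact_letter_display(
    labels: Sequence[str],
    pairs: Sequence[tuple[str, str]],
    significant: Sequence[bool],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups share a letter iff no comparison between them is significant.
    Letters are assigned a, b, c ... in order of each letter set's
    earliest group.
    """
    labels = list(labels)
    if len(pairs) != len(significant):
        raise ValueError("pairs and significance flags must align")
    sets: list[set[str]] = [set(labels)]
    for (a, b), sig in zip(pairs, significant):
        if not sig:
            continue
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb subsets and duplicates
        new_sets.sort(key=len, reverse=True)
        kept: list[set[str]] = []
        for s in new_sets:
            if s and not any(s <= k for k in kept):
                kept.append(s)
        sets = kept
    index = {lab: i for i, lab in enumerate(labels)}
    sets.sort(key=lambda s: min(index[g] for g in s))
    letters = {lab: "" for lab in labels}
    for letter_idx, s in enumerate(sets):
        letter = chr(ord("a") + letter_idx)
        for lab in labels:
            if lab in s:
                letters[lab] += letter
    return letters


def chisq_contingency(table: np.ndarray) -> RankTestResult:
    """Pearson chi-square test for an r x c contingency table.

    No continuity correction; df = (r-1)(c-1).  Degenerate (all-zero)
    rows or columns are rejected.
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or np.any(table < 0):
            raise ValueError("table must contain nonnegative integer counts")
        table = np.round(table).astype(int)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has an all-zero row or column")
    res = sps.chi2_contingency(table, correction=False)
    return RankTestResult(
        "chi2",
        float(res.statistic),
        float(res.pvalue),
        df=int(res.dof),
        exact=False,
        tie_corrected=False,
        method="pearson-chi-square",
    )
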