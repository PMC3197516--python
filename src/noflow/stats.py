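"""Cohort summaries and the exact Mann–Whitney U test.

Cohorts of 10–20 scenarios are the norm here, so summaries are medians with
interquartile ranges (default quantile convention: the SPSS weighted average
at (n+1)p, R type 6) and the group comparison is the two-sided Mann–Whitney
U test, computed exactly from the full null distribution of U whenever the
samples are small and untied.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .metrics import ScenarioMetrics

__all__ = [
    "CohortSummary",
    "ComparisonResult",
    "summarize",
    "mann_whitney_exact",
    "compare_phases",
]

#: map of quantile-convention names to numpy's interpolation methods
QUANTILE_METHODS = {
    "spss": "weibull",  # weighted average at (n+1)p, R type 6 — SPSS EXAMINE default
    "linear": "linear",  # R type 7
    "r6": "weibull",
    "r7": "linear",
    "hazen": "hazen",
}


@dataclass(frozen=True)
class CohortSummary:
    metric_name: str
    n: int
    median: float
    q25: float
    q75: float


@dataclass(frozen=True)
class ComparisonResult:
    """Mann–Whitney comparison: U of the first sample and the two-sided p."""

    u_statistic: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # "exact", "exact_ties" or "normal_approx"


def summarize(
    values: Sequence[float], metric_name: str = "", quantile_method: str = "spss"
) -> CohortSummary:
    """Median and quartiles of a cohort metric under a named quantile convention."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty cohort")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    try:
        method = QUANTILE_METHODS[quantile_method]
    except KeyError:
        raise ValueError(
            f"unknown quantile method {quantile_method!r}; choose from {sorted(QUANTILE_METHODS)}"
        ) from None
    q25, med, q75 = np.quantile(arr, [0.25, 0.5, 0.75], method=method)
    return CohortSummary(metric_name, int(arr.size), float(med), float(q25), float(q75))


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

def _u_statistics(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(U1, U2) from midrank sums; U1 + U2 = n1*n2 identically."""
    n1, n2 = x.size, y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return u1, n1 * n2 - u1


def _exact_rank_sum_counts(n1: int, n2: int) -> np.ndarray:
    """counts[s] = number of n1-subsets of ranks 1..n1+n2 with rank sum s.

    Dynamic programme over items; total count is C(n1+n2, n1).
    """
    n = n1 + n2
    smax = sum(range(n - n1 + 1, n + 1))
    # dp[k, s]: subsets of size k with sum s, items processed so far
    dp = np.zeros((n1 + 1, smax + 1))
    dp[0, 0] = 1.0
    for item in range(1, n + 1):
        kmax = min(item, n1)
        for k in range(kmax, 0, -1):
            dp[k, item:] += dp[k - 1, : smax + 1 - item]
    return dp[n1]

def _exact_p_no_ties(u1: float, n1: int, n2: int) -> float:
    counts = _exact_rank_sum_counts(n1, n2)
    total = counts.sum()
    s_obs = u1 + n1 * (n1 + 1) / 2.0
    s = np.arange(counts.size)
    lo = counts[s <= s_obs + 1e-9].sum() / total
    hi = counts[s >= s_obs - 1e-9].sum() / total
    return min(1.0, 2.0 * min(lo, hi))


def _exact_p_with_ties(x: np.ndarray, y: np.ndarray, u1: float) -> float:
    """Exhaustive permutation distribution of U over all labelings (ties allowed)."""
    pooled = np.concatenate([x, y])
    n1, n = x.size, x.size + y.size
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    us = np.array(
        [sum(ranks[i] for i in combo) - offset for combo in itertools.combinations(range(n), n1)]
    )
    lo = np.mean(us <= u1 + 1e-9)
    hi = np.mean(us >= u1 - 1e-9)
    return min(1.0, 2.0 * float(min(lo, hi)))


def _normal_approx_p(u1: float, n1: int, n2: int, pooled: np.ndarray) -> float:
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return 1.0
    # continuity correction toward the mean
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / math.sqrt(var) if u1 != mu else 0.0
    return min(1.0, 2.0 * float(sps.norm.sf(abs(z))))


def mann_whitney_exact(
    x: Sequence[float],
    y: Sequence[float],
    exact_limit: int = 30,
    ties_exact_limit: int = 12,
) -> ComparisonResult:
    """Two-sided Mann–Whitney U test, exact where feasible.

    Untied samples with n1+n2 ≤ ``exact_limit`` use the exact null
    distribution of U (dynamic programme over rank-sum compositions); tied
    samples with n1+n2 ≤ ``ties_exact_limit`` use exhaustive enumeration over
    labelings; anything else falls back to the normal approximation with tie
    and continuity corrections.  The two-sided p is twice the smaller tail,
    capped at 1.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = xa.size, ya.size
    u1, _ = _u_statistics(xa, ya)
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n1 + n2 <= exact_limit:
        return ComparisonResult(u1, n1, n2, _exact_p_no_ties(u1, n1, n2), "exact")
    if has_ties and n1 + n2 <= ties_exact_limit:
        return ComparisonResult(u1, n1, n2, _exact_p_with_ties(xa, ya, u1), "exact_ties")
    return ComparisonResult(u1, n1, n2, _normal_approx_p(u1, n1, n2, pooled), "normal_approx")


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Paired Wilcoxon signed-rank variant (extension; not the primary analysis).

    Treats x and y as paired by position — appropriate when first-responder
    and team values come from the same scenario — but the primary comparison
    here mirrors the unpaired Mann–Whitney analysis.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise ValueError("paired test requires equal-length samples")
    res = sps.wilcoxon(xa, ya)
    return ComparisonResult(
        float(res.statistic), xa.size, ya.size, float(res.pvalue), "wilcoxon_paired"
    )


def compare_phases(
    cohort: Sequence[ScenarioMetrics],
    metric_name: str = "nfr",
    quantile_method: str = "spss",
    paired: bool = False,
    exact_limit: int = 30,
) -> tuple[CohortSummary, CohortSummary, ComparisonResult]:
    """First-responder vs team comparison of a per-phase metric.

    Returns the two group summaries and their two-sided Mann–Whitney result
    (or the paired Wilcoxon variant when ``paired=True``).  Significance is
    conventionally read against 0.05.
    """
    missing = [
        m.scenario_id
        for m in cohort
        if "first_responders" not in m.phases or "team" not in m.phases
    ]
    if missing:
        raise ValueError(f"scenarios lacking a handover/phase split: {missing}")
    fr = [m.phase_value("first_responders", metric_name) for m in cohort]
    team = [m.phase_value("team", metric_name) for m in cohort]
    s_fr = summarize(fr, f"first_responders.{metric_name}", quantile_method)
    s_team = summarize(team, f"team.{metric_name}", quantile_method)
    if paired:
        cmp = wilcoxon_signed_rank(fr, team)
    else:
        cmp = mann_whitney_exact(fr, team, exact_limit=exact_limit)
    return s_fr, s_team, cmp
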