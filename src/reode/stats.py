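"""Exact-statistics kernel used by every downstream stage.

Thin, validated wrappers around scipy primitives with the conventions fixed
once here: the two-sided Fisher rule is minimum-likelihood summation, the
rank-sum test is exact for small untied inputs and a continuity-corrected
normal approximation otherwise, and the odds ratio is the sample ad/bc with
infinity when bc = 0 and ad > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .model import ContingencyTable2x2

_SIDEDNESS = {"two": "two-sided", "greater": "greater", "less": "less"}


def odds_ratio_2x2(table: ContingencyTable2x2) -> float:
    """Sample odds ratio ad/bc; inf when bc = 0 and ad > 0; NaN when 0/0."""
    ad = table.a * table.d
    bc = table.b * table.c
    if bc == 0:
        return np.inf if ad > 0 else np.nan
    return ad / bc


def fisher_exact_2x2(
    table: ContingencyTable2x2, sidedness: str = "two"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``.  The two-sided p-value sums the point
    probabilities of all tables with the observed margins whose probability
    does not exceed that of the observed table (minimum-likelihood rule).
    """
    if sidedness not in _SIDEDNESS:
        raise ValueError(f"sidedness must be one of {sorted(_SIDEDNESS)}")
    _, p = sps.fisher_exact(table.as_array(), alternative=_SIDEDNESS[sidedness])
    return odds_ratio_2x2(table), float(min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values; NaN entries pass through."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if pm.size and (pm.min() < 0 or pm.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if pm.size:
        n = pm.size
        order = np.argsort(pm, kind="stable")
        ranked = pm[order] * n / np.arange(1, n + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.clip(q, 0.0, 1.0)
        unsorted = np.empty(n)
        unsorted[order] = q
        out[mask] = unsorted
    return out


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    p_value: float
    method: str  # "exact" or "normal"


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the combined sample is small (<= 20) and
    untied; tie-corrected, continuity-corrected normal approximation
    otherwise.  The branch used is reported in ``method``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    untied = np.unique(combined).size == combined.size
    if combined.size <= 20 and untied:
        method = "exact"
    else:
        method = "normal"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(float(res.statistic), float(res.pvalue), method)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both group variances are zero")
    res = sps.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if not (k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    return float(sps.hypergeom.sf(k - 1, N, K, n))
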