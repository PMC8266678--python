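"""Per-sample ternary differential-expression calling.

For each gene with enough stable partners, the reference counts (a, b) and
the within-sample counts (c, d) form a 2x2 table; a two-sided Fisher exact
test with per-sample BH adjustment yields the call:

    +1  if q <= alpha and c/(c+d) > a/(a+b)   (gene moved up)
    -1  if q <= alpha and c/(c+d) < a/(a+b)   (gene moved down)
     0  otherwise

Refinement (``max_iter`` > 1) repeats the pass with each gene's counts
recomputed over partners currently called zero, until the call vector is
unchanged or the pass budget is spent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .model import ExpressionMatrix, IDEProfile, StablePairSet
from .stats import bh_adjust


@dataclass(frozen=True)
class CallParameters:
    alpha: float = 0.05
    min_pairs: int = 5
    max_iter: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_pairs < 1:
            raise ValueError("min_pairs must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


# p-value cache keyed by (a, b, c); d is determined because a + b = c + d.
# Tables repeat heavily across the samples of a cohort.
_fisher_cache: dict[tuple[int, int, int], float] = {}


def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    key = (a, b, c)
    p = _fisher_cache.get(key)
    if p is None:
        p = float(sps.fisher_exact([[a, b], [c, d]])[1])
        _fisher_cache[key] = p
    return p


def _pass(pairs: StablePairSet, hi_above: np.ndarray, params: CallParameters,
          calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One calling pass; per gene, partners currently called != 0 are excluded."""
    n = len(pairs.gene_ids)
    hi, lo = pairs.hi, pairs.lo
    zero = calls == 0
    keep_hi = zero[lo]  # pairs usable from the hi gene's perspective
    keep_lo = zero[hi]  # pairs usable from the lo gene's perspective
    a = np.bincount(hi[keep_hi], minlength=n)
    b = np.bincount(lo[keep_lo], minlength=n)
    # c = partners the gene sits strictly above in this sample; a tie counts
    # as a reversal of the reference direction (adds to c for the lo gene)
    c = (np.bincount(hi[keep_hi & hi_above], minlength=n)
         + np.bincount(lo[keep_lo & ~hi_above], minlength=n))
    d = a + b - c
    p = np.full(n, np.nan)
    testable = (a + b) >= params.min_pairs
    for g in np.nonzero(testable)[0]:
        p[g] = _fisher_p(int(a[g]), int(b[g]), int(c[g]), int(d[g]))
    q = bh_adjust(p)
    out = np.zeros(n, dtype=np.int8)
    sig = testable & (q <= params.alpha)
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_frac = a / np.maximum(a + b, 1)
        obs_frac = c / np.maximum(c + d, 1)
    out[sig & (obs_frac > ref_frac)] = 1
    out[sig & (obs_frac < ref_frac)] = -1
    return out, p, q


def call_sample(pairs: StablePairSet, sample: np.ndarray,
                params: CallParameters = CallParameters()
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ternary calls plus raw/adjusted p-values for one sample vector.

    ``sample`` is indexed by ``pairs.gene_ids``.  Genes with fewer than
    ``min_pairs`` usable partners get call 0 and missing p/q.
    """
    if len(pairs) == 0:
        raise ValueError("empty stable pair set")
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (len(pairs.gene_ids),):
        raise ValueError("sample vector does not cover the pair-set gene universe")
    if not np.all(np.isfinite(sample)):
        raise ValueError("sample vector contains non-finite values")
    hi_above = sample[pairs.hi] > sample[pairs.lo]
    calls = np.zeros(len(pairs.gene_ids), dtype=np.int8)
    p = q = np.full(len(pairs.gene_ids), np.nan)
    for _ in range(params.max_iter):
        new_calls, p, q = _pass(pairs, hi_above, params, calls)
        if np.array_equal(new_calls, calls):
            break
        calls = new_calls
    return calls, p, q


def build_profile(expr_tumors: ExpressionMatrix, pairs: StablePairSet,
                  params: CallParameters = CallParameters()) -> IDEProfile:
    """Assemble the cohort call profile, one :func:`call_sample` per column.

    The profile's gene universe is the pair set's; the tumor matrix must
    cover every gene that appears in a stable pair.
    """
    gene_ids = pairs.gene_ids
    tumor_genes = set(expr_tumors.gene_ids)
    missing = [g for g in gene_ids if g not in tumor_genes]
    if missing:
        raise ValueError(f"tumor matrix lacks pair-set genes: {missing[:5]}")
    rows = [expr_tumors.gene_index(g) for g in gene_ids]
    values = expr_tumors.values[rows]
    n_samples = expr_tumors.n_samples
    calls = np.zeros((len(gene_ids), n_samples), dtype=np.int8)
    pvals = np.full((len(gene_ids), n_samples), np.nan)
    qvals = np.full((len(gene_ids), n_samples), np.nan)
    for j in range(n_samples):
        calls[:, j], pvals[:, j], qvals[:, j] = call_sample(pairs, values[:, j], params)
    return IDEProfile(list(gene_ids), list(expr_tumors.sample_ids),
                      calls, pvals, qvals)


def de_frequency(profile: IDEProfile) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Per-gene up/down call fractions and their cohort means.

    Returns ``(frac_up, frac_down, summary)``; summary holds ``mean_up``,
    ``mean_down`` and ``mean_total``.
    """
    if profile.n_samples == 0:
        raise ValueError("profile has no samples")
    frac_up = (profile.calls == 1).mean(axis=1)
    frac_down = (profile.calls == -1).mean(axis=1)
    summary = {
        "mean_up": float(frac_up.mean()),
        "mean_down": float(frac_down.mean()),
        "mean_total": float((frac_up + frac_down).mean()),
    }
    return frac_up, frac_down, summary
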