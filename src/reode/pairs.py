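"""Mining of stable relative expression orderings from a normal cohort.

A pair (i, j) is stable when expr[i] > expr[j] strictly in at least a
fraction ``threshold_f`` of reference samples.  Ties count against both
directions, so for f > 0.5 the two directions of an unordered pair are
mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import ExpressionMatrix, StablePairSet

# block size for the all-pairs support pass; bounds peak memory at
# ~BLOCK * n_genes * n_samples bytes of booleans
_BLOCK = 256


@dataclass
class PairEvaluation:
    """Per-gene ordering counts for one evaluated sample.

    a/b: stable partners the gene sits above/below in the reference.
    c/d: partners the gene sits above/below in the evaluated sample, with a
    tie always counted as a reversal of the reference direction.
    """

    gene_id: str
    n_high: int
    n_low: int
    sample_high: int
    sample_low: int

    def __post_init__(self) -> None:
        if min(self.n_high, self.n_low, self.sample_high, self.sample_low) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_high + self.n_low != self.sample_high + self.sample_low:
            raise ValueError("a + b must equal c + d")


def pair_support(expr_normals: ExpressionMatrix, gene_i: str, gene_j: str) -> float:
    """Fraction of reference samples with expr[gene_i] strictly > expr[gene_j]."""
    vi = expr_normals.values[expr_normals.gene_index(gene_i)]
    vj = expr_normals.values[expr_normals.gene_index(gene_j)]
    return float(np.mean(vi > vj))


def find_stable_pairs(
    expr_normals: ExpressionMatrix,
    threshold_f: float = 0.99,
    gene_subset: Sequence[str] | None = None,
) -> StablePairSet:
    """All ordered pairs with support >= threshold_f, deterministically ordered.

    Output pairs are sorted by (high_gene index, low_gene index) over the
    input gene order.  ``gene_subset`` restricts the O(G^2 N) pass.
    """
    if not (0.5 < threshold_f <= 1.0):
        raise ValueError("threshold_f must be in (0.5, 1]")
    if expr_normals.n_samples < 2:
        raise ValueError("need at least 2 reference samples")
    if gene_subset is not None:
        rows = [expr_normals.gene_index(g) for g in gene_subset]
        gene_ids = list(gene_subset)
        values = expr_normals.values[rows]
    else:
        gene_ids = list(expr_normals.gene_ids)
        values = expr_normals.values

    n_genes, n_samples = values.shape
    his: list[np.ndarray] = []
    los: list[np.ndarray] = []
    sups: list[np.ndarray] = []
    for start in range(0, n_genes, _BLOCK):
        block = values[start:start + _BLOCK]  # (B, N)
        # support[b, j] = fraction of samples with block[b] > values[j]
        gt = (block[:, None, :] > values[None, :, :]).mean(axis=2)
        bi, j = np.nonzero(gt >= threshold_f)
        i = bi + start
        keep = i != j
        his.append(i[keep])
        los.append(j[keep])
        sups.append(gt[bi[keep], j[keep]])
    hi = np.concatenate(his) if his else np.empty(0, dtype=np.int64)
    lo = np.concatenate(los) if los else np.empty(0, dtype=np.int64)
    support = np.concatenate(sups) if sups else np.empty(0, dtype=float)
    order = np.lexsort((lo, hi))
    return StablePairSet(gene_ids=gene_ids, hi=hi[order], lo=lo[order],
                         support=support[order], threshold_f=threshold_f,
                         n_normals=n_samples)


def ordering_counts(
    pairs: StablePairSet, sample: np.ndarray,
    pair_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-gene (a, b, c, d) counts for one sample vector.

    ``sample`` is indexed by ``pairs.gene_ids``.  ``pair_mask`` optionally
    drops pairs (used by the iterative refinement pass).  Returns four
    int64 arrays of length ``len(pairs.gene_ids)``.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (len(pairs.gene_ids),):
        raise ValueError("sample vector does not cover the pair-set gene universe")
    if not np.all(np.isfinite(sample)):
        raise ValueError("sample vector contains non-finite values")
    hi, lo = pairs.hi, pairs.lo
    if pair_mask is not None:
        hi, lo = hi[pair_mask], lo[pair_mask]
    n = len(pairs.gene_ids)
    hi_above = sample[hi] > sample[lo]  # tie -> False: reversal for the hi gene
    a = np.bincount(hi, minlength=n)
    b = np.bincount(lo, minlength=n)
    # c counts partners the gene is above in this sample; a tie counts as a
    # reversal of the reference direction, so it adds to c for the lo gene
    c = (np.bincount(hi[hi_above], minlength=n)
         + np.bincount(lo[~hi_above], minlength=n))
    d = a + b - c
    return (a.astype(np.int64), b.astype(np.int64),
            c.astype(np.int64), d.astype(np.int64))


def evaluate_sample(pairs: StablePairSet, sample: np.ndarray) -> list[PairEvaluation]:
    """Per-gene ordering counts for one sample, for genes with >= 1 pair."""
    a, b, c, d = ordering_counts(pairs, sample)
    return [
        PairEvaluation(pairs.gene_ids[g], int(a[g]), int(b[g]), int(c[g]), int(d[g]))
        for g in range(len(pairs.gene_ids)) if a[g] + b[g] > 0
    ]
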