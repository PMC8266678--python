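"""Prognostic gene selection, two-class clustering of ternary profiles, and
between-class statistics.

The log-rank test is implemented directly from its O/E/V sums so it can be
cross-checked against an independent survival library in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import average, fcluster, leaves_list
from scipy.spatial.distance import pdist

from .model import ContingencyTable2x2, IDEProfile
from .stats import RankSumResult, fisher_exact_2x2, wilcoxon_rank_sum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"bad survival time for {self.sample_id!r}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1 for {self.sample_id!r}")


def logrank_test(group_a: Sequence[SurvivalRecord],
                 group_b: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi_square, p).

    At each distinct event time the expected events per group come from the
    risk-set proportion with hypergeometric variance; the statistic is
    (sum(O - E))^2 / sum(V) on 1 df.
    """
    if not any(r.event for r in group_a) or not any(r.event for r in group_b):
        raise ValueError("each group needs at least one event")
    times = np.array([r.time for r in group_a] + [r.time for r in group_b])
    events = np.array([r.event for r in group_a] + [r.event for r in group_b])
    in_a = np.array([True] * len(group_a) + [False] * len(group_b))
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = int((events[(times == t)]).sum())
        d_a = int((events[(times == t) & in_a]).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n - d) * n_a * (n - n_a) / (n * n * (n - 1))
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e * o_minus_e / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def prognostic_filter(
    profile: IDEProfile,
    survival: Mapping[str, SurvivalRecord],
    alpha: float = 0.05,
    min_events: int = 3,
) -> tuple[list[str], pd.DataFrame]:
    """Genes whose call status separates survival at raw log-rank p < alpha.

    Per gene, samples with call != 0 versus call = 0; a gene is skipped
    (with a log entry) unless both strata contain >= ``min_events`` events.
    """
    samples = [s for s in profile.sample_ids if s in survival]
    sub = profile.subset_samples(samples)
    recs = [survival[s] for s in samples]
    kept, rows = [], []
    for g in range(sub.n_genes):
        called = sub.calls[g] != 0
        de = [r for r, c in zip(recs, called) if c]
        un = [r for r, c in zip(recs, called) if not c]
        ev_de = sum(r.event for r in de)
        ev_un = sum(r.event for r in un)
        if ev_de < min_events or ev_un < min_events:
            logger.info("gene %s skipped: %d/%d events in called/uncalled strata",
                        sub.gene_ids[g], ev_de, ev_un)
            continue
        chi2, p = logrank_test(de, un)
        rows.append({"gene_id": sub.gene_ids[g], "chi_square": chi2, "p": p,
                     "n_called": len(de), "n_uncalled": len(un)})
        if p < alpha:
            kept.append(sub.gene_ids[g])
    return kept, pd.DataFrame(rows)


@dataclass
class ClusteringResult:
    assignments: dict[str, int]  # sample -> class label in {1, 2}
    leaf_order: list[str]
    degenerate: bool


def cluster_two_classes(profile: IDEProfile) -> ClusteringResult:
    """Average-linkage clustering of samples on ternary call vectors, cut at 2.

    Distance is the fraction of genes with differing calls (Hamming).
    Samples are processed in sorted-ID order so ties break deterministically;
    the larger class is labelled 1 (tie: the class containing the first
    sample ID).  An all-identical profile yields a degenerate cut, flagged.
    """
    if profile.n_samples < 2 or profile.n_genes < 1:
        raise ValueError("need >= 2 samples and >= 1 gene")
    order = sorted(range(profile.n_samples), key=lambda j: profile.sample_ids[j])
    ids = [profile.sample_ids[j] for j in order]
    X = profile.calls[:, order].T.astype(float)  # samples x genes
    dist = pdist(X, metric="hamming")
    degenerate = bool(np.all(dist == 0))
    link = average(dist)
    flat = fcluster(link, t=2, criterion="maxclust")
    if len(set(flat)) < 2:
        # all distances equal (e.g. identical profiles): force a split that
        # is still deterministic, first leaf alone
        flat = np.ones(len(ids), dtype=int)
        flat[0] = 2
        degenerate = True
    size = {c: int((flat == c).sum()) for c in set(flat)}
    first = flat[0]
    ranked = sorted(size, key=lambda c: (-size[c], c != first))
    relabel = {ranked[0]: 1, ranked[1]: 2}
    assignments = {ids[j]: relabel[flat[j]] for j in range(len(ids))}
    leaf_order = [ids[j] for j in leaves_list(link)]
    return ClusteringResult(assignments, leaf_order, degenerate)


@dataclass
class CovariateComparison:
    covariate: str
    test: RankSumResult
    constant: bool


def compare_classes_continuous(
    covariates: Mapping[str, Mapping[str, float]],
    assignments: Mapping[str, int],
) -> dict[str, CovariateComparison]:
    """Two-sided rank-sum test of each covariate between the two classes.

    ``covariates`` maps covariate name -> {sample -> value}.  A covariate
    constant across both classes is reported with p = 1 and flagged; one
    missing for an entire class is an error naming the covariate.
    """
    out = {}
    for name, values in covariates.items():
        groups: dict[int, list[float]] = {1: [], 2: []}
        for s, cls in assignments.items():
            v = values.get(s)
            if v is not None and np.isfinite(v):
                groups[cls].append(float(v))
        for cls in (1, 2):
            if len(groups[cls]) < 2:
                raise ValueError(
                    f"covariate {name!r} has < 2 values in class {cls}")
        pooled = groups[1] + groups[2]
        if len(set(pooled)) == 1:
            out[name] = CovariateComparison(
                name, RankSumResult(0.0, 1.0, "degenerate"), True)
            continue
        out[name] = CovariateComparison(
            name, wilcoxon_rank_sum(groups[1], groups[2]), False)
    return out


def compare_classes_frequency(
    profile: IDEProfile,
    assignments: Mapping[str, int],
    gene_list: Sequence[str],
) -> pd.DataFrame:
    """Per-gene two-sided Fisher on upregulated (call = +1) vs not, by class."""
    samples = [s for s in profile.sample_ids if s in assignments]
    sub = profile.subset_samples(samples)
    cls = np.array([assignments[s] for s in samples])
    rows = []
    for gene in gene_list:
        g = sub.gene_ids.index(gene)
        up = sub.calls[g] == 1
        a = int((up & (cls == 1)).sum())
        b = int((~up & (cls == 1)).sum())
        c = int((up & (cls == 2)).sum())
        d = int((~up & (cls == 2)).sum())
        table = ContingencyTable2x2(a, b, c, d)
        odds, p = fisher_exact_2x2(table, "two")
        rows.append({"gene_id": gene, "up_class1": a, "not_up_class1": b,
                     "up_class2": c, "not_up_class2": d,
                     "odds_ratio": odds, "p": p})
    return pd.DataFrame(rows)


def tmb_counts(mutation, nonsilent) -> pd.DataFrame:
    """Per-sample mutation and non-silent mutation totals (column sums)."""
    if mutation.sample_ids != nonsilent.sample_ids:
        raise ValueError("mutation matrices must share samples")
    return pd.DataFrame({
        "sample_id": mutation.sample_ids,
        "n_mutations": mutation.flags.sum(axis=0).astype(int),
        "n_nonsilent": nonsilent.flags.sum(axis=0).astype(int),
    })
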