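"""Subtype-level analyses of the call profile.

Covers per-subtype over-representation of calls (one-sided Fisher vs all
other tumors, BH within subtype, frequency gate), exclusive subtype-specific
sets, UpSet-style intersection counting, call-by-alteration co-occurrence
edges, and a generic hypergeometric over-representation test for pathway
gene sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import AlterationMatrix, ContingencyTable2x2, IDEProfile
from .stats import bh_adjust, fisher_exact_2x2, hypergeom_upper_tail

logger = logging.getLogger(__name__)


def over_represented(
    profile: IDEProfile,
    subtype_labels: Mapping[str, str],
    alpha: float = 0.05,
    min_freq: float = 0.05,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Genes whose call frequency in a subtype exceeds the rest of the cohort.

    Per subtype and gene: one-sided Fisher (greater) on called-vs-not x
    in-subtype-vs-rest over labelled samples, BH across genes within the
    subtype; keep q <= alpha AND within-subtype call frequency > min_freq.
    Unlabelled samples are excluded; subtypes with < 2 samples are skipped
    with a warning.  Returns the per-subtype sets and a detail table.
    """
    labelled = [s for s in profile.sample_ids if s in subtype_labels]
    sub = profile.subset_samples(labelled)
    labels = np.array([subtype_labels[s] for s in labelled])
    de = sub.calls != 0
    sets: dict[str, set[str]] = {}
    rows = []
    for subtype in sorted(set(labels)):
        in_s = labels == subtype
        n_s, n_r = int(in_s.sum()), int((~in_s).sum())
        if n_s < 2:
            warnings.warn(f"subtype {subtype!r} has < 2 samples; skipped")
            continue
        de_s = de[:, in_s].sum(axis=1)
        de_r = de[:, ~in_s].sum(axis=1)
        pvals = np.empty(sub.n_genes)
        for g in range(sub.n_genes):
            a, b = int(de_s[g]), int(de_r[g])
            table = ContingencyTable2x2(a, b, n_s - a, n_r - b)
            _, pvals[g] = fisher_exact_2x2(table, "greater")
        qvals = bh_adjust(pvals)
        freq = de_s / n_s
        keep = (qvals <= alpha) & (freq > min_freq)
        sets[subtype] = {sub.gene_ids[g] for g in np.nonzero(keep)[0]}
        for g in range(sub.n_genes):
            rows.append({
                "subtype": subtype, "gene_id": sub.gene_ids[g],
                "n_de_subtype": int(de_s[g]), "n_subtype": n_s,
                "n_de_rest": int(de_r[g]), "n_rest": n_r,
                "freq_subtype": float(freq[g]),
                "p": float(pvals[g]), "q": float(qvals[g]),
                "over_represented": bool(keep[g]),
            })
    return sets, pd.DataFrame(rows)


def subtype_specific(over_rep_sets: Mapping[str, set[str]]) -> dict[str, set[str]]:
    """Genes over-represented in exactly one subtype."""
    counts: dict[str, int] = {}
    for genes in over_rep_sets.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return {s: {g for g in genes if counts[g] == 1}
            for s, genes in over_rep_sets.items()}


def intersection_counts(sets: Mapping[str, set[str]]) -> dict[frozenset[str], int]:
    """Exclusive (UpSet-style) membership-combination tally; zeros omitted."""
    if not sets:
        raise ValueError("need at least one set")
    universe = set().union(*sets.values())
    combos: dict[frozenset[str], int] = {}
    for g in universe:
        combo = frozenset(name for name, genes in sets.items() if g in genes)
        combos[combo] = combos.get(combo, 0) + 1
    return combos


@dataclass
class CooccurrenceEdge:
    lncRNA_id: str
    gene_id: str
    alteration_type: str
    subtype: str
    table: ContingencyTable2x2
    odds_ratio: float
    p: float


def cooccurrence_network(
    profile: IDEProfile,
    alteration: AlterationMatrix,
    subtype_samples: Sequence[str],
    lncRNA_set: Sequence[str],
    gene_set: Sequence[str],
    p_cut: float = 0.05,
    subtype: str = "",
) -> list[CooccurrenceEdge]:
    """Call-by-alteration co-occurrence edges within one subtype's samples.

    Per (lncRNA, coding gene): two-sided Fisher on |call| != 0 x flag = 1
    over the subtype samples; keep p < p_cut and odds ratio > 1.  lncRNAs
    or genes that are constant (all-altered or never-altered) across the
    samples carry no information and are skipped with a log entry.
    """
    samples = list(subtype_samples)
    if not samples:
        raise ValueError("subtype sample set is empty")
    prof = profile.subset_samples(samples)
    alt_cols = {s: j for j, s in enumerate(alteration.sample_ids)}
    missing = [s for s in samples if s not in alt_cols]
    if missing:
        raise ValueError(f"alteration matrix lacks samples: {missing[:5]}")
    cols = [alt_cols[s] for s in samples]
    n = len(samples)

    edges: list[CooccurrenceEdge] = []
    prof_rows = {g: i for i, g in enumerate(prof.gene_ids)}
    alt_rows = {g: i for i, g in enumerate(alteration.gene_ids)}
    for lnc in lncRNA_set:
        if lnc not in prof_rows:
            continue
        x = prof.calls[prof_rows[lnc]] != 0
        if x.all() or not x.any():
            logger.info("skipping constant call vector for %s", lnc)
            continue
        for gene in gene_set:
            if gene not in alt_rows:
                continue
            y = alteration.flags[alt_rows[gene]][cols].astype(bool)
            if y.all() or not y.any():
                logger.info("skipping constant alteration vector for %s", gene)
                continue
            table = ContingencyTable2x2(
                int((x & y).sum()), int((x & ~y).sum()),
                int((~x & y).sum()), int((~x & ~y).sum()))
            odds, p = fisher_exact_2x2(table, "two")
            if p < p_cut and odds > 1:
                edges.append(CooccurrenceEdge(
                    lnc, gene, alteration.alteration_type, subtype,
                    table, odds, p))
    return edges


def edges_to_frame(edges: Sequence[CooccurrenceEdge]) -> pd.DataFrame:
    return pd.DataFrame([{
        "lncRNA": e.lncRNA_id, "gene": e.gene_id, "type": e.alteration_type,
        "subtype": e.subtype, "a": e.table.a, "b": e.table.b, "c": e.table.c,
        "d": e.table.d, "odds_ratio": e.odds_ratio, "p": e.p,
    } for e in edges])


def ora_hypergeometric(
    selected: set[str],
    pathways: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each pathway.

    Pathways are intersected with the universe first; p is the upper tail
    P(overlap >= observed); q is BH across pathways.
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    names, overlaps, pvals, sizes = [], [], [], []
    for name, members in pathways.items():
        members = members & universe
        k = len(selected & members)
        p = hypergeom_upper_tail(len(universe), len(members), len(selected), k)
        names.append(name)
        overlaps.append(k)
        sizes.append(len(members))
        pvals.append(p)
    q = bh_adjust(pvals) if pvals else []
    return pd.DataFrame({"pathway": names, "pathway_size": sizes,
                         "overlap": overlaps, "p": pvals, "q": q})
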