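"""Association of call status with clinical drug response and cell-line
drug-sensitivity (ActArea) values."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ContingencyTable2x2, IDEProfile
from .stats import WelchResult, fisher_exact_2x2, welch_t

logger = logging.getLogger(__name__)

GROUP_RULES = {
    "down_vs_unaltered": (-1, 0),
    "up_vs_unaltered": (1, 0),
    "de_vs_unaltered": ("de", 0),
}


@dataclass
class DrugAssociation:
    lncRNA_id: str
    drug: str
    table: ContingencyTable2x2  # [[DE & resp, DE & non-resp], [not-DE & resp, not-DE & non-resp]]
    odds_ratio: float
    p: float
    direction: str  # sensitivity | resistance


def clinical_response_association(
    profile: IDEProfile,
    responses: pd.DataFrame,
    drug: str,
    alpha: float = 0.05,
) -> list[DrugAssociation]:
    """Per-lncRNA two-sided Fisher of call status vs responder status.

    ``responses`` has columns (sample_id, drug, response) with response in
    {responder, non-responder}; only samples treated with ``drug`` and
    present in the profile are used.  Associations with p < alpha are kept;
    direction is sensitivity when the DE-by-responder odds ratio exceeds 1.
    """
    treated = responses[responses["drug"] == drug]
    if treated.empty:
        raise ValueError(f"drug {drug!r} absent from the response table")
    status = {r.sample_id: r.response for r in treated.itertuples()}
    samples = [s for s in profile.sample_ids if s in status]
    sub = profile.subset_samples(samples)
    responder = np.array([status[s] == "responder" for s in samples])
    if responder.sum() < 2 or (~responder).sum() < 2:
        raise ValueError(
            f"need >= 2 responders and >= 2 non-responders for {drug!r}")
    out = []
    for g in range(sub.n_genes):
        de = sub.calls[g] != 0
        table = ContingencyTable2x2(
            int((de & responder).sum()), int((de & ~responder).sum()),
            int((~de & responder).sum()), int((~de & ~responder).sum()))
        odds, p = fisher_exact_2x2(table, "two")
        if p < alpha:
            direction = "sensitivity" if odds > 1 else "resistance"
            out.append(DrugAssociation(sub.gene_ids[g], drug, table, odds, p,
                                       direction))
    return out


@dataclass
class ActAreaAssociation:
    lncRNA_id: str
    drug: str
    group_rule: str
    n_de: int
    n_ref: int
    de_mean: float
    ref_mean: float
    test: WelchResult
    resistance: bool  # DE group mean ActArea lower than reference group


def cellline_actarea_association(
    profile: IDEProfile,
    actarea: pd.DataFrame,
    drug: str,
    group_rule: str = "down_vs_unaltered",
    lncRNA_ids: list[str] | None = None,
) -> list[ActAreaAssociation]:
    """Welch's t on ActArea between call-defined cell-line groups.

    ``actarea`` has columns (cell_line, drug, act_area).  ``group_rule``
    picks the partition: downregulated vs unaltered (default), upregulated
    vs unaltered, or any-call vs unaltered.  Lines lacking either a call or
    an ActArea value are dropped; a lncRNA whose groups fall below 2 lines
    is skipped with a log entry.
    """
    if group_rule not in GROUP_RULES:
        raise ValueError(f"group_rule must be one of {sorted(GROUP_RULES)}")
    de_target, ref_target = GROUP_RULES[group_rule]
    treated = actarea[(actarea["drug"] == drug) & actarea["act_area"].notna()]
    if treated.empty:
        raise ValueError(f"drug {drug!r} absent from the ActArea table")
    values = dict(zip(treated["cell_line"], treated["act_area"].astype(float)))
    lines = [s for s in profile.sample_ids if s in values]
    sub = profile.subset_samples(lines)
    aa = np.array([values[s] for s in lines])
    genes = lncRNA_ids if lncRNA_ids is not None else sub.gene_ids
    out = []
    for gene in genes:
        g = sub.gene_ids.index(gene)
        calls = sub.calls[g]
        de_mask = (calls != 0) if de_target == "de" else (calls == de_target)
        ref_mask = calls == ref_target
        if de_mask.sum() < 2 or ref_mask.sum() < 2:
            logger.info("lncRNA %s skipped for %s: group sizes %d/%d",
                        gene, drug, int(de_mask.sum()), int(ref_mask.sum()))
            continue
        de_vals, ref_vals = aa[de_mask], aa[ref_mask]
        res = welch_t(de_vals, ref_vals)
        out.append(ActAreaAssociation(
            gene, drug, group_rule, int(de_mask.sum()), int(ref_mask.sum()),
            float(de_vals.mean()), float(ref_vals.mean()), res,
            resistance=bool(de_vals.mean() < ref_vals.mean()),
        ))
    return out
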