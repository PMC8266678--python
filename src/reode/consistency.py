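"""Agreement between expression calls and CNV / promoter-methylation flags.

An up call is supported by amplification or hypomethylation of the same
gene in the same sample; a down call by deletion or hypermethylation.  A
call counts as consistent when ANY supporting alteration is flagged, even
if a contradicting one co-occurs.  Samples carrying no alteration flag at
all for the gene are excluded from the denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import AlterationMatrix, IDEProfile, DOWN_SUPPORTING, UP_SUPPORTING


@dataclass
class ConsistencyRecord:
    gene_id: str
    n_evaluable: int
    n_consistent: int
    ratio: float
    category: str  # full | partial | none | no_data

    def __post_init__(self) -> None:
        if self.n_consistent > self.n_evaluable:
            raise ValueError("n_consistent exceeds n_evaluable")


def _categorize(n_eval: int, n_cons: int) -> tuple[float, str]:
    if n_eval == 0:
        return float("nan"), "no_data"
    ratio = n_cons / n_eval
    if ratio == 1.0:
        return ratio, "full"
    if ratio == 0.0:
        return ratio, "none"
    return ratio, "partial"


def consistency_ratio(
    profile: IDEProfile,
    alterations: Sequence[AlterationMatrix],
    top_k: int = 100,
) -> list[ConsistencyRecord]:
    """Consistency records for the ``top_k`` most frequently called genes.

    Genes are ranked by total call frequency, descending, ties broken by
    lexicographic gene ID.  Order of the supplied alteration matrices does
    not matter.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    total = np.abs(profile.calls).sum(axis=1)
    order = sorted(range(profile.n_genes),
                   key=lambda g: (-int(total[g]), profile.gene_ids[g]))
    kept = order[:top_k]

    sample_pos = {s: j for j, s in enumerate(profile.sample_ids)}
    # per alteration matrix, map of gene -> flag row aligned to profile samples
    aligned: list[tuple[str, dict[str, np.ndarray]]] = []
    for alt in alterations:
        cols = np.array([sample_pos.get(s, -1) for s in alt.sample_ids])
        ok = cols >= 0
        rows = {}
        for gi, g in enumerate(alt.gene_ids):
            row = np.zeros(profile.n_samples, dtype=bool)
            row[cols[ok]] = alt.flags[gi, ok].astype(bool)
            rows[g] = row
        aligned.append((alt.alteration_type, rows))

    records = []
    for g in kept:
        gid = profile.gene_ids[g]
        calls = profile.calls[g]
        up_support = np.zeros(profile.n_samples, dtype=bool)
        down_support = np.zeros(profile.n_samples, dtype=bool)
        any_flag = np.zeros(profile.n_samples, dtype=bool)
        for alt_type, rows in aligned:
            row = rows.get(gid)
            if row is None:
                continue
            any_flag |= row
            if alt_type in UP_SUPPORTING:
                up_support |= row
            if alt_type in DOWN_SUPPORTING:
                down_support |= row
        called = calls != 0
        evaluable = called & any_flag
        consistent = evaluable & (((calls == 1) & up_support)
                                  | ((calls == -1) & down_support))
        n_eval = int(evaluable.sum())
        n_cons = int(consistent.sum())
        ratio, category = _categorize(n_eval, n_cons)
        records.append(ConsistencyRecord(gid, n_eval, n_cons, ratio, category))
    return records


def consistency_census(records: Sequence[ConsistencyRecord]) -> dict[str, int]:
    """Tally of full / partial / none / no_data categories."""
    if not records:
        raise ValueError("no records to tally")
    return dict(Counter(r.category for r in records))
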