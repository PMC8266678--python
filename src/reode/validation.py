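"""Paired-cohort validation of the calling machinery.

Two checks: a k-fold cross-validation in which calls made on held-out
tumors (with pairs mined from training normals only) are scored against the
sign of the tumor-minus-matched-normal delta, and a fold-change comparison
contrasting called genes with never-called genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .individualize import CallParameters, call_sample
from .model import IDEProfile, PairedCohort
from .pairs import find_stable_pairs
from .stats import RankSumResult, wilcoxon_rank_sum


@dataclass
class FoldResult:
    fold_index: int
    lncRNA_accuracy: dict[str, float]
    sample_accuracy: dict[str, float]
    n_calls_evaluated: int


@dataclass
class ValidationResult:
    folds: list[FoldResult]
    mean_lncRNA_accuracy: float
    mean_sample_accuracy: float
    #: pooled per-gene concordant/evaluated counts over all folds
    gene_concordant: dict[str, int] = field(default_factory=dict)
    gene_evaluated: dict[str, int] = field(default_factory=dict)


def kfold_paired_validation(
    cohort: PairedCohort,
    k: int = 5,
    threshold_f: float = 0.99,
    params: CallParameters = CallParameters(),
    seed: int = 0,
) -> ValidationResult:
    """Seeded k-fold validation of calls against matched-normal deltas.

    Pairs are shuffled into k folds.  Per fold, stable pairs come from the
    training normals; every held-out tumor is called; a non-zero call
    (gene, sample, v) is concordant iff sign(tumor - matched normal) == v,
    with a zero delta counted discordant.  Gene-level accuracy pools
    concordant/evaluated counts across folds; sample-level accuracy is per
    held-out sample.  The reported means average over genes (samples) with
    at least one evaluated call.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    tumor_ids = sorted(cohort.pairing)
    if k > len(tumor_ids):
        raise ValueError(f"k={k} exceeds {len(tumor_ids)} pairs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tumor_ids))
    fold_of = np.empty(len(tumor_ids), dtype=int)
    fold_of[order] = np.arange(len(tumor_ids)) % k

    gene_ids = cohort.normal.gene_ids
    gene_conc: dict[str, int] = {g: 0 for g in gene_ids}
    gene_eval: dict[str, int] = {g: 0 for g in gene_ids}
    sample_acc_all: dict[str, float] = {}
    folds: list[FoldResult] = []

    for fold in range(k):
        test_tumors = [t for t, f in zip(tumor_ids, fold_of) if f == fold]
        train_tumors = [t for t, f in zip(tumor_ids, fold_of) if f != fold]
        train_normals = [cohort.pairing[t] for t in train_tumors]
        pairs = find_stable_pairs(cohort.normal.subset_samples(train_normals),
                                  threshold_f)
        rows = [cohort.tumor.gene_index(g) for g in pairs.gene_ids]
        fold_gene_conc: dict[str, int] = {}
        fold_gene_eval: dict[str, int] = {}
        fold_sample_acc: dict[str, float] = {}
        n_eval = 0
        for t in test_tumors:
            x = cohort.tumor.sample_vector(t)[rows]
            calls, _, _ = call_sample(pairs, x, params)
            normal_vec = cohort.normal.sample_vector(cohort.pairing[t])[rows]
            delta = x - normal_vec
            called = np.nonzero(calls)[0]
            conc = 0
            for g in called:
                ok = int(np.sign(delta[g]) == calls[g])  # delta == 0 -> discordant
                gid = pairs.gene_ids[g]
                gene_conc[gid] += ok
                gene_eval[gid] += 1
                fold_gene_conc[gid] = fold_gene_conc.get(gid, 0) + ok
                fold_gene_eval[gid] = fold_gene_eval.get(gid, 0) + 1
                conc += ok
            if called.size:
                fold_sample_acc[t] = conc / called.size
                sample_acc_all[t] = conc / called.size
            n_eval += called.size
        folds.append(FoldResult(
            fold_index=fold,
            lncRNA_accuracy={g: fold_gene_conc[g] / fold_gene_eval[g]
                             for g in fold_gene_eval},
            sample_accuracy=fold_sample_acc,
            n_calls_evaluated=n_eval,
        ))

    gene_acc = {g: gene_conc[g] / gene_eval[g] for g in gene_ids if gene_eval[g] > 0}
    mean_gene = float(np.mean(list(gene_acc.values()))) if gene_acc else float("nan")
    mean_sample = (float(np.mean(list(sample_acc_all.values())))
                   if sample_acc_all else float("nan"))
    return ValidationResult(folds, mean_gene, mean_sample, gene_conc, gene_eval)


@dataclass
class FCStratum:
    ide_genes: list[str]
    non_ide_genes: list[str]
    ide_median: float
    non_ide_median: float
    test: RankSumResult | None


def fc_compare(cohort: PairedCohort, profile: IDEProfile) -> dict[str, FCStratum]:
    """Contrast paired log2 fold changes of called vs never-called genes.

    Per gene, log2FC = median over pairs of log2((tumor+1)/(normal+1)).
    A gene is grouped as called-with-consistent-direction when it is called
    non-zero in >= 1 profiled sample and its majority call sign matches the
    sign of its median log2FC; genes never called are the comparison group.
    Strata ("up", "down") split both groups by log2FC sign; an empty
    stratum side yields no test.
    """
    tumor_ids = sorted(cohort.pairing)
    missing = [t for t in tumor_ids if t not in set(profile.sample_ids)]
    if missing:
        raise ValueError(f"profile does not cover paired tumors: {missing[:5]}")
    gene_ids = profile.gene_ids
    t_rows = [cohort.tumor.gene_index(g) for g in gene_ids]
    t_cols = [cohort.tumor.sample_ids.index(t) for t in tumor_ids]
    n_cols = [cohort.normal.sample_ids.index(cohort.pairing[t]) for t in tumor_ids]
    tum = cohort.tumor.values[np.ix_(t_rows, t_cols)]
    nor = cohort.normal.values[np.ix_(t_rows, n_cols)]
    log2fc = np.median(np.log2((tum + 1.0) / (nor + 1.0)), axis=1)

    calls = profile.calls
    n_up = (calls == 1).sum(axis=1)
    n_down = (calls == -1).sum(axis=1)
    ever_called = (n_up + n_down) > 0
    majority_sign = np.sign(n_up - n_down)  # 0 on an up/down tie
    consistent = ever_called & (majority_sign == np.sign(log2fc)) & (majority_sign != 0)

    out: dict[str, FCStratum] = {}
    for name, side in (("up", 1), ("down", -1)):
        ide_idx = np.nonzero(consistent & (np.sign(log2fc) == side))[0]
        non_idx = np.nonzero(~ever_called & (np.sign(log2fc) == side))[0]
        ide_vals, non_vals = log2fc[ide_idx], log2fc[non_idx]
        test = None
        if ide_vals.size and non_vals.size:
            test = wilcoxon_rank_sum(ide_vals, non_vals)
        out[name] = FCStratum(
            ide_genes=[gene_ids[i] for i in ide_idx],
            non_ide_genes=[gene_ids[i] for i in non_idx],
            ide_median=float(np.median(ide_vals)) if ide_vals.size else float("nan"),
            non_ide_median=float(np.median(non_vals)) if non_vals.size else float("nan"),
            test=test,
        )
    return out


def paired_log2fc(cohort: PairedCohort, gene_ids: list[str] | None = None) -> np.ndarray:
    """Median-over-pairs log2((tumor+1)/(normal+1)) per gene."""
    genes = gene_ids if gene_ids is not None else cohort.normal.gene_ids
    tumor_ids = sorted(cohort.pairing)
    rows = [cohort.tumor.gene_index(g) for g in genes]
    t_cols = [cohort.tumor.sample_ids.index(t) for t in tumor_ids]
    n_cols = [cohort.normal.sample_ids.index(cohort.pairing[t]) for t in tumor_ids]
    tum = cohort.tumor.values[np.ix_(rows, t_cols)]
    nor = cohort.normal.values[np.ix_(rows, n_cols)]
    return np.median(np.log2((tum + 1.0) / (nor + 1.0)), axis=1)
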