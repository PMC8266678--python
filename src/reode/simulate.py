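"""Ground-truth synthetic datasets with the statistical structure every
pipeline stage assumes.

Expression is log-normal: gene g has a fixed baseline log2-mean drawn once,
and each sample adds independent log2-scale noise, so orderings between
well-separated genes are stable by construction.  Tumors are fresh draws
from the same process with planted genes multiplied by 2^(+-effect).
Each planted gene carries one direction (down more often than up); its
per-sample dysregulation probability is set so the cohort-mean fraction of
dysregulated (gene, sample) entries hits the configured target exactly in
expectation, after accounting for subtype- and class-coupled genes.

All randomness flows from one seed through named sub-streams, so adding a
stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    AlterationMatrix,
    ExpressionMatrix,
    IDEProfile,
    PairedCohort,
    SampleAnnotation,
)

_UP_TYPES = ("amplification", "hypomethylation")
_DOWN_TYPES = ("deletion", "hypermethylation")
_CNV_METH = _UP_TYPES + _DOWN_TYPES


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 300
    n_normals: int = 50
    n_tumors: int = 300
    baseline_log_spread: float = 2.0   # sd of per-gene baseline log2 mean
    noise_sd: float = 0.3              # within-gene log2-scale noise
    frac_dysregulated_genes: float = 1.0
    de_sample_frac: float = 0.098      # target cohort-mean DE fraction
    down_frac: float = 0.122           # target mean down-call fraction
    up_frac: float = 0.068             # target mean up-call fraction
    effect_log2fc: float = 4.0
    n_subtypes: int = 3
    subtype_genes_per_subtype: int = 4
    subtype_de_frac: float = 0.4       # within the home subtype
    background_de_frac: float = 0.02   # subtype genes, outside home subtype
    n_prognostic_genes: int = 6
    prognostic_de_frac_class2: float = 0.6
    prognostic_de_frac_class1: float = 0.05
    class2_prob: float = 0.25
    hazard_ratio: float = 4.0          # class-2 hazard multiplier
    base_hazard: float = 1e-3          # events per day for class 1
    censor_horizon: float = 2000.0     # days
    consistency_prob: float = 0.9
    background_alteration_rate: float = 0.01
    mutation_rate: float = 0.05
    nonsilent_given_mutation: float = 0.7
    n_drug_genes: int = 2
    drug_odds_ratio: float = 6.0
    drug_base_response: float = 0.4
    drug_name: str = "drugA"
    # Planted direction respects dynamic range: rank-based calling cannot
    # see a further decrease of a gene already at the expression floor (its
    # reversal signal is capped by its few below-partners), so genes in the
    # bottom baseline quantile are planted up, the top quantile down, and
    # the middle band draws its direction with a probability adjusted to
    # keep the overall down:up ratio at its target in expectation.
    floor_quantile: float = 0.2
    ceiling_quantile: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dysregulated_genes", "de_sample_frac", "down_frac",
                     "up_frac", "subtype_de_frac", "background_de_frac",
                     "prognostic_de_frac_class2", "prognostic_de_frac_class1",
                     "class2_prob", "consistency_prob",
                     "background_alteration_rate", "mutation_rate",
                     "nonsilent_given_mutation", "drug_base_response"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be positive")
        if not (0.0 <= self.floor_quantile < self.ceiling_quantile <= 1.0):
            raise ValueError("need 0 <= floor_quantile < ceiling_quantile <= 1")
        n_special = (self.n_subtypes * self.subtype_genes_per_subtype
                     + self.n_prognostic_genes + self.n_drug_genes)
        if n_special > self.n_genes:
            raise ValueError(
                f"{n_special} planted genes exceed n_genes={self.n_genes}")

    @property
    def p_down(self) -> float:
        total = self.down_frac + self.up_frac
        return self.down_frac / total if total > 0 else 0.5


@dataclass
class GroundTruth:
    status: np.ndarray                       # genes x tumors, {-1, 0, +1}
    gene_direction: dict[str, int]           # planted gene -> +1/-1
    subtype_of_gene: dict[str, str]          # subtype-planted gene -> label
    latent_class: dict[str, int]             # tumor sample -> 1/2
    prognostic_genes: list[str]
    drug_genes: list[str]
    seed: int


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    cohort: PairedCohort                     # normals + all tumors, paired subset
    annotations: list[SampleAnnotation]
    alterations: dict[str, AlterationMatrix]
    responses: pd.DataFrame                  # sample_id, drug, response
    truth: GroundTruth

    @property
    def tumors(self) -> ExpressionMatrix:
        return self.cohort.tumor

    @property
    def normals(self) -> ExpressionMatrix:
        return self.cohort.normal


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]))


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw a complete dataset; byte-identical for identical configs."""
    cfg = config
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    normal_ids = [f"N{j:04d}" for j in range(cfg.n_normals)]
    tumor_ids = [f"T{j:04d}" for j in range(cfg.n_tumors)]

    # --- gene role allocation (deterministic given the seed) --------------
    rng_alloc = _rng(cfg.seed, "allocation")
    perm = rng_alloc.permutation(cfg.n_genes)
    cursor = 0
    subtype_names = [f"S{i + 1}" for i in range(cfg.n_subtypes)]
    subtype_of_gene: dict[str, str] = {}
    for name in subtype_names:
        for _ in range(cfg.subtype_genes_per_subtype):
            subtype_of_gene[genes[perm[cursor]]] = name
            cursor += 1
    prognostic = [genes[perm[cursor + i]] for i in range(cfg.n_prognostic_genes)]
    cursor += cfg.n_prognostic_genes
    drug_genes = [genes[perm[cursor + i]] for i in range(cfg.n_drug_genes)]
    cursor += cfg.n_drug_genes
    remaining = [genes[perm[i]] for i in range(cursor, cfg.n_genes)]
    n_bg_eligible = int(round(cfg.frac_dysregulated_genes * len(remaining)))
    background = remaining[:n_bg_eligible]

    # --- sample-level latent structure ------------------------------------
    rng_lat = _rng(cfg.seed, "latent")
    subtype_of_sample = {
        t: subtype_names[rng_lat.integers(cfg.n_subtypes)] if cfg.n_subtypes else None
        for t in tumor_ids}
    latent_class = {t: 2 if rng_lat.random() < cfg.class2_prob else 1
                    for t in tumor_ids}

    # --- ground-truth status ----------------------------------------------
    # Background per-sample probability is solved so the expected cohort
    # mean DE fraction over ALL genes equals de_sample_frac.
    share = 1.0 / cfg.n_subtypes if cfg.n_subtypes else 0.0
    exp_subtype = (cfg.subtype_de_frac * share
                   + cfg.background_de_frac * (1.0 - share))
    exp_prog = (cfg.prognostic_de_frac_class2 * cfg.class2_prob
                + cfg.prognostic_de_frac_class1 * (1.0 - cfg.class2_prob))
    n_subtype_genes = len(subtype_of_gene)
    special_mass = n_subtype_genes * exp_subtype + len(prognostic) * exp_prog
    n_bg = len(background) + len(drug_genes)
    target_mass = cfg.de_sample_frac * cfg.n_genes
    q_bg = (target_mass - special_mass) / n_bg if n_bg else 0.0
    if cfg.frac_dysregulated_genes == 0.0:
        q_bg = 0.0
    if not (0.0 <= q_bg <= 1.0):
        raise ValueError(
            f"infeasible config: background DE probability {q_bg:.3f} "
            "outside [0, 1]; adjust de_sample_frac or planted frequencies")

    # Baseline log2 means are drawn before the truth so planted directions
    # can respect each gene's dynamic range (see floor/ceiling_quantile).
    rng_expr = _rng(cfg.seed, "expression")
    baseline = 5.0 + cfg.baseline_log_spread * rng_expr.standard_normal(cfg.n_genes)
    pct = np.argsort(np.argsort(baseline)) / max(cfg.n_genes - 1, 1)
    mid_share = cfg.ceiling_quantile - cfg.floor_quantile
    top_share = 1.0 - cfg.ceiling_quantile
    p_down_mid = ((cfg.p_down - top_share) / mid_share) if mid_share else 0.5
    p_down_mid = float(np.clip(p_down_mid, 0.0, 1.0))

    rng_truth = _rng(cfg.seed, "truth")
    gene_idx = {g: i for i, g in enumerate(genes)}
    status = np.zeros((cfg.n_genes, cfg.n_tumors), dtype=np.int8)
    gene_direction: dict[str, int] = {}
    planted = (list(subtype_of_gene) + list(prognostic) + list(drug_genes)
               + list(background))
    for g in planted:
        q = pct[gene_idx[g]]
        if q < cfg.floor_quantile:
            gene_direction[g] = 1
        elif q >= cfg.ceiling_quantile:
            gene_direction[g] = -1
        else:
            gene_direction[g] = -1 if rng_truth.random() < p_down_mid else 1
    sub_arr = np.array([subtype_of_sample[t] for t in tumor_ids])
    cls_arr = np.array([latent_class[t] for t in tumor_ids])
    for g, home in subtype_of_gene.items():
        prob = np.where(sub_arr == home, cfg.subtype_de_frac, cfg.background_de_frac)
        hit = rng_truth.random(cfg.n_tumors) < prob
        status[gene_idx[g], hit] = gene_direction[g]
    for g in prognostic:
        prob = np.where(cls_arr == 2, cfg.prognostic_de_frac_class2,
                        cfg.prognostic_de_frac_class1)
        hit = rng_truth.random(cfg.n_tumors) < prob
        status[gene_idx[g], hit] = gene_direction[g]
    for g in drug_genes + background:
        hit = rng_truth.random(cfg.n_tumors) < q_bg
        status[gene_idx[g], hit] = gene_direction[g]

    # --- expression -------------------------------------------------------
    normal_log = baseline[:, None] + cfg.noise_sd * rng_expr.standard_normal(
        (cfg.n_genes, cfg.n_normals))
    tumor_log = baseline[:, None] + cfg.noise_sd * rng_expr.standard_normal(
        (cfg.n_genes, cfg.n_tumors))
    tumor_log = tumor_log + cfg.effect_log2fc * status
    normals = ExpressionMatrix(genes, normal_ids, np.exp2(normal_log))
    tumors = ExpressionMatrix(genes, tumor_ids, np.exp2(tumor_log))
    n_pairs = min(cfg.n_normals, cfg.n_tumors)
    pairing = {tumor_ids[j]: normal_ids[j] for j in range(n_pairs)}
    cohort = PairedCohort(normals, tumors, pairing)

    # --- survival + covariates --------------------------------------------
    rng_surv = _rng(cfg.seed, "survival")
    annotations = []
    for j, t in enumerate(tumor_ids):
        hazard = cfg.base_hazard * (cfg.hazard_ratio if latent_class[t] == 2 else 1.0)
        raw = rng_surv.exponential(1.0 / hazard)
        time = min(raw, cfg.censor_horizon)
        event = int(raw <= cfg.censor_horizon)
        hrd = rng_surv.normal(20.0 if latent_class[t] == 2 else 35.0, 8.0)
        annotations.append(SampleAnnotation(
            sample_id=t, subtype=subtype_of_sample[t],
            surv_time=float(time), surv_event=event,
            covariates={"hrd_score": float(hrd)},
        ))

    # --- alteration matrices ----------------------------------------------
    rng_alt = _rng(cfg.seed, "alterations")
    flags = {k: np.zeros((cfg.n_genes, cfg.n_tumors), dtype=np.int8)
             for k in _CNV_METH}
    for k in _CNV_METH:
        flags[k] |= (rng_alt.random((cfg.n_genes, cfg.n_tumors))
                     < cfg.background_alteration_rate).astype(np.int8)
    gi, sj = np.nonzero(status)
    for g, s in zip(gi, sj):
        if rng_alt.random() < cfg.consistency_prob:
            pool = _UP_TYPES if status[g, s] > 0 else _DOWN_TYPES
        else:
            pool = _CNV_METH
        flags[pool[rng_alt.integers(len(pool))]][g, s] = 1
    mut = (rng_alt.random((cfg.n_genes, cfg.n_tumors))
           < cfg.mutation_rate).astype(np.int8)
    nonsilent = mut & (rng_alt.random((cfg.n_genes, cfg.n_tumors))
                       < cfg.nonsilent_given_mutation).astype(np.int8)
    alterations = {k: AlterationMatrix(k, genes, tumor_ids, flags[k])
                   for k in _CNV_METH}
    alterations["mutation"] = AlterationMatrix("mutation", genes, tumor_ids, mut)
    alterations["nonsilent_mutation"] = AlterationMatrix(
        "nonsilent_mutation", genes, tumor_ids, nonsilent)

    # --- drug response ----------------------------------------------------
    rng_drug = _rng(cfg.seed, "drug")
    drug_rows = [gene_idx[g] for g in drug_genes]
    base_odds = cfg.drug_base_response / (1.0 - cfg.drug_base_response)
    rows = []
    for j, t in enumerate(tumor_ids):
        has_de = bool(drug_rows) and bool(np.any(status[drug_rows, j] != 0))
        odds = base_odds * (cfg.drug_odds_ratio if has_de else 1.0)
        p_resp = odds / (1.0 + odds)
        rows.append({"sample_id": t, "drug": cfg.drug_name,
                     "response": "responder" if rng_drug.random() < p_resp
                     else "non-responder"})
    responses = pd.DataFrame(rows)

    truth = GroundTruth(status=status, gene_direction=gene_direction,
                        subtype_of_gene=dict(subtype_of_gene),
                        latent_class=latent_class,
                        prognostic_genes=prognostic, drug_genes=drug_genes,
                        seed=cfg.seed)
    return SimulatedDataset(cfg, cohort, annotations, alterations, responses, truth)


def truth_profile(dataset: SimulatedDataset) -> IDEProfile:
    """The ground-truth status matrix wrapped as a call profile."""
    status = dataset.truth.status
    shape = status.shape
    return IDEProfile(
        list(dataset.tumors.gene_ids), list(dataset.tumors.sample_ids),
        status.copy(), np.full(shape, np.nan), np.full(shape, np.nan))


def truth_metrics(profile: IDEProfile, truth: GroundTruth) -> dict[str, float]:
    """Precision/recall of non-zero calls against planted statuses.

    Precision counts a call as correct only when its sign matches the
    planted status; recall is the matched fraction of planted entries; sign
    accuracy is scored over entries that are non-zero in both.  Undefined
    ratios (empty denominators) are returned as NaN.
    """
    calls = profile.calls
    if calls.shape != truth.status.shape:
        raise ValueError("profile and truth shapes differ")
    called = calls != 0
    planted = truth.status != 0
    correct = called & planted & (calls == truth.status)
    n_called = int(called.sum())
    n_planted = int(planted.sum())
    both = called & planted
    return {
        "precision": correct.sum() / n_called if n_called else float("nan"),
        "recall": correct.sum() / n_planted if n_planted else float("nan"),
        "sign_accuracy": (float((calls[both] == truth.status[both]).mean())
                          if both.any() else float("nan")),
    }


def two_archetype_profile(
    n_genes: int = 30, n_class1: int = 30, n_class2: int = 10,
    noise: float = 0.1, seed: int = 0,
) -> tuple[IDEProfile, dict[str, int]]:
    """Ternary profiles drawn from two archetypes with per-entry call noise.

    Archetype 1 is all zeros on the second half of genes and -1/+1 blocks
    on the first; archetype 2 is its mirror.  Each entry is replaced by a
    uniformly drawn different value with probability ``noise``.  Returns
    the profile and the true class of each sample.
    """
    rng = np.random.default_rng(seed)
    half = n_genes // 2
    arch1 = np.concatenate([np.ones(half, dtype=np.int8) * -1,
                            np.zeros(n_genes - half, dtype=np.int8)])
    arch2 = np.concatenate([np.zeros(half, dtype=np.int8),
                            np.ones(n_genes - half, dtype=np.int8)])
    samples, classes = [], {}
    cols = []
    for j in range(n_class1 + n_class2):
        cls = 1 if j < n_class1 else 2
        sid = f"C{j:03d}"
        base = (arch1 if cls == 1 else arch2).copy()
        flip = rng.random(n_genes) < noise
        for g in np.nonzero(flip)[0]:
            choices = [v for v in (-1, 0, 1) if v != base[g]]
            base[g] = choices[rng.integers(2)]
        cols.append(base)
        samples.append(sid)
        classes[sid] = cls
    calls = np.column_stack(cols)
    shape = calls.shape
    genes = [f"PG{i:03d}" for i in range(n_genes)]
    return (IDEProfile(genes, samples, calls, np.full(shape, np.nan),
                       np.full(shape, np.nan)), classes)
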