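"""End-to-end orchestration: run every stage whose inputs are present.

The pipeline is a fixed linear order of stages; a stage with missing
optional inputs is skipped and noted in the manifest, a stage that raises
aborts the run naming itself.  Outputs are plain TSV/JSON under the output
directory, and the manifest records parameters and sha256 hashes of every
written file, so an unchanged re-run is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import io as rio
from .consistency import consistency_census, consistency_ratio
from .drugs import clinical_response_association
from .individualize import CallParameters, build_profile, de_frequency
from .model import PairedCohort
from .pairs import find_stable_pairs
from .prognosis import (
    SurvivalRecord,
    cluster_two_classes,
    compare_classes_continuous,
    prognostic_filter,
)
from .subtypes import (
    cooccurrence_network,
    edges_to_frame,
    over_represented,
    subtype_specific,
)
from .validation import kfold_paired_validation

logger = logging.getLogger(__name__)

_ALTERATION_KEYS = ("mutation", "nonsilent_mutation", "amplification",
                    "deletion", "hypermethylation", "hypomethylation")


@dataclass
class PipelineConfig:
    out_dir: str
    normals: str | None = None
    tumors: str | None = None
    pairing: str | None = None
    annotations: str | None = None
    responses: str | None = None
    alterations: dict[str, str] = field(default_factory=dict)
    threshold_f: float = 0.99
    alpha: float = 0.05
    min_pairs: int = 5
    max_iter: int = 2
    subtype_alpha: float = 0.05
    subtype_min_freq: float = 0.05
    cooccurrence_p_cut: float = 0.05
    consistency_top_k: int = 100
    prognostic_alpha: float = 0.05
    focal_subtype: str | None = None
    drugs: list[str] = field(default_factory=list)
    k_folds: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def call_parameters(self) -> CallParameters:
        return CallParameters(alpha=self.alpha, min_pairs=self.min_pairs,
                              max_iter=self.max_iter)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Run the stage chain; returns (and writes) the manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict[str, Any] = {
        "parameters": {k: v for k, v in asdict(config).items()},
        "stages": {},
        "outputs": {},
    }
    t0 = time.time()

    # timings go to the log only; the manifest must be byte-stable across
    # re-runs with unchanged inputs
    def record(stage: str, status: str, note: str = "") -> None:
        manifest["stages"][stage] = {"status": status, "note": note}
        logger.info("stage %s: %s %s (t=%.2fs)", stage, status, note,
                    time.time() - t0)

    def out(name: str) -> str:
        return os.path.join(config.out_dir, name)

    def run_stage(stage, fn):
        try:
            return fn()
        except Exception as exc:
            record(stage, "error", str(exc))
            _write_manifest(manifest, config.out_dir)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stable pairs -----------------------------------------------------
    pairs = None
    if config.normals:
        def _pairs():
            normals = rio.read_expression_tsv(config.normals)
            p = find_stable_pairs(normals, config.threshold_f)
            rio.write_stable_pairs_tsv(p, out("stable_pairs.tsv"))
            return p
        pairs = run_stage("stable_pairs", _pairs)
        record("stable_pairs", "complete", f"{len(pairs)} pairs")
    else:
        record("stable_pairs", "skipped", "no normals input")

    # --- individualize ----------------------------------------------------
    profile = None
    if pairs is not None and config.tumors:
        def _profile():
            tumors = rio.read_expression_tsv(config.tumors)
            prof = build_profile(tumors, pairs, config.call_parameters())
            rio.write_profile(prof, out("profile"))
            fu, fd, summary = de_frequency(prof)
            pd.DataFrame({"gene_id": prof.gene_ids, "frac_up": fu,
                          "frac_down": fd}).to_csv(
                out("de_frequency.tsv"), sep="\t", index=False)
            with open(out("de_summary.json"), "w", encoding="utf-8") as fh:
                json.dump(summary, fh, indent=2)
            return prof
        profile = run_stage("individualize", _profile)
        record("individualize", "complete",
               f"{profile.n_genes} genes x {profile.n_samples} samples")
    else:
        record("individualize", "skipped", "missing normals or tumors input")

    # --- paired evaluation ------------------------------------------------
    if config.normals and config.tumors and config.pairing:
        def _evaluate():
            normals = rio.read_expression_tsv(config.normals)
            tumors = rio.read_expression_tsv(config.tumors)
            pairing = rio.read_pairing_tsv(config.pairing)
            cohort = PairedCohort(normals, tumors, pairing)
            res = kfold_paired_validation(
                cohort, k=config.k_folds, threshold_f=config.threshold_f,
                params=config.call_parameters(), seed=config.seed)
            pd.DataFrame([{
                "fold": f.fold_index, "n_calls": f.n_calls_evaluated,
                "mean_gene_accuracy": (sum(f.lncRNA_accuracy.values())
                                       / max(len(f.lncRNA_accuracy), 1)),
            } for f in res.folds]).to_csv(out("cv_folds.tsv"), sep="\t", index=False)
            with open(out("cv_summary.json"), "w", encoding="utf-8") as fh:
                json.dump({"mean_lncRNA_accuracy": res.mean_lncRNA_accuracy,
                           "mean_sample_accuracy": res.mean_sample_accuracy},
                          fh, indent=2)
        run_stage("evaluate", _evaluate)
        record("evaluate", "complete")
    else:
        record("evaluate", "skipped", "missing paired data")

    # --- alterations ------------------------------------------------------
    alterations = {}
    for key in _ALTERATION_KEYS:
        path = config.alterations.get(key)
        if path:
            alterations[key] = rio.read_alteration_tsv(path, key)

    # --- omics consistency ------------------------------------------------
    cnv_meth = [alterations[k] for k in ("amplification", "deletion",
                                         "hypermethylation", "hypomethylation")
                if k in alterations]
    if profile is not None and cnv_meth:
        def _consistency():
            records = consistency_ratio(profile, cnv_meth,
                                        top_k=config.consistency_top_k)
            pd.DataFrame([r.__dict__ for r in records]).to_csv(
                out("consistency.tsv"), sep="\t", index=False, na_rep="NA")
            census = consistency_census(records)
            with open(out("consistency_census.json"), "w", encoding="utf-8") as fh:
                json.dump(census, fh, indent=2)
        run_stage("consistency", _consistency)
        record("consistency", "complete")
    else:
        record("consistency", "skipped", "missing profile or CNV/methylation input")

    # --- subtype analysis -------------------------------------------------
    annotations = (rio.read_annotations_tsv(config.annotations)
                   if config.annotations else [])
    subtype_labels = {a.sample_id: a.subtype for a in annotations
                      if a.subtype is not None}
    specific: dict[str, set[str]] = {}
    if profile is not None and subtype_labels:
        def _subtypes():
            sets, detail = over_represented(
                profile, subtype_labels, alpha=config.subtype_alpha,
                min_freq=config.subtype_min_freq)
            detail.to_csv(out("over_represented.tsv"), sep="\t", index=False)
            specific_sets = subtype_specific(sets)
            rows = [{"subtype": s, "gene_id": g}
                    for s in sorted(specific_sets)
                    for g in sorted(specific_sets[s])]
            pd.DataFrame(rows, columns=["subtype", "gene_id"]).to_csv(
                out("subtype_specific.tsv"), sep="\t", index=False)
            return specific_sets
        specific = run_stage("subtypes", _subtypes)
        record("subtypes", "complete")
    else:
        record("subtypes", "skipped", "missing profile or subtype labels")

    # --- co-occurrence ----------------------------------------------------
    if profile is not None and specific and alterations:
        def _cooccur():
            frames = []
            for subtype, lnc_set in sorted(specific.items()):
                samples = [s for s in profile.sample_ids
                           if subtype_labels.get(s) == subtype]
                if not samples or not lnc_set:
                    continue
                for key, alt in sorted(alterations.items()):
                    edges = cooccurrence_network(
                        profile, alt, samples, sorted(lnc_set),
                        alt.gene_ids, p_cut=config.cooccurrence_p_cut,
                        subtype=subtype)
                    if edges:
                        frames.append(edges_to_frame(edges))
            df = (pd.concat(frames, ignore_index=True) if frames
                  else pd.DataFrame(columns=["lncRNA", "gene", "type", "subtype",
                                             "a", "b", "c", "d", "odds_ratio", "p"]))
            df.to_csv(out("cooccurrence_edges.tsv"), sep="\t", index=False)
        run_stage("cooccur", _cooccur)
        record("cooccur", "complete")
    else:
        record("cooccur", "skipped", "missing profile, subtype sets or alterations")

    # --- prognostic clustering --------------------------------------------
    survival = {a.sample_id: SurvivalRecord(a.sample_id, a.surv_time, a.surv_event)
                for a in annotations if a.surv_time is not None}
    if profile is not None and survival:
        def _cluster():
            prof = profile
            if config.focal_subtype is not None:
                keep = [s for s in prof.sample_ids
                        if subtype_labels.get(s) == config.focal_subtype]
                prof = prof.subset_samples(keep)
            genes, detail = prognostic_filter(prof, survival,
                                              alpha=config.prognostic_alpha)
            detail.to_csv(out("prognostic_genes.tsv"), sep="\t", index=False)
            if not genes:
                return "no prognostic genes at alpha"
            clustering = cluster_two_classes(prof.subset_genes(genes))
            pd.DataFrame({
                "sample_id": list(clustering.assignments),
                "class_label": list(clustering.assignments.values()),
            }).to_csv(out("class_assignments.tsv"), sep="\t", index=False)
            covariates: dict[str, dict[str, float]] = {}
            for a in annotations:
                for k, v in a.covariates.items():
                    covariates.setdefault(k, {})[a.sample_id] = v
            if covariates:
                comps = compare_classes_continuous(covariates,
                                                   clustering.assignments)
                pd.DataFrame([{"covariate": k, "statistic": c.test.statistic,
                               "p": c.test.p_value, "method": c.test.method}
                              for k, c in comps.items()]).to_csv(
                    out("class_covariates.tsv"), sep="\t", index=False)
            return f"{len(genes)} prognostic genes"
        note = run_stage("cluster", _cluster)
        record("cluster", "complete", note or "")
    else:
        record("cluster", "skipped", "missing profile or survival data")

    # --- drug associations ------------------------------------------------
    if profile is not None and config.responses:
        def _drugs():
            responses = rio.read_drug_response_tsv(config.responses)
            drug_list = config.drugs or sorted(responses["drug"].unique())
            rows = []
            for drug in drug_list:
                for assoc in clinical_response_association(profile, responses,
                                                           drug, alpha=config.alpha):
                    rows.append({
                        "lncRNA": assoc.lncRNA_id, "drug": assoc.drug,
                        "a": assoc.table.a, "b": assoc.table.b,
                        "c": assoc.table.c, "d": assoc.table.d,
                        "odds_ratio": assoc.odds_ratio, "p": assoc.p,
                        "direction": assoc.direction,
                    })
            pd.DataFrame(rows, columns=["lncRNA", "drug", "a", "b", "c", "d",
                                        "odds_ratio", "p", "direction"]).to_csv(
                out("drug_associations.tsv"), sep="\t", index=False)
        run_stage("drugs", _drugs)
        record("drugs", "complete")
    else:
        record("drugs", "skipped", "missing profile or response table")

    # --- manifest ---------------------------------------------------------
    for root, _, files in os.walk(config.out_dir):
        for name in sorted(files):
            if name == "manifest.json":
                continue
            path = os.path.join(root, name)
            rel = os.path.relpath(path, config.out_dir)
            manifest["outputs"][rel] = _sha256(path)
    _write_manifest(manifest, config.out_dir)
    return manifest


def _write_manifest(manifest: dict[str, Any], out_dir: str) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
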