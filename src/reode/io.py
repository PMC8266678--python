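"""TSV readers and writers for all pipeline artifacts.

Conventions: tab-separated UTF-8, first column row IDs, header row column
IDs, "NA" (or empty) as the missing sentinel.  Expression and alteration
matrices are genes x samples; an ``orientation`` flag transposes on read.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    AlterationMatrix,
    ExpressionMatrix,
    IDEProfile,
    SampleAnnotation,
    StablePairSet,
)

NA_VALUES = ["", "NA"]


def _read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=NA_VALUES,
                       keep_default_na=False, dtype=str)


def read_expression_tsv(path: str, orientation: str = "genes_by_samples") -> ExpressionMatrix:
    """Read an expression matrix; rejects duplicates, negatives, non-numbers."""
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError("orientation must be genes_by_samples or samples_by_genes")
    df = _read_table(path)
    if orientation == "samples_by_genes":
        df = df.T
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for g in df.index:
            for s in df.columns:
                try:
                    float(df.at[g, s])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {df.at[g, s]!r} at "
                        f"gene {g!r}, sample {s!r}") from None
        raise
    if np.isnan(values).any():
        g, s = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"{path}: missing value at gene {df.index[g]!r}, "
                         f"sample {df.columns[s]!r}")
    try:
        return ExpressionMatrix(list(df.index), list(df.columns), values)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_expression_tsv(matrix: ExpressionMatrix, path: str) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_alteration_tsv(path: str, alteration_type: str) -> AlterationMatrix:
    df = _read_table(path)
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"{path}: missing values not allowed in alteration matrices")
    return AlterationMatrix(alteration_type, list(df.index), list(df.columns),
                            values.astype(np.int8))


def write_alteration_tsv(matrix: AlterationMatrix, path: str) -> None:
    df = pd.DataFrame(matrix.flags, index=matrix.gene_ids, columns=matrix.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_stable_pairs_tsv(path: str, threshold_f: float,
                          n_normals: int = 0) -> StablePairSet:
    """Read a 3-column (high_gene, low_gene, support) pair table."""
    df = pd.read_csv(path, sep="\t", dtype={"high_gene": str, "low_gene": str})
    genes = sorted(set(df["high_gene"]) | set(df["low_gene"]))
    idx = {g: i for i, g in enumerate(genes)}
    return StablePairSet(
        gene_ids=genes,
        hi=np.array([idx[g] for g in df["high_gene"]], dtype=np.int64),
        lo=np.array([idx[g] for g in df["low_gene"]], dtype=np.int64),
        support=df["support"].to_numpy(dtype=float),
        threshold_f=threshold_f,
        n_normals=n_normals,
    )


def write_stable_pairs_tsv(pairs: StablePairSet, path: str) -> None:
    df = pd.DataFrame({
        "high_gene": [pairs.gene_ids[i] for i in pairs.hi],
        "low_gene": [pairs.gene_ids[i] for i in pairs.lo],
        "support": pairs.support,
    })
    df.to_csv(path, sep="\t", index=False)


def write_profile(profile: IDEProfile, out_dir: str) -> None:
    """Write calls.tsv / pvals.tsv / qvals.tsv into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    for name, m in (("calls", profile.calls), ("pvals", profile.p_values),
                    ("qvals", profile.q_values)):
        df = pd.DataFrame(m, index=profile.gene_ids, columns=profile.sample_ids)
        df.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t",
                  index_label="gene_id", na_rep="NA")


def read_profile(profile_dir: str) -> IDEProfile:
    frames = {}
    for name in ("calls", "pvals", "qvals"):
        frames[name] = pd.read_csv(
            os.path.join(profile_dir, f"{name}.tsv"), sep="\t", index_col=0,
            na_values=NA_VALUES, keep_default_na=False)
    calls = frames["calls"]
    return IDEProfile(
        gene_ids=list(calls.index),
        sample_ids=list(calls.columns),
        calls=calls.to_numpy(dtype=float).astype(np.int8),
        p_values=frames["pvals"].to_numpy(dtype=float),
        q_values=frames["qvals"].to_numpy(dtype=float),
    )


def read_annotations_tsv(path: str) -> list[SampleAnnotation]:
    """Read per-sample annotations.

    Recognized columns: sample_id, subtype, surv_time, surv_event; every
    other column is treated as a numeric covariate.  Drug-response tables
    are separate (see :func:`read_drug_response_tsv`).
    """
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    known = {"sample_id", "subtype", "surv_time", "surv_event"}
    cov_cols = [c for c in df.columns if c not in known]
    out = []
    for _, row in df.iterrows():
        time = row.get("surv_time")
        event = row.get("surv_event")
        covs = {c: float(row[c]) for c in cov_cols if pd.notna(row[c])}
        out.append(SampleAnnotation(
            sample_id=str(row["sample_id"]),
            subtype=None if pd.isna(row.get("subtype")) else str(row["subtype"]),
            surv_time=None if pd.isna(time) else float(time),
            surv_event=None if pd.isna(event) else int(event),
            covariates=covs,
        ))
    return out


def write_annotations_tsv(annotations: Sequence[SampleAnnotation], path: str) -> None:
    cov_names = sorted({k for a in annotations for k in a.covariates})
    rows = []
    for a in annotations:
        row = {
            "sample_id": a.sample_id,
            "subtype": a.subtype,
            "surv_time": a.surv_time,
            "surv_event": a.surv_event,
        }
        for c in cov_names:
            row[c] = a.covariates.get(c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_drug_response_tsv(path: str) -> pd.DataFrame:
    """Clinical drug response: columns sample_id, drug, response."""
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False,
                     dtype=str)
    required = {"sample_id", "drug", "response"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return df


def read_actarea_tsv(path: str) -> pd.DataFrame:
    """Cell-line drug sensitivity: columns cell_line, drug, act_area."""
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)
    required = {"cell_line", "drug", "act_area"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    df["act_area"] = df["act_area"].astype(float)
    if not np.isfinite(df["act_area"].dropna()).all():
        raise ValueError(f"{path}: non-finite act_area values")
    return df


def read_pairing_tsv(path: str) -> dict[str, str]:
    """Two-column (tumor_sample, normal_sample) mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]], df[cols[1]]))


def write_pairing_tsv(pairing: dict[str, str], path: str) -> None:
    pd.DataFrame({"tumor_sample": list(pairing.keys()),
                  "normal_sample": list(pairing.values())}
                 ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
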