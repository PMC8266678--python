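"""Core domain types shared by every pipeline stage.

All matrices are dense numpy arrays oriented genes x samples; identifiers
are kept as plain Python lists alongside the values.  Validation happens at
construction time so downstream stages can assume the invariants hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

ALTERATION_TYPES = (
    "mutation",
    "nonsilent_mutation",
    "amplification",
    "deletion",
    "hypermethylation",
    "hypomethylation",
)

#: alteration types that support an upregulation (+1) call
UP_SUPPORTING = frozenset({"amplification", "hypomethylation"})
#: alteration types that support a downregulation (-1) call
DOWN_SUPPORTING = frozenset({"deletion", "hypermethylation"})


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate {what} IDs: {dups}")
    return ids


@dataclass
class ExpressionMatrix:
    """Non-negative expression values (genes x samples), FPKM-like units."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.values.size and self.values.min() < 0:
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene ID {gene_id!r}") from None

    def sample_vector(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample ID {sample_id!r}") from None
        return self.values[:, j]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids),
                                self.values[:, idx].copy())


@dataclass
class PairedCohort:
    """Matched tumor/normal expression matrices over one gene universe."""

    normal: ExpressionMatrix
    tumor: ExpressionMatrix
    pairing: dict[str, str]  # tumor sample ID -> normal sample ID

    def __post_init__(self) -> None:
        if self.normal.gene_ids != self.tumor.gene_ids:
            raise ValueError("normal and tumor matrices must share gene_ids")
        normals = set(self.normal.sample_ids)
        tumors = set(self.tumor.sample_ids)
        for t, n in self.pairing.items():
            if t not in tumors:
                raise ValueError(f"pairing references unknown tumor sample {t!r}")
            if n not in normals:
                raise ValueError(f"pairing references unknown normal sample {n!r}")
        if len(set(self.pairing.values())) != len(self.pairing):
            raise ValueError("pairing must map tumors one-to-one onto normals")

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)


@dataclass
class StablePairSet:
    """Ordered gene pairs (high, low) stable in >= threshold_f of normals.

    ``hi`` / ``lo`` are integer indices into ``gene_ids``; ``support`` is the
    per-pair fraction of reference samples with expr[hi] > expr[lo].
    """

    gene_ids: list[str]
    hi: np.ndarray
    lo: np.ndarray
    support: np.ndarray
    threshold_f: float
    n_normals: int

    def __post_init__(self) -> None:
        self.hi = np.asarray(self.hi, dtype=np.int64)
        self.lo = np.asarray(self.lo, dtype=np.int64)
        self.support = np.asarray(self.support, dtype=float)
        if not (0.5 < self.threshold_f <= 1.0):
            raise ValueError("threshold_f must be in (0.5, 1]")
        if not (len(self.hi) == len(self.lo) == len(self.support)):
            raise ValueError("hi/lo/support length mismatch")
        if len(self.hi) and np.any(self.hi == self.lo):
            raise ValueError("self-pair encountered")
        if len(self.support) and (self.support.min() < self.threshold_f - 1e-12):
            raise ValueError("pair support below threshold_f")
        key = {frozenset(p) for p in zip(self.hi.tolist(), self.lo.tolist())}
        if len(key) != len(self.hi):
            raise ValueError("an unordered pair appears more than once")

    def __len__(self) -> int:
        return len(self.hi)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(self.gene_ids[h], self.gene_ids[l])
                for h, l in zip(self.hi.tolist(), self.lo.tolist())]


@dataclass
class IDEProfile:
    """Per-sample ternary differential-expression calls with p/q matrices.

    ``calls`` entries are -1 (down), 0 (unaltered) or +1 (up).  p and q are
    NaN for genes that had too few stable partners in a sample.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    calls: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.q_values = np.asarray(self.q_values, dtype=float)
        shape = (len(self.gene_ids), len(self.sample_ids))
        for name, m in (("calls", self.calls), ("p_values", self.p_values),
                        ("q_values", self.q_values)):
            if m.shape != shape:
                raise ValueError(f"{name} shape {m.shape} != {shape}")
        if self.calls.size and not np.isin(self.calls, (-1, 0, 1)).all():
            raise ValueError("calls must be in {-1, 0, +1}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "IDEProfile":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return IDEProfile(list(self.gene_ids), list(sample_ids),
                          self.calls[:, idx].copy(),
                          self.p_values[:, idx].copy(),
                          self.q_values[:, idx].copy())

    def subset_genes(self, gene_ids: Sequence[str]) -> "IDEProfile":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return IDEProfile(list(gene_ids), list(self.sample_ids),
                          self.calls[idx].copy(), self.p_values[idx].copy(),
                          self.q_values[idx].copy())


@dataclass
class AlterationMatrix:
    """Binary genes x samples indicator for one alteration type."""

    alteration_type: str
    gene_ids: list[str]
    sample_ids: list[str]
    flags: np.ndarray

    def __post_init__(self) -> None:
        if self.alteration_type not in ALTERATION_TYPES:
            raise ValueError(
                f"alteration_type {self.alteration_type!r} not in {ALTERATION_TYPES}")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.flags = np.asarray(self.flags)
        if self.flags.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("flags shape does not match ID lists")
        if self.flags.size and not np.isin(self.flags, (0, 1)).all():
            raise ValueError("flags must be binary")
        self.flags = self.flags.astype(np.int8)


@dataclass
class SampleAnnotation:
    """Per-sample clinical annotation; missing fields are None."""

    sample_id: str
    subtype: str | None = None
    surv_time: float | None = None
    surv_event: int | None = None
    covariates: dict[str, float] = field(default_factory=dict)
    drug_response: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.surv_time is None) != (self.surv_event is None):
            raise ValueError(
                f"sample {self.sample_id!r}: surv_time and surv_event must be "
                "present or missing together")
        if self.surv_time is not None:
            if not np.isfinite(self.surv_time) or self.surv_time < 0:
                raise ValueError(f"sample {self.sample_id!r}: bad surv_time")
            if self.surv_event not in (0, 1):
                raise ValueError(f"sample {self.sample_id!r}: surv_event must be 0/1")
        for k, v in self.covariates.items():
            if v is not None and not np.isfinite(v):
                raise ValueError(f"sample {self.sample_id!r}: covariate {k!r} not finite")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] with non-negative integer entries."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def annotations_to_mapping(
    annotations: Sequence[SampleAnnotation],
) -> Mapping[str, SampleAnnotation]:
    out = {}
    for ann in annotations:
        if ann.sample_id in out:
            raise ValueError(f"duplicate annotation for sample {ann.sample_id!r}")
        out[ann.sample_id] = ann
    return out
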