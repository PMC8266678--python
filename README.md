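# reode

Individualized differential-expression analysis of (lnc)RNA expression
profiles from within-sample **r**elative **e**xpression **o**rderings, plus
the downstream analyses that consume the resulting ternary call profiles.

The core idea: gene pairs whose expression ordering is stable across a
normal reference cohort form a reference criterion. For a single tumor
sample, each gene's ordering reversals against its stable partners are
scored with a Fisher exact test (BH-adjusted within the sample), producing
a per-gene call of `+1` (up), `-1` (down), or `0` (unaltered) — no matched
normal required. Because only orderings are used, the calls are robust to
scaling, normalization and batch effects.

## Components

| Module | Purpose |
| --- | --- |
| `reode.model` | Validated domain types (expression matrices, pair sets, call profiles, alteration matrices, annotations) |
| `reode.io` | TSV readers/writers (`NA` missing sentinel), GMT parsing |
| `reode.stats` | Exact-statistics kernel: Fisher 2x2 (minimum-likelihood two-sided rule), BH adjustment, rank-sum, Welch's t, hypergeometric tail |
| `reode.pairs` | Stable-pair mining from a normal cohort; per-sample ordering counts |
| `reode.individualize` | Per-sample ternary calling with optional partner-exclusion refinement; cohort profile assembly; call-frequency summaries |
| `reode.validation` | Seeded k-fold paired cross-validation of calls against tumor-normal deltas; fold-change comparison of called vs never-called genes |
| `reode.consistency` | Agreement of call directions with CNV / promoter-methylation flags |
| `reode.subtypes` | Subtype over-representation, exclusive subtype-specific sets, UpSet-style intersections, call-by-alteration co-occurrence networks, hypergeometric ORA |
| `reode.prognosis` | Log-rank test, prognostic gene selection, two-class hierarchical clustering of ternary profiles, between-class statistics, TMB counts |
| `reode.drugs` | Call status vs clinical drug response (Fisher) and cell-line ActArea (Welch) |
| `reode.simulate` | Seeded ground-truth dataset generator coupling expression, subtypes, survival, alterations and drug response |
| `reode.pipeline` / `reode.cli` | End-to-end orchestration with a byte-stable manifest; `reode` console entry point |

## Quick start (synthetic data)

```sh
reode simulate --seed 1 --out data/
reode stable-pairs --normals data/normals.tsv --f 0.99 --out data/pairs.tsv
reode individualize --tumors data/tumors.tsv --pairs data/pairs.tsv \
    --alpha 0.05 --out data/profile/
reode evaluate --paired-normals data/normals.tsv --paired-tumors data/tumors.tsv \
    --pairing data/pairing.tsv --k 5 --seed 17 --out data/cv.json
```

Or run everything from one YAML config:

```sh
reode run-all --config pipeline.yaml
```

where `pipeline.yaml` lists input paths (`normals`, `tumors`, `pairing`,
`annotations`, `responses`, `alterations: {mutation: ..., ...}`), an
`out_dir`, and optional parameters (`threshold_f`, `alpha`, `min_pairs`,
`subtype_alpha`, `cooccurrence_p_cut`, `focal_subtype`, `k_folds`, `seed`).
Stages whose inputs are absent are skipped and noted in
`out_dir/manifest.json`, which also records sha256 hashes of every output.

## Python API

```python
from reode import (SimulationConfig, generate_dataset, find_stable_pairs,
                   build_profile, truth_metrics)

ds = generate_dataset(SimulationConfig(seed=1))
pairs = find_stable_pairs(ds.normals, threshold_f=0.99)
profile = build_profile(ds.tumors, pairs)       # genes x samples in {-1,0,+1}
print(truth_metrics(profile, ds.truth))          # precision / recall / sign acc
```

## Conventions

- All matrices are dense, genes x samples, TSV with a header row of sample
  IDs and first-column row IDs; `NA` (or empty) marks missing values.
- Ties in expression orderings count against pair stability and against
  concordance when evaluating a sample (conservative, deterministic).
- The two-sided Fisher rule is minimum-likelihood summation, matching
  mainstream statistical software.
- FDR control for calling is Benjamini-Hochberg within each sample.
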