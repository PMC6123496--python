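# sctnbc

A tested, reusable re-implementation of a single-cell triple-negative breast
cancer (TNBC) heterogeneity analysis pipeline: quality control and
normalization, two-step marker/cluster cell typing, cycling classification,
expression-inferred copy-number profiling with subclone calls, patient-
regressed density-peak clustering of epithelial cells, gene-signature scoring
and derivation, and survival validation (Kaplan–Meier, log-rank, univariate
Cox). A synthetic-tumor generator with full ground truth drives every
recovery and calibration test, so the whole pipeline runs end to end on one
CPU without external data.

## Layout

| module | contents |
| --- | --- |
| `sctnbc.types` | core data types (`ExpressionMatrix`, `GeneSignature`, record schemas, MAD) |
| `sctnbc.core_io` | TSV / MatrixMarket expression IO, GMT, BED-like genes & segments, survival cohorts |
| `sctnbc.synthetic` | synthetic tumors (marker sets, cycling, CNV blocks, batch effects, dropout), normal reference, survival cohorts |
| `sctnbc.qc` | per-cell QC metrics, 4-MAD cell filter, per-patient prevalence gene filter, mode-anchored relative counts, size factors (median-ratio / pooled deconvolution), RUV-style correction |
| `sctnbc.celltype` | gene-set scoring, two-step cell typing, cycling calls (median + 2·MAD) |
| `sctnbc.cnv` | reference normalization on the log2(TPM+1)/10 scale, 100-gene sliding-window CNV inference, burden/carrier/subclone calls, Spearman correlation maps |
| `sctnbc.clustering` | patient-effect regression, PCA + t-SNE embedding, density-peak clustering with automatic center selection |
| `sctnbc.signatures` | directional signature scores, per-cell subtype assignment, cluster-signature derivation (rank-sum + BH), hypergeometric over-representation, segment→gene mapping |
| `sctnbc.survival` | bulk scoring, quartile stratification, product-limit KM, K-group log-rank, Newton/Breslow Cox |
| `sctnbc.pipeline` / `sctnbc.cli` | staged orchestration + `scTNBC` console entry point |

## CLI

Every stage reads a YAML config and writes TSV/JSON outputs into a run
directory:

```sh
scTNBC all --config cfg.yaml --out runs/demo        # simulate → … → survive
scTNBC simulate --config cfg.yaml --out runs/demo   # single stage
```

Minimal synthetic config:

```yaml
seed: 7
simulate:
  n_patients: 3
  cells_per_patient: 60
  n_genes: 800
  n_epithelial_programs: 2
  cnv_specs:
    - {patient: P1, carrier_fraction: 0.5, block_start: 100, block_end: 250, dosage: 1.5}
params:
  window: 51
```

Real data enters through an `inputs:` section instead of `simulate:`
(expression TSV/MatrixMarket, per-cell table, gene positions, GMT marker and
signature files, WES segments, survival cohort TSV); analysis parameters
default to the standard values (MAD k = 4 and 2, prevalence 0.95,
expression threshold 0.1, window 100, clip 3).

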