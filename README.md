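# sigconn

Connectivity and master-regulator analysis for perturbational expression
signatures, from raw inputs to validation statistics:

- **dose_response** — four-parameter Hill fits of growth-inhibition curves
  and closed-form GI20 extraction (the concentration at which response
  crosses 80% of untreated growth).
- **diff_expr** — negative-binomial Wald differential expression on count
  matrices (median-of-ratios size factors, method-of-moments dispersion,
  BH-FDR), producing disjoint up/down gene signatures.
- **connectivity** — the full scoring chain against a reference signature
  compendium: signed KS-like enrichment score (ES), weighted connectivity
  score (WCS), cell-line/perturbagen-type normalized score (NCS), signed
  quantile τ on a ±100 scale, and max-quantile aggregation over perturbagen
  classes (PCLs).
- **master_regulator** — Welch-t Z-score signatures, permutation nulls,
  weighted regulon enrichment (NES + empirical p + FDR), TF→disease mapping
  with a ≥2-regulator evidence filter, and ICD-9 chapter rollup.
- **validation** — within-PCL vs null τ comparisons (effect sizes +
  t-tests) and expected-PCL rank-percentile analysis by cell line or drug.
- **simulate** — seeded generators for every input (NB counts with planted
  fold changes, reference compendia with planted classes, regulons with a
  planted dysregulated TF, Hill dose-response curves), so the whole
  pipeline is testable offline.
- **io / workflow / cli** — TSV/GMT/JSON/YAML readers and writers, and an
  orchestrated end-to-end run with a reproducibility manifest.

## Test

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the headline property checks (ES oracle
equivalence, planted-class and planted-regulon recovery, DE calibration,
Hill/GI20 identities, validation statistics, byte-level determinism).

## CLI

All stages are subcommands of `sigconn` (or `python -m sigconn.cli`):

```sh
# generate a complete synthetic input set
sigconn simulate --spec spec.yaml --out-dir data/        # spec.yaml: {seed: 3, ...}

# Hill fits + GI20 per venom
sigconn gi20 --doses data/dose_response.tsv --out gi20.tsv

# differential-expression signature for one perturbagen vs controls
sigconn signature --counts data/counts.tsv --meta data/sample_meta.tsv \
    --venom venom1 --out sig.tsv

# connectivity scoring (ES -> WCS -> NCS -> tau -> PCL)
sigconn connect --signatures sig.json --reference data/reference_matrix.tsv \
    --reference-meta data/reference_meta.tsv --pcl-gmt data/pcls.gmt --out-dir conn/

# regulon enrichment + disease associations
sigconn mra --counts data/counts.tsv --meta data/sample_meta.tsv --venom venom1 \
    --regulons data/regulons.tsv --tf-disease data/tf_disease.tsv --out-dir mra/

# validation statistics from a tau matrix
sigconn validate --tau conn/tau_matrix.tsv --reference data/reference_matrix.tsv \
    --reference-meta data/reference_meta.tsv --pcl-gmt data/pcls.gmt \
    --annotations annotations.tsv --out-dir val/

# or everything at once from a YAML config
sigconn run --config config.yaml
```

Exit codes: 0 ok, 2 configuration error, 3 data error.

## File formats

Tab-separated UTF-8 throughout (`#` starts a comment line): gene × sample
count TSVs with a sample-metadata TSV; gene × reference score matrices with
reference metadata; PCL membership as standard GMT; regulons as 4-column
TSV (tf, target, mode ∈ {+,−}, weight ∈ (0,1]); TF-disease maps as TSV with
`|`-separated ICD-9 codes; signatures as a statistics TSV plus a compact
JSON with the up/down lists.
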