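# prsport

Analysis toolkit for studying how well polygenic risk scores (PRS) transfer
across populations, exercised end to end on synthetic cohorts:

- **synthetic_data** — two-population cohorts with Balding–Nichols allele
  frequency drift, Hardy–Weinberg genotypes, liability-threshold
  case/control status, tumor-stage and Gleason labels for cases, missing
  genotypes, proxy variants tagging causal variants at a target r², and
  haplotype panels with an optional planted sweep. Includes a quadrature
  oracle for the expected AUC of a score under the liability model, used to
  engineer cohorts with a chosen discrimination level.
- **io_formats** — readers/writers for tab-separated scoring files
  (per-ancestry odds-ratio weights), proxy maps (including multi-marker
  expansion entries), VCF 4.2 genotypes (via cyvcf2; effect-allele
  orientation with strand-unambiguous flips), iHS tables (MAF > 0.05
  availability rule), sample metadata and plain-text haplotype matrices.
  Gzip is handled transparently.
- **prs_engine** — resolution of score variants against a genotyped marker
  set through a proxy map (r² ≥ 0.4 by default; below-threshold variants
  dropped; two-marker expansion supported), weight adjustment
  β = ln(OR) · r², per-site mean imputation of missing doses, PRS summation
  and z-standardization.
- **divergence_stats** — folded-MAF ("bow-tie") informativeness
  classification of the joint site frequency spectrum, exact two-sided
  binomial test of the region counts, Mann–Whitney comparisons of PRS
  distributions, per-population medians.
- **selection_scan** — EHH and unstandardized iHS on haplotype panels
  (trapezoid integration, configurable truncation), frequency-bin
  standardization, percentile placement against a genome-wide reference,
  and a one-sample KS uniformity test.
- **structure_qc** — sample missingness filter (> 5% excluded), genotype
  PCA with allele-frequency scaling, 2-SD PC1/PC2 outlier filter, classical
  (Torgerson) MDS on 1 − IBS distances, and seeded case:control
  ratio-matched downsampling.
- **evaluation** — ROC/AUC with DeLong variance and 95% CIs, paired and
  unpaired DeLong tests, top-decile vs middle-20% covariate-adjusted odds
  ratios (age median-filled, PCs as covariates), aggressiveness
  classification (stage = T4, or Gleason ≥ 8), and report assembly.
- **pipeline / cli** — a seeded, configured end-to-end run
  (simulate → QC → structure → score → divergence/selection → evaluate)
  producing TSV/JSON tables plus a provenance manifest.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (marker-resolution
counts, AUC identities, standardization contract, two-population parameter
recovery, statistical calibration, and oracle-equivalence checks).

## CLI

```sh
prs simulate --seed 0 --n-samples 500 --out-dir sim/
prs score --vcf sim/cohort.vcf --score-file sim/score.tsv \
    --meta sim/metadata.tsv --ancestry popA --out scores.tsv
prs structure --vcf sim/cohort.vcf --k 10 --out-pcs pcs.tsv --out-mds mds.tsv
prs evaluate --scores scores.tsv --meta sim/metadata.tsv --pcs pcs.tsv \
    --out report.tsv
prs bowtie --freqs freqs.tsv --out bowtie.json
prs ihs --haplotypes panel.tsv --core-index 50 --out ihs.tsv
prs ks-uniform --percentiles percentiles.tsv
prs run --config run.yaml --seed 1 --out-dir run/
```

`prs run` accepts a YAML config (population specs, architecture,
thresholds, classifier list); identical configs and seeds give
byte-identical outputs.

## File formats

Scoring file (tab-separated, `#` headers declare the weight scale):

```
# score_name=demo
# weight_scale=OR
variant_id  chrom  pos  effect_allele  other_allele  weight_EUR  weight_AFR
```

Proxy map: `source_id  proxy_id  r2  same_direction  rule  log_or`, where
`rule` is `proxy` (ordinary substitution) or `expand` (multi-marker
inference rows, each carrying its own log-odds weight).

iHS table: `variant_id  freq  ihs`; rows failing the strict MAF > 0.05 rule
are flagged `excluded`.

Metadata: `sample  site  status  age  stage  gleason  population`.
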