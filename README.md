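# cnakit

Downstream analysis of segmented somatic copy-number profiles: from SEG-style
segment tables to tiered aberration regions, a binary sample×region
aberration matrix, pairwise co-occurrence/mutual-exclusivity statistics with
parametric and permutation nulls, copy-number/expression linkage, and
genomic-instability indices with survival association. A synthetic-cohort
generator provides tumour/normal data with planted structure so the whole
pipeline is testable offline.

## Modules

| module | role |
|---|---|
| `cnakit.genome_io` | coordinate model (0-based half-open) and SEG/BED/TSV readers & writers |
| `cnakit.simulate` | synthetic cohorts (latent-factor co-occurrence, CNPs, expression, survival) |
| `cnakit.preprocess` | CNP derivation from normals + masking, small-segment merging, threshold calling |
| `cnakit.regions` | breakpoint-union frequency tracks, tiered region calling, aberration matrix, pair filters |
| `cnakit.assoc` | signed-√χ² score test, BH correction, column-permutation test with average-exceedance FDR, replication filter |
| `cnakit.exprlink` | gene-level copy number and the four-test CN/expression screen |
| `cnakit.outcome` | instability indices, quartile binning, Cox survival association |
| `cnakit.cli` | subcommand-per-stage pipeline over files |

Default thresholds follow the analysis this re-implements: gain/loss calls
past ±0.3 (log2, strict), high-gain tiers at 0.6 / 0.8 / 1.0, homozygous
deletion below −1, CNP exclusion at >5% of normals, tier frequency bars of
30% / 10% / 5% / 2.5%, HD in ≥4 samples, and 5% FDR for associations.

## CLI

Each stage reads the previous stage's artifacts from `--out-dir`:

```sh
cnakit simulate   --seed 7 --n-tumours 200 --n-normals 50 --out-dir run
cnakit preprocess --out-dir run                 # cnp.bed, tumours_clean.seg
cnakit regions    --out-dir run                 # regions.bed, track_*.bedgraph
cnakit matrix     --out-dir run                 # matrix.tsv
cnakit assoc      --cnp-file run/cnp.bed --out-dir run     # assoc.tsv
cnakit perm       -B 1000 --seed 1 --cnp-file run/cnp.bed --out-dir run
cnakit replicate  --validation other_run/assoc.tsv --out-dir run
cnakit explink    --expression expr.tsv --genes genes.bed --out-dir run
cnakit instability --out-dir run
cnakit survival   --annotations annots.tsv --out-dir run
cnakit report     --out-dir run
```

`cnakit simulate --config cohort.yaml` accepts a YAML cohort description
(genome, planted regions with base frequencies / amplitude mixes / latent
factor loadings, CNPs, noise, probe density). Without a config a built-in
example cohort is used. Every output file carries a header comment with the
config hash and seed.

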