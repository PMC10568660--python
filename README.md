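# popvar

Population-genetic analysis of variants called from RNA-seq alignments.
Starting from a multi-sample VCF (any ploidy, including pooled samples
treated as ploidy = 2 × pool size), per-position pileup base counts, a GFF3
annotation, a tab-separated sample sheet and small marker TSVs, the package
computes:

- **Variant filters** — SNP-only, inclusive QUAL threshold, per-site
  missingness cap, with a per-filter removal report (`popvar.core_io`).
- **Selection scans** — per-site Hudson F_ST components, windowed and
  per-gene ratio-of-averages estimates with top-percentile gene flagging,
  and the population branch statistic with clipped branch lengths
  (`popvar.popgen`).
- **Diversity** — windowed nucleotide diversity (π) and Watterson's θ, with
  seeded percentile-bootstrap genome-wide CIs, optional down-sampling for
  sample-size standardization, and an observed/expected-heterozygosity
  inbreeding coefficient (`popvar.popgen`).
- **Structure** — LD pruning of unphased alt-allele dosages (sliding
  SNP windows, iterated to a fixed point) and deterministic sample PCA
  (`popvar.structure`).
- **Expressed allele balance** — allele frequencies of variants of interest
  measured directly in read pileups, per replicate and group-averaged, with
  NOT_DETECTED / NO_COVERAGE states (`popvar.allele_balance`).
- **Inversion karyotyping** — pooled-sample inversion frequencies from
  tag-SNP read fractions, with exact Mann–Whitney group comparisons and BH
  adjustment (`popvar.karyotype`).
- **Ancestry** — ancestry-informative-marker fractions per chromosome,
  sample and group, from genotype calls or pileups (`popvar.ancestry`).
- **Annotation & enrichment** — exon/intron/intergenic SNP classification
  against merged GFF3 features, effect-annotation tallies, per-gene
  missense reports, hypergeometric term enrichment, sweep-interval overlap,
  gene-family expression summaries and shared-direction gene sets
  (`popvar.annotation_enrichment`).
- **Synthetic data** — a seeded generator (Balding–Nichols populations,
  binomial pooled pileups, marker panels, toy GFF3) with ground-truth
  tables for every estimator (`popvar.simulate`).

## CLI

A single executable with one subcommand per analysis:

```sh
# emit a complete synthetic data set with ground truth
popvar simulate --outdir sim --seed 1 --f-target 0.25 --n-sites 2000

# filter and scan
popvar filter    --config sim/config.yaml --samples sim/samples.tsv --vcf sim/variants.vcf --outdir out
popvar fst       --config sim/config.yaml --samples sim/samples.tsv --vcf sim/variants.vcf --outdir out
popvar diversity --config sim/config.yaml --samples sim/samples.tsv --vcf sim/variants.vcf --outdir out
popvar pca       --config sim/config.yaml --samples sim/samples.tsv --vcf sim/variants.vcf --outdir out
popvar features  --config sim/config.yaml --samples sim/samples.tsv --vcf sim/variants.vcf \
                 --gff3 sim/annotation.gff3 --outdir out
popvar karyotype --config sim/config.yaml --samples sim/samples.tsv \
                 --pileup counts.tsv --tags sim/tag_snps.tsv --outdir out
popvar allele-balance --config sim/config.yaml --samples sim/samples.tsv \
                 --pileup counts.tsv --voi sim/variants_of_interest.tsv --outdir out
popvar aims      --config sim/config.yaml --samples sim/samples.tsv --vcf sim/variants.vcf \
                 --aims sim/aims.tsv --outdir out
```

Further subcommands: `pbs`, `genescan`, `enrich`. Every run writes TSV
outputs plus a `manifest.json` registering input checksums and outputs;
reruns with identical inputs are byte-identical (plots excluded). Plots are
secondary artifacts — each has a TSV twin.

Configuration is YAML (`ploidy`, `qual_min`, `max_missing_fraction`,
`window_size_bp`, `contrasts`, `pbs_triples`, LD-pruning parameters,
`fst_top_percentile`, `random_seed`); the sample sheet is a TSV with
`sampleID` and `treatment` columns.

## Conventions

- Coordinates are 1-based inclusive (VCF/GFF3 convention); sweep-interval
  overlap uses half-open semantics.
- Contig names are taken verbatim; a mismatch between VCF and GFF3 names is
  an error, never a silent empty join.
- Multiallelic SNPs are kept for diversity but reduced to ref vs
  most-frequent-alt for F_ST/PBS/LD/PCA (logged).
- Window aggregation is ratio-of-averages; negative per-site components are
  retained. Window length is the full window span (RNA-seq coverage gaps
  are not corrected for).
- Wherever an adjusted p-value is emitted, the adjustment is
  Benjamini–Hochberg.
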