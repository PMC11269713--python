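# hapsel

A selection-scan pipeline for phased SNP panels, built around the analysis
used to find positively selected variants in a high-altitude-adapted
population against lowland references:

1. **QC** — GATK-style hard filtering of INFO annotations, sample
   missingness/heterozygosity filters, iterative PCA admixture-outlier
   flagging, and locus-level missingness / Hardy–Weinberg / MAF filters.
2. **Selection statistics** — per-SNP FST (Hudson or Weir–Cockerham), iHS,
   XPEHH, dIHH and nSL from phased haplotypes, with derived-allele-frequency
   bin standardization.
3. **Composite score** — the five statistics combined per SNP via
   log-likelihood ratios of calibrated selected/neutral score densities;
   genome-wide significance by top-quantile threshold.
4. **LD clumping** — greedy clumping of significant SNPs into candidate
   regions (index/SP2 quantiles, r² ≥ 0.2, 500 kb radius, > 5 SP2 members),
   peak-SNP gene calls, interval-class SNP annotation, and target-enriched
   allele calls.
5. **Phenotypes** — blood-index outlier filtering (mean ± 3 SD), Welch
   t-tests with BH correction, pairwise correlations, and an
   altitude-response blunting test (population × altitude interaction).
6. **Association** — covariate-adjusted additive model per SNP with
   Freedman–Lane max-|t| permutation adjustment and per-SNP variance
   explained.
7. **Enrichment** — organ/system assignment of candidate genes by eQTL
   interval overlap and one-sided Fisher exact enrichment.
8. **Simulator** — a forward Wright–Fisher generator (three populations,
   optional hard sweep, recombination, infinite-sites mutation) that emits
   complete synthetic studies (phased VCFs, manifest, blood phenotypes with
   a blunted altitude response in the target, gene/regulatory annotations,
   organ eQTL map) with full ground truth, deterministic per seed.

## CLI

All stages are exposed as subcommands of `hapsel` (thresholds overridable by
flags or a YAML `--config`):

```bash
hapsel simulate --seed 1 --out-dir study/            # synthetic study
hapsel qc       --vcf in.vcf --out-prefix out        # hard filter + QC
hapsel scores   --vcf study/all.vcf --manifest study/manifest.tsv \
                --target TBP --ref DUROC --ref2 YKX --out scores.tsv
hapsel cms      --scores scores.tsv --calib calib.json --q 0.001 --out cms.tsv
hapsel clump    --cms cms.tsv --vcf study/all.vcf --manifest study/manifest.tsv \
                --annotation study/genes.bed --out regions.tsv,genes.tsv
hapsel pheno    --pheno study/phenotypes.tsv --groups TBP,YKX --out pheno.tsv
hapsel gwas     --vcf study/all.vcf --pheno study/phenotypes.tsv \
                --perms 100000 --seed 1 --out assoc.tsv
hapsel enrich   --genes genes.tsv --annotation study/genes.bed \
                --eqtl study/organs.bed --out enrich.tsv
```

File dialects: VCF 4.x (biallelic SNVs, ancestral allele in the `AA` INFO
key), manifest TSV (`sample population altitude sex age`), gene annotation
BED6-like (`chrom start end gene class strand`, classes CDS/UTR5/UTR3/
regulatory/intron/intergenic, 0-based half-open), organ eQTL map BED4
(`chrom start end organ`).

## Notes

- Composite-score calibration normally comes from the bundled simulator
  (`hapsel.pipeline.simulate_calibration`); without simulations,
  `hapsel cms` falls back to an empirical-tail approximation, which is
  clearly weaker and logged as such.
- Distances for iHH integration are physical (bp); EHH walks stop at a
  0.05 cutoff, 200 kb gaps and chromosome ends. All conventions are
  configurable and recorded in output metadata sidecars.
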