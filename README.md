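# meqtlkit

Integrative analysis of genotype and DNA-methylation data:

* **Screen design** — count candidate cis SNP–CpG regression tests, compute
  additive-model power at a Bonferroni alpha, and pick the most permissive
  query parameters hierarchically (methylation-sd cutoff, then MAF floor,
  then window size).
* **cis-meQTL discovery** — OLS of beta values (0–100) on dosage plus two
  ancestry PCs and sex, with an FDR threshold calibrated by genotype-label
  permutation (one shared sample shuffle per permutation, preserving LD);
  FDR(p) = mean null distinct-CpG count / observed distinct-CpG count.
* **GWAS enrichment** — LD-proxy expansion, GWAS-p-supervised LD pruning,
  stratification by MAF bin × CpG-opportunity bin, 1000 matched null SNP
  sets, enrichment fold and permutation p.
* **GO pathways** — meQTL-target CpGs of disease SNPs mapped to nearest
  genes, Wallenius noncentral hypergeometric test correcting probes-per-gene
  bias, redundancy filtering at >70% gene-list overlap, cross-tissue scaled
  ranking.
* **Regulatory overlap** — seven target-list categories (per-tissue plus
  harmonized down-sampled intersections), two Fisher 2×2 contrasts per
  feature, family-wise Bonferroni threshold `alpha / (n_features × n_lists)`.
* **Synthetic data** — Gaussian-copula LD-blocked genotypes, beta-valued
  methylation with planted additive effects, GWAS p-values with a planted
  enrichment factor, feature tracks with a planted odds ratio, and gene/GO
  annotations with non-uniform probe counts, so every stage is testable
  offline.

## CLI

```bash
meqtlkit simulate --name planted_meqtl --out-dir data/ --seed 1
meqtlkit discover --config analysis.cfg --out-dir out/     # meqtls.tsv
meqtlkit fdr      --config analysis.cfg --out-dir out/     # calibration.tsv, thresholds.tsv
meqtlkit enrich   --config analysis.cfg --meqtls out/meqtls.tsv --out-dir out/
meqtlkit go       --config analysis.cfg --meqtls out/meqtls.tsv \
                  --disease-snps dz.tsv --out-dir out/
meqtlkit overlap  --config analysis.cfg --meqtls pb=out/meqtls.tsv --out-dir out/
meqtlkit expand   --config analysis.cfg --meqtls out/meqtls.tsv \
                  --disease-snps dz.tsv --out-dir out/
```

The config is a flat `key = value` file mirroring
`meqtlkit.io.AnalysisConfig`; `simulate` scenarios are `null`,
`planted_meqtl`, `planted_enrichment`, `planted_feature`, `planted_go`.
Exit codes: 0 success, 1 stage failure, 2 usage error.  Fixed seeds give
byte-identical outputs.

## Formats

* genotypes: VCF (GT hard calls) or TSV `snp_id  chrom  pos  <samples...>`
  with dosages in {0,1,2};
* methylation: TSV `cpg_id  chrom  pos  <samples...>`, beta values 0–100
  (0–1 inputs are rescaled with a warning);
* GWAS: TSV `snp_id  chrom  pos  p  maf`;
* features: BED3+ (0-based half-open); SNPs/CpGs are 1-based points,
  conversion is centralized in `meqtlkit.types`;
* meQTL lists: TSV `snp_id  cpg_id  p`.

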