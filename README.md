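# sdscreen

Whole-genome screen for sex-determining (SD) regions from resequenced
males and females. Given biallelic SNP genotypes (VCF) and a sample→sex
map, the pipeline computes per-SNP between-sex differentiation (F_ST) and
within-sex fixation (F_IS) using Weir–Cockerham (1984) variance components
with the two sexes as groups, averages them over SNP-count sliding windows,
calls candidate regions under dual thresholds (F_ST ≥ 0.3 and F_IS ≤ −0.5
by default, windows spanning > 1 kb), classifies each candidate as XX/XY or
ZW/ZZ from per-sex heterozygosity, and inspects linkage disequilibrium
(composite genotypic r² plus a Monte-Carlo exact test of genotypic
disequilibrium) across the top region to detect inversion-like
recombination suppression.

At a fully sex-linked SNP in a balanced sample the expected values are
F_ST = 0.5, F_IS = −1, with pooled allele frequencies 0.75 (X/Z allele)
and 0.25 (Y/W allele); these identities are enforced to 1e-12 in the test
suite.

Additional stages:

- **panel validation** — re-test candidate SNPs in a larger sexed sample:
  per-SNP F_ST / F_IS plus a two-sided Fisher exact test on allele counts
  by sex (exact integer hypergeometric enumeration).
- **depth check** — test for sex-specific gene duplication by comparing
  library-size-normalized read counts between sexes with an (exhaustive
  when feasible) label-permutation test.
- **synthetic data** — a simulator that embeds a recombination-suppressed
  XX/XY (or ZW) block, with a single shared Y haplotype, inside neutral
  background SNPs, with configurable partial sex-linkage, genotyping error
  and missingness; used throughout the tests for parameter-recovery and
  specificity checks.

## CLI

```sh
# simulate a desk-scale dataset (VCF + sex map + ground-truth JSON)
sdscreen simulate --out sim/ --seed 1

# run the full screen
sdscreen run --vcf sim/genotypes.vcf --sex-map sim/sex_map.tsv --out out/ \
    --window-k 10 --maf 0.2 --qual 20 --fst-min 0.3 --fis-max -0.5 \
    --min-span 1000 --seed 1

# pairwise LD for a region
sdscreen ld --vcf sim/genotypes.vcf --chrom chr1 --start 4000000 \
    --end 6000000 --out ld.tsv

# panel validation and read-depth duplication check
sdscreen validate-panel --panel-tsv panel.tsv --sex-map sex.tsv --out res.tsv
sdscreen depth-check --table depth.tsv --gene sox3
```

`sdscreen run` writes `locus_stats.tsv`, `windows.tsv`, `regions.tsv`,
`ld_top_region.tsv` and a `manifest.json` with parameters, seed and SNP
counts after each filter stage; outputs are byte-identical across reruns
with the same inputs and seed (modulo the manifest timestamp).

## Conventions

- VCF positions are 1-based; region spans are inclusive
  (`end − start + 1` bp) and the > 1 kb span rule is strict.
- SNPs with QUAL below the threshold are removed (QUAL exactly at the
  threshold is kept); multiallelic records and indels are dropped and
  counted; half-calls are treated as missing; phase is ignored.
- F-statistics use per-locus complete-case genotypes within each sex; loci
  with fewer than two complete genotypes in either sex are UNDEFINED (NaN)
  and excluded from window means, never silently dropped. Negative
  estimates are reported un-truncated.
- MAF is computed pooled over both sexes.

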