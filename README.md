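# haplopop

A haploid-aware comparative population-genomics pipeline for haplodiploid
resequencing studies in which behavior (or any binary trait) varies among
populations. It covers the full post-variant-calling workflow:

- **variant QC** — the filter cascade for haploid males: indel removal, site
  quality, heterozygous-artifact filters (site-level count and per-individual
  fraction), missingness, MAF, and biallelic restriction, with per-filter
  removal tallies;
- **popgen statistics** — nucleotide diversity (π) and Watterson's θ, haploid
  Weir–Cockerham F\_ST (per site and ratio-of-sums genome-wide) with a
  label-permutation significance test, LD decay in 50 kb windows, PLINK-style
  `--indep 50 5 2` VIF pruning, and frequency-scaled genotype PCA;
- **GWAS** — univariate linear mixed model with a centered genomic relatedness
  matrix, per-SNP REML variance-ratio optimization, Wald tests, and
  Benjamini–Hochberg FDR;
- **annotation & enrichment** — strand-aware positional classes (5 kb
  upstream of the TSS, 1 kb downstream of the last codon, intron,
  synonymous/non-synonymous exon calls, 10 kb proximal, intergenic),
  derived-allele polarization against outgroup haplotypes, and upper-tail
  hypergeometric enrichment for positional classes and gene sets;
- **assay statistics** — ΔCT qPCR normalization with fold changes and a
  two-sample t-test, and one-way ANOVA with Tukey HSD for reporter assays;
- **synthetic data** — a Balding–Nichols island-model generator with
  block-structured LD, planted behavior-associated SNPs, haploid
  heterozygous-artifact/missingness noise, outgroup haplotypes, and GFF3 gene
  models, so the whole pipeline is testable end to end without external data.

Inputs are standard formats: VCF v4.2 (haploid genotypes accepted as `0` or
`0/0` style), GFF3 gene models, and a 4-column sample metadata TSV
(`sample_id`, `population`, `behavior`, `is_outgroup`).

## CLI

Everything is exposed through one executable with subcommands:

```sh
haplopop simulate --out sim/ --seed 1 --n-snps 10000 --n-causal 1 --causal-shift 0.6
haplopop qc      --vcf sim/simulated.vcf --meta sim/samples.tsv --out qc/
haplopop popgen  --vcf qc/filtered.vcf --meta sim/samples.tsv \
                 --genome-length 2000000 --out popgen/
haplopop gwas    --vcf qc/filtered.vcf --meta sim/samples.tsv --out gwas/
haplopop annotate --vcf qc/filtered.vcf --meta sim/samples.tsv \
                  --gff sim/genes.gff3 --hits gwas/hits.tsv --out annot/
haplopop assays qpcr     --table plate.csv --target syx --reference rps --out q/
haplopop assays reporter --table luminescence.csv --out r/
haplopop all --out run/ --seed 1        # simulate -> qc -> popgen -> gwas -> annotate
```

Thresholds and window sizes default to the published values (QUAL ≥ 30,
het-site cap 15, uncalled cap 16, 30 % individual heterozygosity, MAF ≥ 0.05,
1000 permutations over 100 000-SNP subsets, FDR q < 5 × 10⁻⁵, 5 kb/1 kb/10 kb
annotation windows) and can be overridden with a flat `key = value` config
file passed as `haplopop --config run.cfg <subcommand> ...`.

## Layout

```
src/haplopop/
  types.py        core domain types (genotype matrix, variants, samples, genes)
  pipeline_io.py  VCF/GFF3/metadata readers & writers, run config, manifests
  simulate.py     synthetic haplodiploid dataset generator
  qc.py           post-calling filter cascade
  popgen.py       diversity, F_ST + permutation null, LD, pruning, PCA
  gwas.py         mixed-model association scan and FDR
  annotate.py     positional annotation, polarization, enrichment tests
  assays.py       qPCR and reporter-assay statistics
  cli.py          click-based command-line interface
```
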