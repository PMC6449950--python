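# maescan

Detection and quantification of **monoallelic expression (MAE)** from
paired DNA genotypes and RNA-seq allelic counts.

In a diploid cell both alleles of a gene are usually expressed. MAE is the
restriction of expression to a single allele at a locus that is
heterozygous in genomic DNA — constitutive for imprinted genes, olfactory
receptors and the inactive X in females, and frequent in tumors where
copy-number loss or epigenetic silencing removes one allele from the
transcriptome. `maescan` finds MAE by genotype concordance: a SNP called
heterozygous in DNA whose RNA-seq reads support only one allele is
monoallelically expressed.

## What it computes

For each SNP heterozygous in DNA with RNA coverage (an *informative* SNP),
the **B-allele frequency** is

&nbsp;&nbsp;&nbsp;&nbsp;BAF = n_B / (n_A + n_B),

where n_A, n_B are reads supporting each genotype allele. SNPs with depth
≤ 5 or outside annotated CDS are excluded. With threshold τ (default
0.05), BAF ≤ τ or ≥ 1 − τ is a homozygous RNA genotype (complete MAE);
BAF in the intermediate tails (default outside 0.35–0.65) is skewed
differential allelic expression (DAE); the center is balanced. The
per-sample **MAE frequency** is

&nbsp;&nbsp;&nbsp;&nbsp;f_MAE = (# informative SNPs homozygous in RNA) / (# informative SNPs),

reported over autosomes, with X-linked SNPs summarized separately. On top
of the per-SNP calls the package builds:

- **per-chromosome MAE matrix** — samples × chromosomes MAE fractions with
  *complete-chromosome MAE* flags (fraction ≥ 0.9, ≥ 50 informative SNPs),
  and an exact two-sided enrichment test of one chromosome against all
  other autosomes (hypergeometric enumeration in integer arithmetic);
- **CN explanation** — overlap of MAE SNPs with pre-called copy-number
  loss/gain segments, classifying each sample-chromosome as CN-explained,
  partial or unexplained (the unexplained remainder pointing to epigenetic
  silencing);
- **positive controls** — MAE fractions on the female X (X inactivation)
  and in imprinted / olfactory-receptor gene sets;
- **recurrent-MAE genes** — genes with ≥ 2 MAE SNPs per sample shared by
  ≥ 8 samples;
- **synthetic cohorts** — a simulator emitting array genotypes, allelic
  counts (binomial reads over truncated-Poisson depth with allele-flip
  error), CN segments, gene models and per-SNP expression truth, for
  validating every stage against known ground truth.

## Worked example

A bundled table carries per-cell-line MAE frequencies for 15 melanoma
cell lines genotyped against their parental tumor-infiltrating
lymphocytes, for both the directly genotyped ("non-imputed") and the
imputation-extended SNP sets:

```bash
python examples/02_published_cohort_summaries.py
```

```
 non-imputed: mean 0.54 +- 0.24 (range 0.17-0.77, n=15)
     imputed: mean 0.60 +- 0.21 (range 0.28-0.80, n=15)

NRAS lines: mean 0.59 SD 0.18 (n=6)
BRAF lines: mean 0.54 SD 0.27 (n=8)
Welch t-test p = 0.70 — no significant difference in MAE
rate between the two mutation groups at this sample size.
```

Between 17% and 80% of informative SNPs per line are monoallelically
expressed — far above the 5–20% reported for normal tissues — and the MAE
rate does not separate BRAF- from NRAS-mutant lines. Complete-chromosome
MAE concentrates strikingly on chromosome 9:

```bash
python examples/03_chromosome_mae_and_enrichment.py
```

```
chr9: 11 of 15 lines under complete MAE; other autosomes: 36 of 315 sample-chromosome pairs
odds ratio 21.3, exact two-sided p = 1.43e-07
```

The remaining examples simulate cohorts with known truth: per-sample MAE
recovery (`01`), separating CN-driven from epigenetic chromosome MAE
(`04`), and recovering planted recurrent-MAE genes (`05`).

## Command line

A thin CLI wraps the library: `maescan simulate | qc | mae | chrom | cn |
genes | all` (see `maescan --help`); `all` runs the full pipeline from a
YAML configuration and writes TSV tables plus a JSON run report with a
configuration hash for reproducibility.

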