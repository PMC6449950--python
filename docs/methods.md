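# Methods

## Model and procedure

`maescan` detects monoallelic expression (MAE) by DNA–RNA genotype
concordance. The atomic unit is the *informative SNP*: a biallelic SNP
called heterozygous (AB) in genomic DNA whose position has sufficient
RNA-seq read support. For each informative SNP the B-allele frequency
BAF = n_B/(n_A + n_B) is computed from the allelic read counts; reads
supporting bases other than the two genotype alleles are ignored, so
depth is always n_A + n_B. A homozygous RNA genotype at a DNA-het site is
the operational signature of MAE.

The analysis chain:

1. **Genotype QC** (array-style). Per-call confidence (GenCall-type)
   scores below 0.15 mask the call to NoCall; scores exactly at the
   cutoff are retained (vendor ≥-convention). Markers with cluster
   (GenTrain-type) score < 0.5 are removed. Markers and samples with call
   rate < 95% are then dropped, iterating marker/sample passes to a fixed
   point so the filter is idempotent — a single pass can leave a marker
   whose call rate falls below the floor only after a bad sample is
   removed. Whether a low GenCall score should mask a single call or
   discard the whole sample is genuinely open; masking is the less
   destructive choice and feeds the call-rate filter naturally.
2. **Heterozygosity selection.** Only AB calls proceed; homozygous DNA
   genotypes carry no allelic information.
3. **Count join and filters.** RNA allelic counts are joined on
   (sample, chromosome, position); het SNPs without counts are reported
   as uncovered, never silently dropped. Depth must be strictly greater
   than 5; SNPs outside every annotated CDS are excluded as potentially
   unrepresentative of their gene. A SNP inside several overlapping CDS
   is credited to every such gene (this affects only gene-level
   recurrence).
4. **RNA genotype and per-SNP class.** With τ = 0.05: HomA if BAF ≤ τ,
   HomB if BAF ≥ 1 − τ, else Het. The three-way expression class adds
   skew bands: complete MAE for BAF ≤ τ or ≥ 1 − τ, skewed DAE for BAF in
   (τ, 0.35] ∪ [0.65, 1 − τ), balanced otherwise. An optional exact
   binomial guard additionally requires a two-sided test of n_B against
   p = 0.5 to reject at 10⁻³ before a homozygous call, protecting
   low-depth sites.
5. **Sample statistic.** MAE frequency = RNA-homozygous informative SNPs
   over all informative SNPs, computed over autosomes; X-linked SNPs are
   summarized separately because X inactivation makes female X MAE
   expected rather than informative about the tumor genome. Cohort
   summaries use the sample SD (n − 1); group comparison is Welch's
   unequal-variance t-test, the safer default when group variances
   differ.
6. **Chromosome calls.** Per (sample, chromosome): MAE fraction among
   informative SNPs; *complete-chromosome MAE* when the fraction is
   ≥ θ = 0.90 with ≥ 50 informative SNPs. Both values are configurable;
   the indicator has no canonical definition, and the floor on SNP count
   prevents sparse chromosomes from being flagged on noise.
7. **Enrichment.** One chromosome versus the pool of all other autosomes,
   as a 2×2 table of flagged/unflagged sample-chromosome pairs. The
   two-sided exact p sums hypergeometric probabilities of all tables (at
   fixed margins) no more probable than the observed one. Probabilities
   are compared as exact integer numerators over a common binomial
   denominator, so ties need no floating-point tolerance; the float
   division happens once, at the end. X is excluded (confounded by XCI).
8. **CN explanation.** A complete-MAE SNP inside a pre-called loss *or*
   gain segment is CN-explained (a gain can amplify one allele;
   losses-only is a switch). Per sample-chromosome, explained fraction
   ≥ 0.8 ⇒ CN-explained, ≤ 0.2 ⇒ unexplained, else partial; samples
   without any segment data give "no-data" rather than a fake verdict.
   Segment containment is 1-based inclusive, matching SNP coordinates;
   same-state overlapping segments are merged on load, so the result is
   invariant under segment splitting.
9. **Gene recurrence.** A gene shows MAE in a sample when ≥ 2 of its
   informative SNPs are complete-MAE; genes doing so in ≥ 8 samples are
   reported, ranked by sample count with gene id as tie-break. An
   alternative reading (≥ 2 informative SNPs, ≥ 1 of them MAE) sits
   behind `relaxed_rule`.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `depth_min` | 5 (strict >) | minimum RNA depth for an informative SNP |
| `hom_baf_tau` | 0.05 | BAF threshold for RNA homozygosity |
| `skew_lo`/`skew_hi` | 0.35 / 0.65 | balanced vs skewed-DAE band |
| `min_call_rate` | 0.95 | sample/marker call-rate floor |
| `min_gencall` / `min_gentrain` | 0.15 / 0.5 | per-call and per-marker score cutoffs |
| `theta_chrom` / `min_snps` | 0.90 / 50 | complete-chromosome MAE rule |
| `theta_cn` | 0.8 | CN-explained verdict threshold |
| `min_mae_snps_per_gene` / `min_samples` | 2 / 8 | recurrence filter |

The skew bands are the one genuinely arbitrary pair: they separate the
central mass of a typical BAF histogram from its tails, and at 30×
depth a balanced SNP has ≈ 10% probability of drifting past 0.35/0.65 by
sampling alone. Conclusions about *complete* MAE depend only on τ, which
is why the headline statistic counts RNA-homozygous SNPs rather than
everything outside the balanced band.

## The simulator

`SimConfig`/`generate_cohort` emulate the full input stack: tiled genes
(80% CDS per block) with SNPs every 2 kb, per-sample heterozygosity at
rate 0.3, read depth ~ Poisson(λ = 30) truncated at 1 (negative binomial
optional), and n_B ~ Binomial(depth, p) with p = 0.5 for balanced SNPs,
s or 1 − s (s = 0.8) for skewed DAE, and ε or 1 − ε (ε = 0.005) for
complete MAE — the allele-flip error makes MAE BAFs cluster *near* 0/1
as in real pileups. Causes layer in increasing precedence: genome-wide
random MAE/DAE mixture, imprinted genes (MAE in every sample), female X
under XCI (one expressed haplotype per SNP; partial skew configurable),
epigenetic MAE spans, and CN events, which also emit the matching SEG
records with the surviving haplotype fixed per event. Males are
hemizygous on X (never het there).

Randomness: one seed spawns independent substreams per layer
(genotypes, expression states, alleles, depth, counts, CN, XCI,
quality), and counts are drawn by quantile transform
(`binom.ppf(u, depth, p)` with per-SNP uniforms), so adding a CN event
re-draws only the SNPs it covers and two runs with one seed are
byte-identical.

What the simulator does **not** model: linkage and phasing (each MAE
SNP's expressed allele is independent except within CN events),
reference-mapping bias toward the reference allele, overdispersion from
PCR duplicates (unless the negative-binomial depth is enabled), genotype
errors in DNA, and shared CN landscapes across samples. Passing
recovery tests therefore demonstrates the statistical machinery is
correct under the stated sampling model, not that real-data artifacts
are handled; on real cohorts the depth filter and the binomial guard are
the main defenses.

## Numerical choices

- Exact test: integer numerators via a multiplicative hypergeometric
  recurrence; per-margin p-values computed by sort + prefix-sum +
  bisect, validated against an independent enumeration oracle for every
  2×2 table with grand total ≤ 200 at 10⁻¹².
- BAF at zero depth is undefined (NaN) and such records are excluded by
  the depth filter before any call is made.
- Histogram bins on [0, 1] are left-closed with the final bin closed, so
  BAF = 1 is counted and totals are conserved.
- Degenerate inputs warn and produce missing values rather than raising:
  a sample with zero informative SNPs, a single-sample cohort SD, an
  absent female for the XCI control.
- Tie-breaks are deterministic everywhere a ranking is emitted (gene id
  as secondary key), and all tables are sorted on their keys so outputs
  are invariant under input row order.

## Validation set-up

Tests size simulations to run on one CPU in seconds: recovery checks use
~10,000 informative SNPs per cohort (22 × 1600 SNPs at 30% het), 20
seeds per mixture setting; CN/XCI checks use 6 or 4 chromosomes at
100–300 SNPs each. The bundled per-cell-line frequency table and the
complete-chromosome flag matrix (see `maescan.datasets`; the flag
matrix's per-cell entries are a synthetic reconstruction consistent with
the published margins) provide fixed worked examples whose summary
statistics are asserted exactly.

## Known limitations

- No phasing: the package scores per-SNP allelic imbalance, not
  haplotype-level expression; a gene's SNPs are aggregated by count, not
  by consistent direction.
- Imputed genotypes are consumed as a second, flagged input set;
  imputation itself, variant calling and read alignment are out of
  scope, as is aCGH segmentation (segments are consumed pre-called).
- The enrichment test treats sample-chromosome pairs as exchangeable
  units; correlation between chromosomes of one sample (e.g. genome-wide
  instability) is not modeled.
- Functional interpretation of the recurrent-gene list (pathway
  enrichment) is deliberately left to external tools; the list is
  exported with deterministic ordering for that purpose.
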