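# Methods

## Model and assumptions

The package estimates, per gene and genetic ancestry, the frequency of
carriers and of disease-compatible genotypes from population allele
frequencies, under four assumptions:

1. **Additive cumulative allele frequency.** Qualifying variants in a gene
   assort independently, so the gene-level pathogenic allele frequency is
   CAF = Σ ACᵢ/ANᵢ. No linkage disequilibrium or phasing: two pathogenic
   alleles in one individual are assumed to be in trans, which makes the
   compound-heterozygote term 2·AFᵢ·AFⱼ and the biallelic frequency exactly
   CAF². Cis configurations would make CAF² an overestimate.
2. **Hardy-Weinberg equilibrium.** Genotype frequencies are (1−c)², 2c(1−c),
   c² at c = CAF — no inbreeding, assortative mating or recent migration.
3. **Full penetrance at the genotype level.** GP counts genotypes compatible
   with disease, not diagnoses; incompletely penetrant alleles (HFE C282Y is
   the canonical case) make GP an upper bound on clinical prevalence.
4. **1:1 sex ratio for X-linked genes**, males hemizygous: the XLR affected
   fraction is c/2 (males) + c²/2 (females) = c(c+1)/2, and XLD adds the
   heterozygous females, c(1−c).

Genetic prevalence dispatches on inheritance mode: dominant (AD, AD/AR,
pseudoautosomal-dominant) → CrF; recessive (AR, pseudoautosomal-recessive)
→ CAF²; XLR and XLD as above. A gene listing both a dominant and a recessive
phenotype (an ANO5-like gene with GoF and LoF conditions) produces one
burden row per (gene, mode) pair; aggregations count it once per mode for
genotype burdens, but once per gene for carrier sums, since carriership does
not depend on the mode.

### Numerical choices

- CAF sums use `math.fsum` (correctly rounded), so results are independent
  of variant row order and the generator's recorded ground truth can be
  compared bit-for-bit with the pipeline's output.
- CAF is capped at 1.0 (with a logged warning and a row flag) if the
  additive sum exceeds 1; the CrF formula is applied literally beyond
  CAF = 0.5, where it decreases, and such rows carry a `high_caf` flag so
  common-allele genes are visible rather than silently odd.
- The non-carrier likelihood Π(1−CrFᵢ) is evaluated as exp(Σ log1p(−CrFᵢ));
  a CrF of exactly 1 short-circuits to 0 with a warning.
- `invert_crf` returns the smaller root (1−√(1−2·CrF))/2 of 2c(1−c) = CrF;
  near CrF = 0.5 the square root loses about half the available precision,
  so the inverse is accurate to ~1e−8 there (tested at that tolerance).
- AN = 0 raises an undefined-frequency error rather than returning AF = 0:
  an uncalled site carries no frequency information.

## Filters

- **QC retention** is per ancestry: FILTER = PASS and AN strictly greater
  than 50% of the callable alleles, where callable = ploidy × sample size
  with ploidy 2 for autosomes and pseudoautosomal regions, 1.5 for chrX
  non-PAR (1:1 sexes) and 0.5 for chrY. The per-individual coverage rule is
  translated to allele numbers because AN is what frequency tables carry;
  the ploidy map and the choice of denominator (ancestry-specific vs total
  sample size) are configurable, ancestry-specific being the default.
- **Gene eligibility**: genes whose inheritance is entirely undefined or
  mitochondrial, or whose mechanism is undefined or repeat-expansion-only,
  are excluded with machine-readable reasons (`inheritance`, `mechanism`).
  Short-variant tables carry no signal for repeat-expansion disease.
- **Screening** uses a strict CrF > 1/200 per ancestry; the shared candidate
  set is the intersection across ancestries.
- **Constraint flags** are strict comparisons at pLI > 0.9, LOEUF < 0.6,
  S_het > 0.073, missense Z > 3.09, synonymous Z > 3.71; a missing metric
  yields a missing flag, never False.

## Interpretations made where the definition was open

- **"Probability of carrying any variant" as an expected count.** The
  cross-gene carrier sum Σ CrF exceeds 1 for realistic panels, so it is
  reported as the expected number of genes in which an individual carries a
  qualifying variant, not as a probability; the non-carrier likelihood
  Π(1−CrF) is the actual probability of carrying nothing.
- **Dominant adjustment** of a disease group = mean GP per dominant
  (gene, mode) pair in the group. This is one reasonable normalization —
  groups whose dominant genes are depleted of pathogenic variation
  (haploinsufficiency under purifying selection) rank low — and it is
  isolated in `dominant_adjusted_burden` so an alternative definition can
  be swapped in.
- **Reported carrier frequency conventions.** From a reported disease
  prevalence rP, the default computes rCrF = 2·rP·(1−rP) directly
  (`as-printed`); the alternative `sqrt-prevalence` convention first
  recovers the allele frequency as √rP, which is the standard HWE relation
  for a fully penetrant recessive disease. Both are exposed because the
  direct form treats a prevalence as an allele frequency; the package does
  not silently decide which was intended.
- **X-linked carrier frequency** is reported as the female heterozygote
  frequency 2c(1−c) — the conventional reading of "carrier" for X-linked
  recessive disease.
- **Cross-ancestry means** are unweighted arithmetic means over the
  ancestries present, with a warning when a subset is supplied.
- **Headcounts** are per-ancestry rate × population size, summed; the
  global "1 in x" is the summed headcount over the total population.

## The synthetic-data generator

`simulate_cohort` emulates the structure of a classified population exome
callset, with defaults chosen once to mirror the study conditions:

- eight ancestry groups with an nfe-dominated sample-size imbalance
  (140 000 simulated exomes total by default — desk scale);
- tier proportions 0.6% P, 2.2% LP, 1.0% VUS-H, with the benign-side
  remainder distributed so the seven tiers sum to exactly 1;
- an inheritance mix proportional to the PanelApp-style breakdown
  (2013 AR : 1425 AD : 256 AD/AR : 148 XLR : 65 XLD : 1 : 1 pseudoautosomal),
  restricted to modes the prevalence dispatch can handle;
- per-variant allele frequencies from a truncated exponential on (0, 0.05]
  (scale 0.002), optionally mixed with uniform common-variant outliers to
  emulate HFE/G6PD-like alleles;
- Poisson(60) variants per gene; 1–9 ICD-10 groups per gene with ~33%/~35%
  of genes in one/two groups and a long tail to nine;
- a 5% non-PASS fraction, and AN jittered uniformly between 40% and 100% of
  the callable alleles so the coverage filter sees both passing and failing
  rows (the strict >50% boundary would otherwise almost never be crossed);
- X-linked genes are placed on chrX with ~1.5 callable alleles per
  individual; pseudoautosomal genes on a diploid chrX_PAR contig.

Per variant and ancestry, AC ~ Binomial(AN, AF_true); the recorded ground
truth is the fsum of the *realized* AC/AN over the rows that survive the
PASS + coverage rule, per gene × ancestry × tier set. The pipeline
re-derives retention from the written files, so the exact-recovery test is a
genuine round trip through serialization, parsing, QC and summation.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, inbreeding, ancestry-correlated allele frequencies
(each ancestry's AC is an independent binomial around a shared true AF),
site-level sequencing artifacts, and the real panel's gene-to-group
topology. Passing tests therefore demonstrate that the estimators implement
the stated formulas and filters faithfully on data matching the model's own
assumptions — not that those assumptions hold in any real population.

`simulate_genotypes` is the independent Monte-Carlo oracle: it draws
individuals allele-by-allele (sexes 1:1 for X-linked modes) and its
empirical genotype fractions are required to match the closed forms within
three binomial standard errors at n = 10⁵.

## Problem sizes

The test suite exercises a 40-gene structural fixture throughout and one
500-gene × 8-ancestry end-to-end run (~30 000 variants, a few seconds); the
acceptance script runs a 50-gene self-check plus the closed-form worked
examples. These sizes were chosen to keep the full suite under a minute
while covering every inheritance mode, both I/O dialects, and the QC
boundary behaviour.

## Known limitations

- No penetrance modelling, no inbreeding coefficient, no LD-aware phasing;
  GP is a genotype frequency, not a clinical prevalence.
- CrF beyond CAF = 0.5 follows the literal formula and must be read with
  the `high_caf` flag in hand.
- Multiallelic VCF sites are split per alternate allele with shared
  site-level GENE/TIER annotations; allele-specific annotations beyond the
  first are not modelled.
- The regression validation assumes log-normal errors and user-supplied
  ancestry→stratum and gene→reported-prevalence pairings.
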