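# burdenkit

Carrier frequency and genetic prevalence of Mendelian disease, estimated
gene-by-gene from multi-ancestry population allele frequency tables.

## The problem

Population sequencing databases such as gnomAD report, for every observed
variant, an allele count (AC) and allele number (AN) per genetic ancestry
group. Once each variant carries a pathogenicity tier — P, LP, VUS-H, VUS-M,
VUS-L, LB, B, by descending posterior odds of pathogenicity — these
frequencies imply, for every disease gene, how common carriers are and how
common disease-compatible genotypes are in each population. `burdenkit` turns
a classified variant table plus gene-panel metadata (inheritance mode,
disease mechanism, ICD-10 disease groups, actionable-gene and screening
flags) into those estimates, for geneticists, genetic epidemiologists and
screening-programme designers.

## The model

For a gene and ancestry, with qualifying variants' allele frequencies
AFᵢ = ACᵢ/ANᵢ summed under independent assortment into a cumulative allele
frequency CAF = Σ AFᵢ, Hardy-Weinberg equilibrium gives

- carrier frequency  CrF = 2·CAF·(1−CAF)
- homozygote + compound-heterozygote frequency  HomF = CAF²
- genetic prevalence GP, dispatched on inheritance:
  CrF for dominant genes (AD, AD/AR, pseudoautosomal-dominant), CAF² for
  recessive genes, CAF·(CAF+1)/2 for X-linked recessive and
  CAF·(1−CAF) + CAF·(CAF+1)/2 for X-linked dominant (1:1 sexes, hemizygous
  males).

Qualifying variants are taken at three nested tiers (P ⊂ P+LP ⊂ P+LP+VUS-H)
after a per-ancestry QC rule: FILTER = PASS and AN covering more than 50% of
that ancestry's callable alleles. Gene-level results aggregate into expected
carried-gene counts (Σ CrF), expected disease-genotype counts (Σ GP over
(gene, mode) pairs), the non-carrier likelihood Π(1−CrFᵢ), ICD-10
disease-group burdens, ACMG secondary-findings summaries (with single-variant
restrictions like HFE's), and carrier-screening candidates (CrF > 1/200).

A synthetic-cohort generator (`burdenkit.simulate`) produces gnomAD-shaped
variant tables with recorded ground truth so the entire chain is testable
without the real download.

## Worked example

```python
from burdenkit import carrier_frequency, invert_crf

# Two carrier classes in one gene, published as carrier frequencies:
# 1 in 21 (hypomorphic alleles) and 1 in 27 (disease-causing alleles).
caf = invert_crf(1 / 21) + invert_crf(1 / 27)
print(round(caf, 6))                     # 0.04328
combined = carrier_frequency(caf)
print(round(combined, 4))                # 0.0828
print(f"1 in {round(1 / combined)}")     # 1 in 12
```

Inverting each class's CrF recovers its cumulative allele frequency
(0.024405 and 0.018875), the CAFs add under independent assortment to
0.04328, and re-applying 2c(1−c) shows that roughly one person in twelve
carries an allele of either class — carrier classes combine through CAF
space, not by adding carrier frequencies.

An end-to-end run on synthetic data:

```sh
burdenkit simulate --out-dir sim --seed 1 --n-genes 100
burdenkit run --config pipeline.yaml
```

where `pipeline.yaml` points at the simulated `variants.tsv` (or
`variants.vcf`), `gene_meta.tsv` and `populations.tsv` and names the
per-ancestry sample sizes. The output directory contains per-gene burdens
(`gene_burdens.tsv` with CAF/CrF/HomF/GP and "1 in x" renderings), the
cohort summary, group burdens, screening candidates, secondary-findings
summaries, a manifest and a run log.

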