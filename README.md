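# vwdprev

Population-scale estimation of von Willebrand disease (VWD) prevalence from
gnomAD-style allele-frequency data of the *VWF* gene.

VWD is the most common inherited bleeding disorder, caused by quantitative
(types 1 and 3) or qualitative (types 2A, 2B, 2M, 2N) defects of von
Willebrand factor. Clinically ascertained prevalence estimates (0.6–1.3%)
are limited by referral bias and geography; an alternative is to count
pathogenic *VWF* alleles in population sequencing databases and convert
allele frequencies into genotype frequencies under Hardy–Weinberg
equilibrium. This package implements that workflow as a tested, reusable
pipeline for researchers in hemostasis genetics and population genetics:

1. **Cohort I/O** — typed per-variant records with per-population
   `AC`/`AN`/`nhomalt` counts, read and written as TSV or VCF 4.2
   (multi-allelic sites split into biallelic records).
2. **Knowledge base** — an HGMD/LOVD-style known-variant lookup with VWD
   type, inheritance mode, a clear-association flag, and a merge policy that
   defers to the primary literature when the sources disagree.
3. **Pathogenicity cascade** — a conservative five-rule filter: known
   database membership; truncating variants (nonsense, frameshift, inframe
   indels, stop-loss); core splice-site variants (intronic positions ±1/±2);
   splice-region variants (±3..±8) passing a 4-of-4 predictor consensus
   (Varseak, ESEFinder, BDGP and CADD ≥ 20); and missense variants passing a
   7-of-7 consensus (SIFT, PolyPhen2, LRT, MutationTaster, MutationAssessor,
   FATHMM and CADD ≥ 20). Missing predictions fail closed.
4. **Allele aggregation** — per-population affected-allele tallies split
   into reported vs novel, recurrent-variant rankings, MAF > 1% flags, and a
   homozygote census.
5. **Hardy–Weinberg prevalence** — with collective pathogenic-allele
   frequency *q* and *p* = 1 − *q*:
   carrier frequency ≈ 2*q*, dominant prevalence = 2*pq*, recessive
   prevalence = *q*², compound-recessive (type 2N) prevalence =
   *q*₂ₙ² + 2·*q*₂ₙ·*q*_null with null alleles pooled from types 1 and 3,
   and pooled-recessive (type 3) prevalence = (*q*₃ + *q*₁)².
6. **Domain annotation** — maps protein positions onto the VWF domain
   architecture (SP, D1-D2 propeptide, D′-D3-A1-A2-A3-D4-C1..C6-CK) and
   builds VWD-type × domain crosstabs.
7. **Synthetic cohorts** — a seeded generator drawing per-individual
   genotypes under Hardy–Weinberg equilibrium at configurable true allele
   frequencies, with predictor profiles of configurable concordance and a
   matching knowledge-base fixture, so the whole pipeline is testable
   without any external downloads.

## Worked example

Generate the planted-count population fixture (eight gnomAD-style strata,
141,456 individuals, affected-allele totals planted per stratum) and run the
full pipeline on it:

```bash
vwdprev simulate --fixture table4_populations --out-dir fixture/
vwdprev report \
  --variants fixture/table4_populations.variants.tsv \
  --known-db fixture/table4_populations.known_db.tsv \
  --populations fixture/table4_populations.populations.yaml \
  --out-dir results/
```

`results/affected_alleles.tsv` then contains (abridged):

```
population  total_affected  affected_reported  affected_novel  an_ref   novel_fraction
eas         546             443                103             19954    0.18864...
all         31785           30850              935             282912   0.02941...
```

i.e. 31,785 of 282,912 alleles carry a pathogenic variant, 2.9% of them
novel (18.9% in the East Asian stratum). `results/prevalence.tsv` contains
the Hardy–Weinberg grid; with the default exclusion config (three common
African/African-American variants removed from that stratum) the global row
gives

```
population  label          model          value     scale   q
all         all_variants   carrier_2q     13.9216   per100  0.069608
all         all_variants   dominant_2pq   12.9526   per100  0.069608
all         all_variants   recessive_q2    0.4845   per100  0.069608
```

read as: collective pathogenic-allele frequency q ≈ 0.07, so about 13.9% of
alleles (≈ 13% of individuals, 2pq) are in the heterozygous state and 0.48
per 100 individuals are homozygous/recessive. The same grid holds
per-population rows, the reported-variants-only approach, and the per-type
dominant/compound/pooled models per 1000 individuals.

The same analysis is available as library calls
(`read_variant_table`, `classify_cohort`, `affected_alleles`,
`prevalence_report`) for use in notebooks.

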