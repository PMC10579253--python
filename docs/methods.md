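# Methods

## Model

The pipeline estimates VWD prevalence from allele counts alone, under three
assumptions: (i) the population is at Hardy–Weinberg equilibrium at each
*VWF* site, (ii) pathogenic alleles at different sites can be pooled into a
single "affected allele" class with collective frequency
q = Σᵢ qᵢ (valid for rare alleles, where multi-site genotypes are
negligible; the MAF > 1% cutoff and the named common-variant exclusions keep
the per-type sums in that regime), and (iii) penetrance is complete —
estimates are therefore genotype prevalences, an upper bound on clinical
prevalence.

With p = 1 − q, the genotype frequencies p² + 2pq + q² = 1 give:

| model | formula | used for |
|---|---|---|
| carrier frequency | 2q | allele-counting approximation of carriership |
| dominant prevalence | 2pq | types 1, 2A, 2B, 2M |
| recessive prevalence | q² | cohort-wide recessive figure |
| compound recessive | q₂ₙ² + 2·q₂ₙ·q_null | type 2N (2N/2N or 2N/null genotypes) |
| pooled recessive | (q₃ + q₁)² | type 3 (type 1 alleles pooled as the null class) |

Carrier frequency 2q and dominant prevalence 2pq are deliberately exposed
as distinct models: for q ≈ 0.07 they differ visibly (13.9 vs 13.0 per
100) and both conventions appear in published tables. 2q exceeds 1 beyond
q = 0.5, where it is an expected allele dosage rather than a probability;
the code permits it and documents the caveat.

Two q conventions coexist by design. Cohort-wide collective q divides the
summed allele counts of pathogenic variants by the fixed stratum
denominator an_ref = 2·n_individuals, which is how population-database
summary tables are normalized. Type-specific q sums per-variant MAFs, each
with its own genotyped allele number AN, which is how per-variant frequency
tables are printed. Both are exact for planted fixtures and differ only
through per-site call-rate variation on real data.

For the pooled type 3 model the package uses (q₃ + q₁)² — both allele
classes pooled into one recessive class — rather than q₃² + 2·q₃·q₁. The
alternative equals the compound model with q_null = q₁ and is available by
calling `compound_recessive_prevalence` directly; the pooled form was
chosen because type 1 and type 3 alleles are both null-like for the
homozygous-deficiency phenotype. The audit trail on every estimate records
the variant set, exclusions and cutoff actually used.

## Pathogenicity cascade

Rules are evaluated in priority order: known-database membership >
truncating > core splice site > splice consensus > missense consensus. The
first matching rule is recorded; database membership also defines the
reported/novel split, so a variant both known and truncating counts as
reported. Details that matter:

- *Fail-closed consensus.* A missing predictor call or missing CADD score
  can never satisfy a consensus rule; the 7/7 and 4/4 requirements are
  conjunctions over the full tool lists.
- *Splice tool rule.* A tool votes deleterious when it abolishes the
  wild-type site or when the variant score is strictly below half the
  wild-type score; a wild-type score of 0 can only pass via abolition.
- *CADD threshold.* PHRED-scaled CADD ≥ 20 (inclusive) counts as
  deleterious; 19.9 fails.
- *Stop-loss.* Admitted under the truncating rule as a stop-codon-affecting
  class, configurable off (`CascadeConfig.admit_stop_lost`).
- *Synonymous variants.* Only the knowledge-base rule can admit them.

Knowledge-base merging unions HGMD- and LOVD-style tables by
whitespace-normalized cDNA HGVS string. Agreement keeps the type;
disagreement resolves to a literature override when present, otherwise to
UC (unclassified). Entries without a clear disease association are loaded
but never returned by lookup, so they contribute to nothing downstream.

## Synthetic cohorts: what they emulate and what they do not

`SimulationSpec` defaults encode the study conditions of a gnomAD v2.1
*VWF* analysis: eight strata totalling 141,456 individuals; 4,313 variants
of which 505 are pathogenic and 218 of those reported; the pathogenic
consequence mix 355 missense / 53 frameshift / 40 stop-gained / 1
stop-loss / 41 splice / 14 inframe / 1 synonymous; the reported VWD-type
mix 78:54:23:21:15:12:15 over types 1/3/2A/2M/2N/2B/UC; ten recurrent
reported variants with per-population point-mass frequencies; and a rare
tail in which 48% of pathogenic variants are cohort-wide singletons, the
rest drawn log-uniformly from [1e-5, 2e-3]. The published total of 41
splice variants is not split between core sites and splice regions; the
generator uses 28 core / 13 region.

Genotypes are sampled per individual under HWE — a multinomial draw over
dosages (0, 1, 2) with probabilities (p², 2pq, q²) per variant and stratum —
so allele counts, homozygote counts and the per-individual brute-force
aggregation oracle are jointly consistent by construction
(ac = n₁ + 2·n₂, an = 2N). Predictor profiles are drawn with configurable
concordance: at concordance 1.0 and false-positive rate 0, classification
recovers the planted pathogenic set exactly, which is the pipeline-closure
test; lower concordance produces only false negatives in the
consensus-dependent classes, mirroring how a strict consensus behaves.

Not emulated: linkage/haplotype structure between variants, sequencing
error, per-site call-rate variation (simulated AN is always 2N), population
substructure within strata, and variable penetrance. Passing tests
therefore validate the accounting and the models, not the biological
accuracy of any particular predictor or database.

Named fixtures (`end_to_end_fixture`) plant counts instead of sampling:
`table4_populations` reproduces the per-stratum affected-allele totals
(31,785 of 282,912 overall) including the three common African/African-
American variants (4,743 + 4,497 + 2,852 alleles) whose exclusion yields
the headline 19,693; `fig1_mix` plants the 505-variant class mix;
`fig2_types` the 218 typed reported variants; `table3_finnish` the five
most frequent Finnish variants with six-decimal MAFs reproduced exactly by
planting integer counts against a synthetic AN of 10⁶; `table6_common` the
ten MAF > 1% variants across strata. These are synthetic stand-ins with the
same schema as the real inputs, not redistributions of HGMD/LOVD/gnomAD.

## Numerical and design choices

- Exclusion lists are per-population data (`data/default_config.yaml`), not
  code: the arithmetic of the published totals shows the common-variant
  exclusion was applied to the African stratum only, while other strata and
  the grand total keep those variants' (small) allele counts elsewhere.
- The MAF > 1% cutoff for per-type models is strict and evaluated in the
  population being estimated (pooled MAF for the global rows).
- All computation is kept at full double precision; rounding happens only
  at rendering. Reported tables carry the raw values.
- Domain boundaries below the architectural anchors (signal peptide
  1..22, propeptide 23..763, mature subunit to 2813) are not fixed by any
  single authority, so the domain map is configuration data validated for
  total, gap-free, ordered coverage; the shipped default follows commonly
  used boundaries. A residue belongs to exactly one domain; junction labels
  are not modelled.
- TSV is the canonical dialect (deterministic, annotation-tool-free
  fixtures); VCF 4.2 support exists for interoperability, with HGVS strings
  percent-encoded in INFO to survive verbatim. HGVS strings are never
  recomputed from genomic coordinates (*VWF* is on the minus strand).
- An absent population stratum and an all-zero (ac, an, n_hom) triple are
  the same state, keeping write/read round trips exact under any cohort
  population spec.
- Degenerate inputs: an = 0 makes MAF undefined (error, not 0); empty
  cohorts yield empty summaries and zero tables; q is validated into [0, 1]
  at every model entry point; compound/pooled models reject component sums
  above 1.

## Problem sizes in tests

Unit and property tests run on cohorts of 40–500 variants over strata of
10²–10⁴ individuals; the parameter-recovery checks use one stratum of
50,000 individuals at true collective frequencies 0.001/0.01/0.1 with a
4-binomial-SE acceptance band; the exhaustive cascade oracle enumerates all
2⁶ categorical call patterns × CADD ∈ {19, 20}. The full suite completes in
a few seconds.

## Known limitations

- Prevalence estimates assume complete penetrance and independence of
  sites; compound heterozygosity across strata is modelled only through the
  pooled-q approximation (population databases carry no phase).
- The cascade consumes precomputed predictor calls; it cannot detect
  variants the predictors were never run on (they fail closed into the
  benign class).
- The homozygote census reports what the counts contain and asserts no
  external total.
- Gross deletions, rearrangements, promoter and deep-intronic variants are
  out of scope; the input model is SNVs and short indels with intronic
  offsets within ±8 of an exon boundary.
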