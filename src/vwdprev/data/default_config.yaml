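# Default study configuration.
#
# Exclusion lists are study choices, kept as data: the three VWF variants
# common in the African/African-American stratum (p.Arg2185Gln, p.Met740Ile,
# p.His817Gln) are removed from that stratum's collective tallies for the
# cohort-wide carrier/dominant/recessive models, and the two of them with an
# assigned VWD type are likewise removed from the per-type models (where the
# MAF > 1% cutoff applies as well).
exclusions:
  global: []
  by_population:
    afr: ["c.6554G>A", "c.2220G>A", "c.2451T>A"]
type_exclusions:
  by_population:
    afr: ["c.2451T>A", "c.6554G>A"]
    all: ["c.2451T>A", "c.6554G>A"]
type_maf_cutoff: 0.01
scale: per100
type_scale: per1000
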