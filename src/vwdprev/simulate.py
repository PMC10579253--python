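"""Synthetic gnomAD-like cohorts with known ground truth.

The generator emulates the input that a population-scale VWF variant
analysis consumes: per-population allele summaries for a mixture of
pathogenic and benign variants, an HGMD/LOVD-style knowledge-base fixture
for the reported subset, and in-silico predictor profiles with configurable
concordance with true pathogenicity.

Defaults encode the study conditions of a gnomAD v2.1 VWF analysis:

* population sizes — the eight gnomAD strata (141,456 individuals total);
* 4,313 variants of which 505 are pathogenic, 218 of those reported;
* the pathogenic consequence mix (355 missense, 53 frameshift, 40
  stop-gained, 1 stop-lost, 41 splice, 14 inframe indel, 1 synonymous);
* the reported VWD-type mix (78 type 1, 54 type 3, 23 2A, 21 2M, 15 2N,
  12 2B, 15 unclassified);
* ten recurrent reported variants with per-population point-mass true
  frequencies, plus a rare tail in which roughly half of pathogenic
  variants are cohort-wide singletons.

Genotypes are drawn per individual under Hardy–Weinberg equilibrium at the
true allele frequency (dosage 2 with probability q², 1 with 2q(1-q)), and
tallied into ``ac``/``an``/``n_hom`` with ``an = 2·n_individuals``, so
allele-level and individual-level accounting are jointly realizable.

:func:`end_to_end_fixture` builds deterministic, noise-free fixtures whose
aggregated counts equal known published-table totals exactly (planted
counts, no sampling), for table-shaped regression tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from vwdprev.cohort import (
    AlleleCounts,
    Consequence,
    PopulationLabel,
    PredictorProfile,
    SpliceScores,
    VariantKey,
    VariantRecord,
    write_variant_table,
)
from vwdprev.cohort import MISSENSE_TOOLS, SPLICE_TOOLS
from vwdprev.knowledge_base import KnownVariantDB, KnownVariantEntry, write_known_variants

__all__ = [
    "DEFAULT_POPULATIONS",
    "CohortTruth",
    "SimulationSpec",
    "build_fixture",
    "end_to_end_fixture",
    "simulate_cohort",
    "write_population_config",
]

#: gnomAD v2.1 stratum sizes (individuals).
DEFAULT_POPULATIONS = (
    PopulationLabel("afr", "African/African American", 12487),
    PopulationLabel("amr", "Latino/Admixed American", 17720),
    PopulationLabel("asj", "Ashkenazi Jewish", 5185),
    PopulationLabel("eas", "East Asian", 9977),
    PopulationLabel("fin", "European (Finnish)", 12562),
    PopulationLabel("nfe", "European (non-Finnish)", 64603),
    PopulationLabel("sas", "South Asian", 15308),
    PopulationLabel("oth", "Other", 3614),
)

_POP_CODES = tuple(p.code for p in DEFAULT_POPULATIONS)

#: Pathogenic consequence-class counts among the 505-variant reference mix.
PATHOGENIC_CLASS_COUNTS: dict[Consequence, int] = {
    Consequence.MISSENSE: 355,
    Consequence.FRAMESHIFT: 53,
    Consequence.STOP_GAINED: 40,
    Consequence.STOP_LOST: 1,
    Consequence.SPLICE_CORE: 28,
    Consequence.SPLICE_REGION: 13,
    Consequence.INFRAME_INDEL: 14,
    Consequence.SYNONYMOUS: 1,
}

#: VWD-type counts among the 218 reported variants.
REPORTED_TYPE_COUNTS: dict[str, int] = {"1": 78, "3": 54, "2A": 23, "2M": 21, "2N": 15, "2B": 12, "UC": 15}

_INHERITANCE_BY_TYPE = {
    "1": "dominant",
    "2A": "dominant",
    "2B": "dominant",
    "2M": "dominant",
    "2N": "recessive",
    "3": "recessive",
    "UC": "unknown",
}

# (hgvs_c, hgvs_p, consequence, vwd_type, per-population true q) for the ten
# recurrent reported variants; frequencies follow the published MAF grid.
RECURRENT_VARIANTS: tuple[tuple[str, str, Consequence, str, dict[str, float]], ...] = (
    ("c.6554G>A", "p.Arg2185Gln", Consequence.MISSENSE, "1",
     dict(afr=0.1899, amr=0.0106, asj=0.0050, eas=0.0002, fin=0.0001, nfe=0.0013, sas=0.0043, oth=0.0089)),
    ("c.2220G>A", "p.Met740Ile", Consequence.MISSENSE, "UC",
     dict(afr=0.1801, amr=0.0117, asj=0.0043, eas=0.0, fin=0.0, nfe=0.0007, sas=0.0002, oth=0.0076)),
    ("c.6187C>T", "p.Pro2063Ser", Consequence.MISSENSE, "1",
     dict(afr=0.0012, amr=0.0102, asj=0.0250, eas=0.0001, fin=0.0012, nfe=0.0081, sas=0.0485, oth=0.0147)),
    ("c.2451T>A", "p.His817Gln", Consequence.MISSENSE, "2N",
     dict(afr=0.1157, amr=0.0062, asj=0.0, eas=0.0, fin=0.0, nfe=0.0002, sas=0.0002, oth=0.0046)),
    ("c.2771G>A", "p.Arg924Gln", Consequence.MISSENSE, "1",
     dict(afr=0.0032, amr=0.0045, asj=0.0030, eas=0.0001, fin=0.0056, nfe=0.0187, sas=0.0037, oth=0.0115)),
    ("c.1728G>T", "p.Met576Ile", Consequence.MISSENSE, "1",
     dict(afr=0.0002, amr=0.0375, asj=0.0, eas=0.0002, fin=0.0, nfe=0.0002, sas=0.0002, oth=0.0041)),
    ("c.7940C>T", "p.Thr2647Met", Consequence.MISSENSE, "1",
     dict(afr=0.0007, amr=0.0004, asj=0.0019, eas=0.0002, fin=0.0198, nfe=0.0037, sas=0.0003, oth=0.0040)),
    ("c.2900G>A", "p.Gly967Asp", Consequence.MISSENSE, "UC",
     dict(afr=0.0257, amr=0.0016, asj=0.0, eas=0.0, fin=0.0, nfe=0.0001, sas=0.0001, oth=0.0008)),
    ("c.3101_3103del", "p.Thr1034del", Consequence.INFRAME_INDEL, "3",
     dict(afr=0.0152, amr=0.0008, asj=0.0, eas=0.0, fin=0.0, nfe=0.0002, sas=0.0001, oth=0.0004)),
    ("c.5191T>A", "p.Ser1731Thr", Consequence.MISSENSE, "2M",
     dict(afr=0.0001, amr=0.0010, asj=0.0209, eas=0.0, fin=0.0, nfe=0.0011, sas=0.0002, oth=0.0022)),
)

_AA3 = ("Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val")

_BENIGN_CLASS_WEIGHTS: dict[Consequence, float] = {
    Consequence.MISSENSE: 0.45,
    Consequence.SYNONYMOUS: 0.35,
    Consequence.SPLICE_REGION: 0.10,
    Consequence.OTHER: 0.10,
}


def _normalized(weights: Mapping, label: str) -> tuple[list, np.ndarray]:
    keys = list(weights)
    values = np.asarray([float(weights[k]) for k in keys])
    if (values < 0).any() or values.sum() <= 0:
        raise ValueError(f"{label}: weights must be non-negative and sum to a positive value")
    return keys, values / values.sum()


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic cohort (defaults are the study conditions)."""

    populations: tuple[PopulationLabel, ...] = DEFAULT_POPULATIONS
    n_variants: int = 4313
    pathogenic_fraction: float = 505 / 4313
    reported_fraction: float = 218 / 505
    consequence_mix: Mapping[Consequence, float] = field(
        default_factory=lambda: dict(PATHOGENIC_CLASS_COUNTS)
    )
    vwd_type_mix: Mapping[str, float] = field(default_factory=lambda: dict(REPORTED_TYPE_COUNTS))
    recurrent_variants: tuple = RECURRENT_VARIANTS
    singleton_fraction: float = 0.48
    rare_q_range: tuple[float, float] = (1e-5, 2e-3)
    predictor_concordance: float = 1.0
    false_positive_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pathogenic_fraction", "reported_fraction", "singleton_fraction",
                     "predictor_concordance", "false_positive_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        if self.n_variants < 0:
            raise ValueError("n_variants must be >= 0")
        codes = [p.code for p in self.populations]
        if len(codes) != len(set(codes)):
            raise ValueError("population codes must be unique")


@dataclass
class CohortTruth:
    """Simulator ground truth for recovery tests.

    ``genotype_tallies[pop]`` is an (n_variants, 3) array of individual
    counts by alt-allele dosage (0, 1, 2); realized ``ac`` always equals
    ``tallies[:, 1] + 2 * tallies[:, 2]``.
    """

    hgvs_c: list[str]
    true_pathogenic: np.ndarray
    in_db: np.ndarray
    vwd_type: list[Optional[str]]
    true_q: dict[str, np.ndarray]
    genotype_tallies: dict[str, np.ndarray]


def _sample_genotypes(rng: np.random.Generator, n_individuals: int, q: float) -> tuple[int, int, int]:
    """HWE genotype tally (n0, n1, n2) for one variant in one stratum."""
    q = min(max(q, 0.0), 1.0)
    p = 1.0 - q
    n0, n1, n2 = rng.multinomial(n_individuals, [p * p, 2 * p * q, q * q])
    return int(n0), int(n1), int(n2)


def _pathogenic_missense_profile(rng: np.random.Generator, spec: SimulationSpec) -> PredictorProfile:
    calls = {
        tool: "deleterious" if rng.random() < spec.predictor_concordance else "tolerated"
        for tool in MISSENSE_TOOLS
    }
    cadd = rng.uniform(20, 40) if rng.random() < spec.predictor_concordance else rng.uniform(0, 20)
    return PredictorProfile(cadd_phred=float(cadd), missense_calls=calls)


def _benign_missense_profile(rng: np.random.Generator, spec: SimulationSpec) -> PredictorProfile:
    calls = {
        tool: "deleterious" if rng.random() < spec.false_positive_rate else "tolerated"
        for tool in MISSENSE_TOOLS
    }
    cadd = rng.uniform(20, 40) if rng.random() < spec.false_positive_rate else rng.uniform(0, 20)
    return PredictorProfile(cadd_phred=float(cadd), missense_calls=calls)


def _splice_profile(rng: np.random.Generator, deleterious_prob: float) -> PredictorProfile:
    scores = {}
    for tool in SPLICE_TOOLS:
        wt = float(rng.uniform(4, 12))
        if rng.random() < deleterious_prob:
            if rng.random() < 0.5:
                scores[tool] = SpliceScores(wild_type=wt, variant=0.0, site_abolished=True)
            else:
                scores[tool] = SpliceScores(wild_type=wt, variant=wt * float(rng.uniform(0.0, 0.45)), site_abolished=False)
        else:
            scores[tool] = SpliceScores(wild_type=wt, variant=wt * float(rng.uniform(0.6, 1.0)), site_abolished=False)
    cadd = rng.uniform(20, 40) if rng.random() < deleterious_prob else rng.uniform(0, 20)
    return PredictorProfile(cadd_phred=float(cadd), splice_scores=scores)


def _hgvs_for(rng: np.random.Generator, index: int, consequence: Consequence) -> tuple[VariantKey, str, Optional[str], Optional[int]]:
    """Plumbing identifiers: a unique genomic key, c./p. strings, intronic offset."""
    pos = 6_060_000 + 10 * index
    aa = int(rng.integers(23, 2814))
    ref, alt = ("G", "A") if rng.random() < 0.5 else ("C", "T")
    # generated cDNA coordinates start beyond the recurrent variants' real
    # coordinates so synthetic hgvs_c strings never collide with them
    cpos = 10_000 + 3 * index
    intronic_offset = None
    hgvs_p: Optional[str] = None
    if consequence in (Consequence.FRAMESHIFT, Consequence.INFRAME_INDEL):
        key = VariantKey("12", pos, ref + "CA", ref)
        hgvs_c = f"c.{cpos}_{cpos + 1}del"
        hgvs_p = f"p.{_AA3[int(rng.integers(len(_AA3)))]}{aa}del"
    else:
        key = VariantKey("12", pos, ref, alt)
        hgvs_c = f"c.{cpos}{ref}>{alt}"
    if consequence is Consequence.MISSENSE:
        a, b = rng.choice(len(_AA3), size=2, replace=False)
        hgvs_p = f"p.{_AA3[a]}{aa}{_AA3[b]}"
    elif consequence is Consequence.STOP_GAINED:
        hgvs_p = f"p.{_AA3[int(rng.integers(len(_AA3)))]}{aa}Ter"
    elif consequence is Consequence.STOP_LOST:
        hgvs_p = f"p.Ter2813{_AA3[int(rng.integers(len(_AA3)))]}"
    elif consequence is Consequence.SPLICE_CORE:
        offset = int(rng.choice([-2, -1, 1, 2]))
        hgvs_c = f"c.{cpos}{'+' if offset > 0 else ''}{offset}{ref}>{alt}"
        intronic_offset = offset
    elif consequence is Consequence.SPLICE_REGION:
        offset = int(rng.choice([-8, -7, -6, -5, -4, -3, 3, 4, 5, 6, 7, 8]))
        hgvs_c = f"c.{cpos}{'+' if offset > 0 else ''}{offset}{ref}>{alt}"
        intronic_offset = offset
    return key, hgvs_c, hgvs_p, intronic_offset


def simulate_cohort(spec: SimulationSpec) -> tuple[list[VariantRecord], KnownVariantDB, CohortTruth]:
    """Draw one synthetic cohort; deterministic for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_variants
    n_recurrent = min(len(spec.recurrent_variants), n_total)
    n_pathogenic = max(int(round(n_total * spec.pathogenic_fraction)), n_recurrent)
    n_pathogenic = min(n_pathogenic, n_total)
    n_reported = min(int(round(n_pathogenic * spec.reported_fraction)), n_pathogenic)
    n_reported = max(n_reported, n_recurrent)
    n_tail = n_pathogenic - n_recurrent
    n_benign = n_total - n_pathogenic

    class_keys, class_p = _normalized(spec.consequence_mix, "consequence_mix")
    type_keys, type_p = _normalized(spec.vwd_type_mix, "vwd_type_mix")
    benign_keys, benign_p = _normalized(_BENIGN_CLASS_WEIGHTS, "benign_mix")

    n_individuals_total = sum(p.n_individuals for p in spec.populations)
    singleton_q = 1.0 / (2 * n_individuals_total) if n_individuals_total else 0.0
    lo, hi = spec.rare_q_range

    plan: list[dict] = []
    # Recurrent reported point-mass variants.
    for hgvs_c, hgvs_p, consequence, vwd_type, freqs in spec.recurrent_variants[:n_recurrent]:
        plan.append(
            dict(hgvs_c=hgvs_c, hgvs_p=hgvs_p, consequence=consequence, pathogenic=True,
                 reported=True, vwd_type=vwd_type, q={p.code: freqs.get(p.code, 0.0) for p in spec.populations})
        )
    # Rare pathogenic tail.
    tail_classes = [class_keys[i] for i in rng.choice(len(class_keys), size=n_tail, p=class_p)]
    reported_flags = np.zeros(n_tail, dtype=bool)
    n_tail_reported = max(n_reported - n_recurrent, 0)
    if n_tail:
        # Knowledge-base membership is the only pathogenicity route for
        # synonymous variants, so those are forced into the reported subset.
        forced = [i for i, c in enumerate(tail_classes) if c is Consequence.SYNONYMOUS]
        reported_flags[forced[:n_tail_reported]] = True
        remaining = [i for i in range(n_tail) if not reported_flags[i]]
        extra = n_tail_reported - int(reported_flags.sum())
        if extra > 0:
            chosen = rng.choice(len(remaining), size=min(extra, len(remaining)), replace=False)
            for j in np.atleast_1d(chosen):
                reported_flags[remaining[int(j)]] = True
    for i in range(n_tail):
        is_singleton = rng.random() < spec.singleton_fraction
        q = singleton_q if is_singleton else float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        vwd_type = type_keys[int(rng.choice(len(type_keys), p=type_p))] if reported_flags[i] else None
        plan.append(
            dict(hgvs_c=None, hgvs_p=None, consequence=tail_classes[i], pathogenic=True,
                 reported=bool(reported_flags[i]), vwd_type=vwd_type,
                 q={p.code: q for p in spec.populations})
        )
    # Benign background.
    benign_classes = [benign_keys[i] for i in rng.choice(len(benign_keys), size=n_benign, p=benign_p)]
    for consequence in benign_classes:
        q = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        plan.append(
            dict(hgvs_c=None, hgvs_p=None, consequence=consequence, pathogenic=False,
                 reported=False, vwd_type=None, q={p.code: q for p in spec.populations})
        )

    records: list[VariantRecord] = []
    db_entries: list[KnownVariantEntry] = []
    truth = CohortTruth(
        hgvs_c=[],
        true_pathogenic=np.zeros(len(plan), dtype=bool),
        in_db=np.zeros(len(plan), dtype=bool),
        vwd_type=[],
        true_q={p.code: np.zeros(len(plan)) for p in spec.populations},
        genotype_tallies={p.code: np.zeros((len(plan), 3), dtype=np.int64) for p in spec.populations},
    )

    for index, item in enumerate(plan):
        consequence: Consequence = item["consequence"]
        key, hgvs_c, hgvs_p, offset = _hgvs_for(rng, index, consequence)
        if item["hgvs_c"] is not None:
            hgvs_c, hgvs_p = item["hgvs_c"], item["hgvs_p"]
        # Predictor profile by class and true status.
        if consequence is Consequence.MISSENSE:
            profile = (
                _pathogenic_missense_profile(rng, spec) if item["pathogenic"]
                else _benign_missense_profile(rng, spec)
            )
        elif consequence is Consequence.SPLICE_REGION:
            profile = _splice_profile(
                rng, spec.predictor_concordance if item["pathogenic"] else spec.false_positive_rate
            )
        else:
            profile = PredictorProfile(cadd_phred=float(rng.uniform(0, 40)))
        counts = {}
        for pop in spec.populations:
            q = item["q"][pop.code]
            n0, n1, n2 = _sample_genotypes(rng, pop.n_individuals, q)
            counts[pop.code] = AlleleCounts(ac=n1 + 2 * n2, an=pop.an_ref, n_hom=n2)
            truth.true_q[pop.code][index] = q
            truth.genotype_tallies[pop.code][index] = (n0, n1, n2)
        records.append(
            VariantRecord(
                key=key,
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                rsid=None,
                consequence=consequence,
                intronic_offset=offset,
                predictors=profile,
                counts=counts,
                mean_depth=float(rng.uniform(25, 60)),
            )
        )
        truth.hgvs_c.append(hgvs_c)
        truth.true_pathogenic[index] = item["pathogenic"]
        truth.in_db[index] = item["reported"]
        truth.vwd_type.append(item["vwd_type"])
        if item["reported"]:
            source = ("HGMD", "LOVD", "HGMD;LOVD")[int(rng.integers(3))]
            db_entries.append(
                KnownVariantEntry(
                    hgvs_c=hgvs_c,
                    vwd_type=item["vwd_type"],
                    inheritance=_INHERITANCE_BY_TYPE[item["vwd_type"]],
                    sources=frozenset(source.split(";")),
                    clear_association=True,
                    key=key,
                )
            )
    return records, KnownVariantDB.from_entries(db_entries), truth


# ---------------------------------------------------------------------------
# Named deterministic fixtures (planted counts, no sampling noise)
# ---------------------------------------------------------------------------

# Per-population affected-allele plan: (reported bulk, novel bulk) counts,
# reproducing the published per-stratum affected-allele table; the African
# stratum additionally carries the three common variants (type 1 / UC / 2N)
# that the headline estimates exclude.
_TABLE_COUNTS: dict[str, tuple[int, int]] = {
    "afr": (2144, 222),   # + 4743 + 4497 + 2852 common-variant alleles = 14458 total
    "amr": (3530, 143),
    "asj": (820, 26),
    "eas": (443, 103),
    "fin": (1222, 16),
    "nfe": (7282, 291),
    "sas": (2725, 115),
    "oth": (592, 19),
}

_AFR_COMMON = (
    ("c.6554G>A", "p.Arg2185Gln", "1", 4743),
    ("c.2220G>A", "p.Met740Ile", "UC", 4497),
    ("c.2451T>A", "p.His817Gln", "2N", 2852),
)

FIXTURE_NAMES = ("table4_populations", "fig1_mix", "fig2_types", "table3_finnish", "table6_common")


def _zero_counts(populations: Sequence[PopulationLabel]) -> dict[str, AlleleCounts]:
    return {p.code: AlleleCounts(ac=0, an=p.an_ref, n_hom=0) for p in populations}


def _full_missense_profile() -> PredictorProfile:
    return PredictorProfile(cadd_phred=28.0, missense_calls={t: "deleterious" for t in MISSENSE_TOOLS})


def _full_splice_profile() -> PredictorProfile:
    return PredictorProfile(
        cadd_phred=26.0,
        splice_scores={t: SpliceScores(wild_type=8.0, variant=0.0, site_abolished=True) for t in SPLICE_TOOLS},
    )


def _plain_record(
    index: int,
    consequence: Consequence,
    populations: Sequence[PopulationLabel],
    ac: Mapping[str, int] = {},
    hgvs_c: Optional[str] = None,
    hgvs_p: Optional[str] = None,
    aa: int = 1000,
    supported: bool = True,
) -> VariantRecord:
    pos = 6_060_000 + 10 * index
    if consequence in (Consequence.FRAMESHIFT, Consequence.INFRAME_INDEL):
        key = VariantKey("12", pos, "GCA", "G")
        default_c = f"c.{100 + 3 * index}_{101 + 3 * index}del"
        default_p = f"p.Thr{aa}del"
    else:
        key = VariantKey("12", pos, "G", "A")
        default_c = f"c.{100 + 3 * index}G>A"
        default_p = f"p.Arg{aa}Gln"
    offset = None
    if consequence is Consequence.SPLICE_CORE:
        offset, default_p = 2, None
    elif consequence is Consequence.SPLICE_REGION:
        offset, default_p = 5, None
    elif consequence is Consequence.SYNONYMOUS:
        default_p = None
    elif consequence is Consequence.STOP_GAINED:
        default_p = f"p.Arg{aa}Ter"
    elif consequence is Consequence.STOP_LOST:
        default_p = f"p.Ter2813Arg"
    profile = PredictorProfile()
    if supported:
        if consequence is Consequence.MISSENSE:
            profile = _full_missense_profile()
        elif consequence is Consequence.SPLICE_REGION:
            profile = _full_splice_profile()
    counts = {
        p.code: AlleleCounts(ac=int(ac.get(p.code, 0)), an=p.an_ref, n_hom=0) for p in populations
    }
    return VariantRecord(
        key=key,
        hgvs_c=hgvs_c or default_c,
        hgvs_p=hgvs_p if hgvs_p is not None else default_p,
        consequence=consequence,
        intronic_offset=offset,
        predictors=profile,
        counts=counts,
        mean_depth=35.0,
    )


def _entry(record: VariantRecord, vwd_type: str) -> KnownVariantEntry:
    return KnownVariantEntry(
        hgvs_c=record.hgvs_c,
        vwd_type=vwd_type,
        inheritance=_INHERITANCE_BY_TYPE[vwd_type],
        sources=frozenset({"HGMD", "LOVD"}),
        clear_association=True,
        key=record.key,
    )


def _fixture_table4(populations: Sequence[PopulationLabel]):
    records: list[VariantRecord] = []
    entries: list[KnownVariantEntry] = []
    index = 0
    for hgvs_c, hgvs_p, vwd_type, ac in _AFR_COMMON:
        rec = _plain_record(index, Consequence.MISSENSE, populations, ac={"afr": ac},
                            hgvs_c=hgvs_c, hgvs_p=hgvs_p, aa=800 + index)
        records.append(rec)
        entries.append(_entry(rec, vwd_type))
        index += 1
    for pop in populations:
        reported_ac, novel_ac = _TABLE_COUNTS[pop.code]
        rec = _plain_record(index, Consequence.MISSENSE, populations, ac={pop.code: reported_ac}, aa=1200 + index)
        records.append(rec)
        entries.append(_entry(rec, "1"))
        index += 1
        records.append(_plain_record(index, Consequence.FRAMESHIFT, populations, ac={pop.code: novel_ac}, aa=1600 + index))
        index += 1
    return records, entries


def _fixture_fig1(populations: Sequence[PopulationLabel]):
    records: list[VariantRecord] = []
    entries: list[KnownVariantEntry] = []
    type_cycle = [t for t, n in REPORTED_TYPE_COUNTS.items() for _ in range(n)]
    index = 0
    n_reported = 0
    # The single pathogenic synonymous variant is only admissible via the
    # knowledge base, so it is placed in the reported subset first.
    ordered = [Consequence.SYNONYMOUS] + [
        c for c, n in PATHOGENIC_CLASS_COUNTS.items() for _ in range(n if c is not Consequence.SYNONYMOUS else 0)
    ]
    for consequence in ordered:
        ac = {"nfe": 1}
        rec = _plain_record(index, consequence, populations, ac=ac, aa=23 + (index % 2791))
        records.append(rec)
        if n_reported < len(type_cycle):
            entries.append(_entry(rec, type_cycle[n_reported]))
            n_reported += 1
        index += 1
    return records, entries


def _fixture_fig2(populations: Sequence[PopulationLabel]):
    records: list[VariantRecord] = []
    entries: list[KnownVariantEntry] = []
    index = 0
    for vwd_type, n in REPORTED_TYPE_COUNTS.items():
        for _ in range(n):
            rec = _plain_record(index, Consequence.MISSENSE, populations, ac={"nfe": 1}, aa=23 + (index * 12) % 2791)
            records.append(rec)
            entries.append(_entry(rec, vwd_type))
            index += 1
    return records, entries


_FINNISH_TOP5 = (
    ("c.7940C>T", "p.Thr2647Met", "1", 19783),
    ("c.2561G>A", "p.Arg854Gln", "2N", 5692),
    ("c.2771G>A", "p.Arg924Gln", "1", 5573),
    ("c.4315G>A", "p.Val1439Met", "2M", 4857),
    ("c.3797C>T", "p.Pro1266Leu", "2B", 3667),
)


def _fixture_table3_finnish(_populations):
    # One large synthetic stratum with an = 10^6 so the planted allele
    # counts reproduce the published 6-decimal MAFs exactly.
    populations = (PopulationLabel("fin", "European (Finnish)", 500_000),)
    records: list[VariantRecord] = []
    entries: list[KnownVariantEntry] = []
    for index, (hgvs_c, hgvs_p, vwd_type, ac) in enumerate(_FINNISH_TOP5):
        rec = _plain_record(index, Consequence.MISSENSE, populations, ac={"fin": ac},
                            hgvs_c=hgvs_c, hgvs_p=hgvs_p, aa=854 + index)
        records.append(rec)
        entries.append(_entry(rec, vwd_type))
    return records, entries, populations


def _fixture_table6(populations: Sequence[PopulationLabel]):
    records: list[VariantRecord] = []
    entries: list[KnownVariantEntry] = []
    pop_by_code = {p.code: p for p in populations}
    for index, (hgvs_c, hgvs_p, consequence, vwd_type, freqs) in enumerate(RECURRENT_VARIANTS):
        ac = {code: int(round(freqs.get(code, 0.0) * pop_by_code[code].an_ref)) for code in pop_by_code}
        rec = _plain_record(index, consequence, populations, ac=ac, hgvs_c=hgvs_c, hgvs_p=hgvs_p, aa=576 + index)
        records.append(rec)
        entries.append(_entry(rec, vwd_type))
    return records, entries


def build_fixture(name: str):
    """Build a named deterministic fixture in memory.

    Returns ``(records, db_entries, populations)``.  Raises ValueError on
    unknown names, listing the available fixtures.
    """
    populations = DEFAULT_POPULATIONS
    if name == "table4_populations":
        records, entries = _fixture_table4(populations)
    elif name == "fig1_mix":
        records, entries = _fixture_fig1(populations)
    elif name == "fig2_types":
        records, entries = _fixture_fig2(populations)
    elif name == "table3_finnish":
        records, entries, populations = _fixture_table3_finnish(populations)
    elif name == "table6_common":
        records, entries = _fixture_table6(populations)
    else:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return records, entries, populations


def write_population_config(populations: Sequence[PopulationLabel], path: str) -> None:
    payload = {
        "populations": [
            {"code": p.code, "name": p.display_name, "n_individuals": p.n_individuals} for p in populations
        ]
    }
    with open(path, "w") as handle:
        yaml.safe_dump(payload, handle, sort_keys=False)


def end_to_end_fixture(name: str, out_dir: str, dialect: str = "tsv") -> dict[str, str]:
    """Write a named fixture to disk (variant table, knowledge base, populations)."""
    records, entries, populations = build_fixture(name)
    os.makedirs(out_dir, exist_ok=True)
    ext = "vcf" if dialect == "vcf" else "tsv"
    paths = {
        "variants": os.path.join(out_dir, f"{name}.variants.{ext}"),
        "known_db": os.path.join(out_dir, f"{name}.known_db.tsv"),
        "populations": os.path.join(out_dir, f"{name}.populations.yaml"),
    }
    write_variant_table(records, paths["variants"], dialect=dialect, populations=populations)
    write_known_variants(entries, paths["known_db"])
    write_population_config(populations, paths["populations"])
    return paths
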