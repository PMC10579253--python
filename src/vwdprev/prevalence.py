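"""Hardy–Weinberg prevalence models for dominant, recessive and compound VWD.

Let q be the collective frequency of pathogenic VWF alleles in a population
and p = 1 - q.  Under Hardy–Weinberg equilibrium (p² + 2pq + q² = 1):

* carrier frequency  ≈ 2q      (allele-counting approximation of carriership),
* dominant prevalence = 2pq    (heterozygote genotype frequency),
* recessive prevalence = q²    (homozygote genotype frequency),
* compound-recessive prevalence = q_primary² + 2·q_primary·q_null
  (homozygous for the primary class, or compound heterozygous with a null
  allele) — used for type 2N VWD, whose phenotype arises from 2N/2N or
  2N/null (type 1 or 3) genotypes,
* pooled recessive prevalence = (Σ q_i)² — used for type 3 VWD, pooling
  type 3 with type 1 alleles into one recessive allele class.

Two q conventions coexist, mirroring the two table styles of gnomAD-scale
prevalence work: cohort-wide collective q divides summed affected allele
counts by the fixed stratum denominator an_ref = 2·n_individuals, whereas
type-specific q sums per-variant MAFs (each with its own genotyped an).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from vwdprev.cohort import PopulationLabel, VariantRecord
from vwdprev.knowledge_base import normalize_hgvs
from vwdprev.pathogenicity import ClassificationResult

__all__ = [
    "CollectiveFrequency",
    "PrevalenceConfig",
    "PrevalenceEstimate",
    "carrier_frequency",
    "cohort_collective_q",
    "collective_q",
    "compound_recessive_prevalence",
    "dominant_prevalence",
    "pooled_recessive_prevalence",
    "prevalence_report",
    "recessive_prevalence",
    "type_specific_q",
]

_SCALE_FACTORS = {"unit": 1.0, "per100": 100.0, "per1000": 1000.0}


@dataclass(frozen=True)
class CollectiveFrequency:
    """Collective frequency q of affected alleles in one population."""

    population: str
    q: float
    numerator_ac: Optional[int] = None
    denominator_an: Optional[int] = None
    variant_set_id: str = ""
    exclusions: tuple[str, ...] = ()
    maf_cutoff_applied: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must be in [0,1], got {self.q}")


def collective_q(ac_total: int, an_total: int, population: str = "all", variant_set_id: str = "") -> CollectiveFrequency:
    """q = ac_total / an_total with the counts recorded for audit."""
    if an_total <= 0:
        raise ValueError("an_total must be > 0")
    if not 0 <= ac_total <= an_total:
        raise ValueError(f"require 0 <= ac_total <= an_total, got {ac_total}/{an_total}")
    return CollectiveFrequency(
        population=population,
        q=ac_total / an_total,
        numerator_ac=ac_total,
        denominator_an=an_total,
        variant_set_id=variant_set_id,
    )


def _check_q(q: float) -> float:
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0,1], got {q}")
    return q


def carrier_frequency(q: float) -> float:
    """Allele-counting carrier frequency 2q.

    Exceeds 1 for q > 0.5 — at that point it is no longer a probability but
    the expected pathogenic-allele dosage per individual.
    """
    return 2.0 * _check_q(q)


def dominant_prevalence(q: float) -> float:
    """Heterozygote genotype frequency 2pq = 2q(1-q)."""
    q = _check_q(q)
    return 2.0 * q * (1.0 - q)


def recessive_prevalence(q: float) -> float:
    """Homozygote genotype frequency q²."""
    return _check_q(q) ** 2


def compound_recessive_prevalence(q_primary: float, q_null: float) -> float:
    """q_primary² + 2·q_primary·q_null (homozygous or compound with a null allele)."""
    q_primary, q_null = _check_q(q_primary), _check_q(q_null)
    if q_primary + q_null > 1.0:
        raise ValueError(f"q_primary + q_null must be <= 1, got {q_primary + q_null}")
    return q_primary**2 + 2.0 * q_primary * q_null


def pooled_recessive_prevalence(q_components: Sequence[float]) -> float:
    """(Σ q_i)² — all components pooled into one recessive allele class."""
    q_pool = sum(_check_q(q) for q in q_components)
    if q_pool > 1.0:
        raise ValueError(f"sum of components must be <= 1, got {q_pool}")
    return q_pool**2


# ---------------------------------------------------------------------------
# Collective frequencies from classified cohorts
# ---------------------------------------------------------------------------


def _excluded_set(
    population: str,
    exclusions_global: Sequence[str],
    exclusions_by_population: Mapping[str, Sequence[str]],
) -> frozenset[str]:
    merged = list(exclusions_global) + list(exclusions_by_population.get(population, ()))
    return frozenset(normalize_hgvs(h) for h in merged)


def cohort_collective_q(
    records: Sequence[VariantRecord],
    results: Sequence[ClassificationResult],
    populations: Sequence[PopulationLabel],
    reported_only: bool = False,
    exclusions_global: Sequence[str] = (),
    exclusions_by_population: Mapping[str, Sequence[str]] = {},
) -> dict[str, CollectiveFrequency]:
    """Cohort-wide collective q per population, plus an ``all`` entry.

    The numerator sums allele counts of pathogenic variants (optionally
    restricted to reported variants) after removing excluded variants; the
    denominator is the fixed an_ref = 2·n_individuals of the stratum.
    Exclusion lists are applied per population, so a variant excluded in
    one stratum still contributes to the others; the ``all`` entry sums the
    per-population numerators and denominators.
    """
    if len(records) != len(results):
        raise ValueError("records and results length mismatch")
    out: dict[str, CollectiveFrequency] = {}
    total_ac = 0
    total_an = 0
    set_id = "reported" if reported_only else "all_pathogenic"
    for pop in populations:
        excluded = _excluded_set(pop.code, exclusions_global, exclusions_by_population)
        dropped: list[str] = []
        ac = 0
        for rec, res in zip(records, results):
            if not res.pathogenic:
                continue
            if reported_only and res.status != "reported":
                continue
            if normalize_hgvs(rec.hgvs_c) in excluded:
                if rec.allele_counts(pop.code).ac > 0:
                    dropped.append(rec.hgvs_c)
                continue
            ac += rec.allele_counts(pop.code).ac
        out[pop.code] = CollectiveFrequency(
            population=pop.code,
            q=ac / pop.an_ref if pop.an_ref else 0.0,
            numerator_ac=ac,
            denominator_an=pop.an_ref,
            variant_set_id=set_id,
            exclusions=tuple(dropped),
        )
        total_ac += ac
        total_an += pop.an_ref
    out["all"] = CollectiveFrequency(
        population="all",
        q=total_ac / total_an if total_an else 0.0,
        numerator_ac=total_ac,
        denominator_an=total_an,
        variant_set_id=set_id,
        exclusions=tuple(sorted({h for cf in out.values() for h in cf.exclusions})),
    )
    return out


def type_specific_q(
    records: Sequence[VariantRecord],
    results: Sequence[ClassificationResult],
    population: Union[str, PopulationLabel],
    vwd_types: Sequence[str],
    reported_only: bool = True,
    maf_cutoff: Optional[float] = None,
    exclusions: Sequence[str] = (),
) -> CollectiveFrequency:
    """Collective q for a set of VWD types, as a sum of per-variant MAFs.

    ``population`` may be a stratum code or ``"all"`` (pooled counts over
    every stratum on the records).  Variants named in ``exclusions`` and —
    when ``maf_cutoff`` is set — variants whose MAF in this population
    strictly exceeds the cutoff are dropped; every dropped variant appears
    in the audit ``exclusions`` tuple of the result.
    """
    if not vwd_types:
        raise ValueError("vwd_types must be non-empty")
    code = population.code if isinstance(population, PopulationLabel) else population
    excluded_names = frozenset(normalize_hgvs(h) for h in exclusions)
    wanted = frozenset(vwd_types)
    q = 0.0
    dropped: list[str] = []
    for rec, res in zip(records, results):
        if not res.pathogenic or res.vwd_type not in wanted:
            continue
        if reported_only and res.status != "reported":
            continue
        counts = rec.pooled_counts() if code == "all" else rec.allele_counts(code)
        if counts.an == 0:
            continue
        maf = counts.ac / counts.an
        if normalize_hgvs(rec.hgvs_c) in excluded_names:
            if counts.ac > 0:
                dropped.append(rec.hgvs_c)
            continue
        if maf_cutoff is not None and maf > maf_cutoff:
            dropped.append(rec.hgvs_c)
            continue
        q += maf
    return CollectiveFrequency(
        population=code,
        q=min(q, 1.0),
        variant_set_id="types:" + "+".join(sorted(wanted)),
        exclusions=tuple(dropped),
        maf_cutoff_applied=maf_cutoff,
    )


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrevalenceEstimate:
    """One prevalence figure with its model, inputs and audit trail."""

    population: str
    model: str  # carrier_2q | dominant_2pq | recessive_q2 | recessive_compound
    value: float
    scale: str
    q_inputs: tuple[CollectiveFrequency, ...]
    label: str = ""

    @property
    def exclusions(self) -> tuple[str, ...]:
        return tuple(h for cf in self.q_inputs for h in cf.exclusions)


@dataclass(frozen=True)
class PrevalenceConfig:
    """Study-level configuration for the prevalence report.

    ``exclusions_by_population`` removes named variants (hgvs_c) from a
    stratum's collective tally — e.g. common African/African-American
    variants whose penetrance is doubtful.  ``type_maf_cutoff`` drops
    variants above the given MAF from the per-type models (default 1%).
    """

    exclusions_global: tuple[str, ...] = ()
    exclusions_by_population: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    type_exclusions_by_population: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    type_maf_cutoff: Optional[float] = 0.01
    include_uc_in_types: bool = False
    dominant_types: tuple[str, ...] = ("1", "2A", "2B", "2M")
    scale: str = "per100"
    type_scale: str = "per1000"

    def __post_init__(self) -> None:
        for scale in (self.scale, self.type_scale):
            if scale not in _SCALE_FACTORS:
                raise ValueError(f"unknown scale {scale!r}; expected one of {sorted(_SCALE_FACTORS)}")


def _scaled(value: float, scale: str) -> float:
    return value * _SCALE_FACTORS[scale]


def prevalence_report(
    records: Sequence[VariantRecord],
    results: Sequence[ClassificationResult],
    populations: Sequence[PopulationLabel],
    config: PrevalenceConfig = PrevalenceConfig(),
) -> list[PrevalenceEstimate]:
    """Full prevalence grid over populations, models and VWD types.

    Produces, per population and for the pooled cohort:

    * carrier (2q), dominant (2pq) and recessive (q²) estimates under two
      variant-set approaches — every pathogenic variant, and reported
      variants only;
    * per-type dominant estimates (types 1, 2A, 2B, 2M as 2pq);
    * the type 2N compound-recessive estimate (2N alleles homozygous or
      compound with a type 1/3 null allele);
    * the type 3 pooled-recessive estimate ((q₃ + q₁)²).

    Per-type models use reported variants only (only those carry a VWD
    type), apply the MAF cutoff and honour the per-population type
    exclusion lists.
    """
    estimates: list[PrevalenceEstimate] = []
    pop_codes = [p.code for p in populations] + ["all"]

    for reported_only, approach in ((False, "all_variants"), (True, "reported_only")):
        qs = cohort_collective_q(
            records,
            results,
            populations,
            reported_only=reported_only,
            exclusions_global=config.exclusions_global,
            exclusions_by_population=config.exclusions_by_population,
        )
        for code in pop_codes:
            cf = qs[code]
            for model, fn in (
                ("carrier_2q", carrier_frequency),
                ("dominant_2pq", dominant_prevalence),
                ("recessive_q2", recessive_prevalence),
            ):
                estimates.append(
                    PrevalenceEstimate(
                        population=code,
                        model=model,
                        value=_scaled(fn(cf.q), config.scale),
                        scale=config.scale,
                        q_inputs=(cf,),
                        label=approach,
                    )
                )

    null_types = ["1", "3"]
    if config.include_uc_in_types:
        null_types.append("UC")
    for code in pop_codes:
        exclusions = list(config.exclusions_global) + list(config.type_exclusions_by_population.get(code, ()))

        def q_of(types: Sequence[str]) -> CollectiveFrequency:
            return type_specific_q(
                records,
                results,
                code,
                types,
                reported_only=True,
                maf_cutoff=config.type_maf_cutoff,
                exclusions=exclusions,
            )

        for vwd_type in config.dominant_types:
            cf = q_of([vwd_type])
            estimates.append(
                PrevalenceEstimate(
                    population=code,
                    model="dominant_2pq",
                    value=_scaled(dominant_prevalence(cf.q), config.type_scale),
                    scale=config.type_scale,
                    q_inputs=(cf,),
                    label=f"type_{vwd_type}",
                )
            )
        q_2n = q_of(["2N"])
        q_null = q_of(null_types)
        estimates.append(
            PrevalenceEstimate(
                population=code,
                model="recessive_compound",
                value=_scaled(compound_recessive_prevalence(q_2n.q, q_null.q), config.type_scale),
                scale=config.type_scale,
                q_inputs=(q_2n, q_null),
                label="type_2N",
            )
        )
        q_3 = q_of(["3"])
        q_1 = q_of(["1"])
        estimates.append(
            PrevalenceEstimate(
                population=code,
                model="recessive_q2",
                value=_scaled(pooled_recessive_prevalence([q_3.q, q_1.q]), config.type_scale),
                scale=config.type_scale,
                q_inputs=(q_3, q_1),
                label="type_3",
            )
        )
    return estimates


def report_frame(estimates: Sequence[PrevalenceEstimate]) -> pd.DataFrame:
    """Flatten estimates into a tidy DataFrame for rendering or export."""
    rows = []
    for est in estimates:
        rows.append(
            {
                "population": est.population,
                "label": est.label,
                "model": est.model,
                "value": est.value,
                "scale": est.scale,
                "q": est.q_inputs[0].q if len(est.q_inputs) == 1 else None,
                "n_excluded": len(est.exclusions),
                "excluded": ";".join(est.exclusions),
            }
        )
    return pd.DataFrame(rows)
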