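"""Per-population aggregation of classified variants.

All tallies here are allele-level: an individual carrying two distinct
pathogenic variants contributes two affected alleles.  Two denominator
conventions coexist deliberately: the affected-allele table is reported
against the fixed stratum denominator ``an_ref = 2 * n_individuals``
(gnomAD-style "total number of alleles"), while per-variant MAF uses the
variant's own genotyped allele number ``an``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import pandas as pd

from vwdprev.cohort import PopulationLabel, VariantRecord
from vwdprev.pathogenicity import ClassificationResult

__all__ = [
    "HomozygoteCensus",
    "affected_alleles",
    "common_variant_flags",
    "homozygote_census",
    "top_variants",
    "variant_maf",
]


def _pop_code(population: Union[str, PopulationLabel]) -> str:
    return population.code if isinstance(population, PopulationLabel) else population


def variant_maf(record: VariantRecord, population: Union[str, PopulationLabel]) -> float:
    """Alt-allele frequency ac/an of one variant in one population."""
    counts = record.allele_counts(_pop_code(population))
    if counts.an == 0:
        raise ZeroDivisionError(f"{record.key}: MAF undefined, an=0 in population {_pop_code(population)!r}")
    return counts.ac / counts.an


def pooled_maf(record: VariantRecord) -> float:
    """Alt-allele frequency with counts pooled over all populations."""
    pooled = record.pooled_counts()
    if pooled.an == 0:
        raise ZeroDivisionError(f"{record.key}: MAF undefined, pooled an=0")
    return pooled.ac / pooled.an


def _pathogenic_pairs(
    records: Sequence[VariantRecord],
    results: Sequence[ClassificationResult],
) -> list[tuple[VariantRecord, ClassificationResult]]:
    if len(records) != len(results):
        raise ValueError(f"{len(records)} records but {len(results)} classification results")
    return [(rec, res) for rec, res in zip(records, results) if res.pathogenic]


def affected_alleles(
    records: Sequence[VariantRecord],
    results: Sequence[ClassificationResult],
    populations: Sequence[PopulationLabel],
) -> pd.DataFrame:
    """Per-population affected-allele tallies split by reported/novel status.

    Returns a DataFrame indexed by population code plus a grand-total
    ``all`` row, with columns ``total_affected``, ``affected_reported``,
    ``affected_novel``, ``an_ref`` and ``novel_fraction``
    (= affected_novel / total_affected, 0 when nothing is affected).
    """
    pairs = _pathogenic_pairs(records, results)
    rows = {}
    for pop in populations:
        reported = sum(rec.allele_counts(pop.code).ac for rec, res in pairs if res.status == "reported")
        novel = sum(rec.allele_counts(pop.code).ac for rec, res in pairs if res.status == "novel")
        rows[pop.code] = (reported + novel, reported, novel, pop.an_ref)
    total = tuple(sum(r[i] for r in rows.values()) for i in range(4))
    rows["all"] = total
    table = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["total_affected", "affected_reported", "affected_novel", "an_ref"],
    )
    denom = table["total_affected"].to_numpy()
    with pd.option_context("mode.chained_assignment", None):
        table["novel_fraction"] = [
            novel / total if total else 0.0 for novel, total in zip(table["affected_novel"], denom)
        ]
    table.index.name = "population"
    return table


def top_variants(
    records: Sequence[VariantRecord],
    results: Sequence[ClassificationResult],
    population: Union[str, PopulationLabel],
    k: int = 5,
) -> pd.DataFrame:
    """The k most frequent pathogenic variants in a population.

    Sorted by MAF descending; ties broken by genomic position ascending.
    Variants with an = 0 in the population are skipped (no genotyped
    alleles, MAF undefined).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    code = _pop_code(population)
    rows = []
    for rec, res in _pathogenic_pairs(records, results):
        counts = rec.allele_counts(code)
        if counts.an == 0:
            continue
        rows.append(
            {
                "population": code,
                "hgvs_c": rec.hgvs_c,
                "hgvs_p": rec.hgvs_p,
                "rsid": rec.rsid,
                "consequence": rec.consequence.value,
                "maf": counts.ac / counts.an,
                "vwd_type": res.vwd_type,
                "pos": rec.key.pos,
            }
        )
    frame = pd.DataFrame(rows, columns=["population", "hgvs_c", "hgvs_p", "rsid", "consequence", "maf", "vwd_type", "pos"])
    frame = frame.sort_values(["maf", "pos"], ascending=[False, True], kind="mergesort").head(k)
    return frame.drop(columns="pos").reset_index(drop=True)


def common_variant_flags(
    records: Sequence[VariantRecord],
    populations: Sequence[PopulationLabel],
    threshold: float = 0.01,
) -> dict[str, list[str]]:
    """Variants with MAF strictly above ``threshold`` in at least one population.

    Returns a mapping from hgvs_c to the list of triggering population
    codes (input population order).  MAF exactly at the threshold does not
    flag.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    flags: dict[str, list[str]] = {}
    for rec in records:
        triggering = []
        for pop in populations:
            counts = rec.allele_counts(pop.code)
            if counts.an > 0 and counts.ac / counts.an > threshold:
                triggering.append(pop.code)
        if triggering:
            flags[rec.hgvs_c] = triggering
    return flags


@dataclass(frozen=True)
class HomozygoteCensus:
    """Distinct pathogenic variants observed homozygous, and individual totals."""

    per_population: Mapping[str, tuple[int, int]]
    n_distinct_variants: int
    total_hom_individuals: int


def homozygote_census(
    records: Sequence[VariantRecord],
    results: Sequence[ClassificationResult],
) -> HomozygoteCensus:
    """Census of homozygous-alt individuals over pathogenic variants.

    Per population and overall: the number of distinct pathogenic variants
    with at least one homozygote, and the summed homozygote individual
    count.
    """
    per_pop: dict[str, list[int]] = {}
    overall_variants = 0
    overall_total = 0
    for rec, _res in _pathogenic_pairs(records, results):
        variant_total = 0
        for code, counts in rec.counts.items():
            if counts.n_hom > 0:
                entry = per_pop.setdefault(code, [0, 0])
                entry[0] += 1
                entry[1] += counts.n_hom
                variant_total += counts.n_hom
        if variant_total > 0:
            overall_variants += 1
            overall_total += variant_total
    return HomozygoteCensus(
        per_population={code: (v[0], v[1]) for code, v in per_pop.items()},
        n_distinct_variants=overall_variants,
        total_hom_individuals=overall_total,
    )
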