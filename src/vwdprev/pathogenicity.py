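"""Conservative rule cascade for calling VWF variants deleterious.

A variant is considered pathogenic if the first matching rule, in priority
order, fires:

1. **known_db** — clearly associated with VWD in the HGMD/LOVD knowledge
   base (any consequence class; this is the only route for e.g. a
   synonymous variant).
2. **truncating** — nonsense (stop-gained), frameshift, or inframe
   insertion/deletion; stop-lost is admitted here as a
   stop-codon-affecting class (configurable off).
3. **splice_core** — disruptive splice-site variant in the first/last 2
   intronic nucleotides.
4. **splice_consensus** — splice-region variant (intronic offsets 3..8)
   called deleterious by all splice predictors (Varseak, ESEFinder, BDGP)
   *and* CADD PHRED >= 20.  A tool calls a variant deleterious when it
   abolishes the wild-type splice site or scores it below half the
   wild-type score (strictly).
5. **missense_consensus** — missense variant called deleterious by all six
   categorical predictors (SIFT, PolyPhen2, LRT, MutationTaster,
   MutationAssessor, FATHMM) *and* CADD PHRED >= 20 (the "7 of 7" rule).

Missing predictor values fail closed: a missing call or missing CADD score
can never satisfy a consensus rule.  Pathogenic variants found in the
knowledge base are *reported*; those admitted only by in-silico rules are
*novel*.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from vwdprev.cohort import (
    MISSENSE_TOOLS,
    SPLICE_TOOLS,
    Consequence,
    PredictorProfile,
    VariantRecord,
)
from vwdprev.knowledge_base import KnownVariantDB, KnownVariantEntry, lookup

__all__ = [
    "CascadeConfig",
    "ClassificationResult",
    "CohortSummary",
    "Rule",
    "classify_cohort",
    "classify_variant",
    "missense_consensus_deleterious",
    "splice_consensus_deleterious",
    "splice_tool_deleterious",
]


class Rule(str, Enum):
    KNOWN_DB = "known_db"
    TRUNCATING = "truncating"
    SPLICE_CORE = "splice_core"
    SPLICE_CONSENSUS = "splice_consensus"
    MISSENSE_CONSENSUS = "missense_consensus"
    NONE = "none"


@dataclass(frozen=True)
class CascadeConfig:
    """Tunable parameters of the cascade.

    ``cadd_threshold`` — PHRED-scaled CADD score at or above which CADD is
    counted as a deleterious call (default 20).
    ``admit_stop_lost`` — whether stop-lost variants count as truncating.
    ``required_splice_tools`` — splice predictors that must all concur; the
    default is all three score-pair tools (CADD is always additionally
    required for the splice consensus).
    """

    cadd_threshold: float = 20.0
    admit_stop_lost: bool = True
    required_splice_tools: tuple[str, ...] = SPLICE_TOOLS

    def truncating_classes(self) -> frozenset[Consequence]:
        classes = {Consequence.STOP_GAINED, Consequence.FRAMESHIFT, Consequence.INFRAME_INDEL}
        if self.admit_stop_lost:
            classes.add(Consequence.STOP_LOST)
        return frozenset(classes)


@dataclass(frozen=True)
class ClassificationResult:
    """Verdict for one variant: pathogenic or not, which rule, novel/reported."""

    pathogenic: bool
    rule: Rule
    status: str  # "reported" | "novel" | "not_pathogenic"
    vwd_type: Optional[str] = None
    inheritance: Optional[str] = None
    audit: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.pathogenic == (self.rule is not Rule.NONE)
        assert (self.status == "not_pathogenic") == (not self.pathogenic)


def splice_tool_deleterious(wild_type_score: float, variant_score: float, site_abolished: bool) -> bool:
    """One splice tool's deleterious call.

    True when the variant abolishes the wild-type splice site, or when its
    score drops strictly below half the wild-type score.  A wild-type score
    of 0 can therefore only pass via abolition.
    """
    if wild_type_score < 0 or variant_score < 0:
        raise ValueError("splice scores must be >= 0")
    return site_abolished or variant_score < 0.5 * wild_type_score


def _cadd_deleterious(profile: PredictorProfile, config: CascadeConfig) -> bool:
    return profile.cadd_phred is not None and profile.cadd_phred >= config.cadd_threshold


def splice_consensus_deleterious(profile: PredictorProfile, config: CascadeConfig = CascadeConfig()) -> bool:
    """4-of-4 splice consensus: every splice tool deleterious and CADD >= 20.

    Any missing tool or missing CADD score fails the consensus.
    """
    if not _cadd_deleterious(profile, config):
        return False
    for tool in config.required_splice_tools:
        scores = profile.splice_scores.get(tool)
        if scores is None:
            return False
        if not splice_tool_deleterious(scores.wild_type, scores.variant, scores.site_abolished):
            return False
    return True


def missense_consensus_deleterious(profile: PredictorProfile, config: CascadeConfig = CascadeConfig()) -> bool:
    """7-of-7 missense consensus: six categorical tools deleterious and CADD >= 20."""
    if not _cadd_deleterious(profile, config):
        return False
    return all(profile.missense_call(tool) == "deleterious" for tool in MISSENSE_TOOLS)


def classify_variant(
    record: VariantRecord,
    db: KnownVariantDB,
    config: CascadeConfig = CascadeConfig(),
) -> ClassificationResult:
    """Run the cascade on one variant; first matching rule wins."""
    entry: Optional[KnownVariantEntry] = lookup(db, record)
    checks = {
        Rule.KNOWN_DB: entry is not None,
        Rule.TRUNCATING: record.consequence in config.truncating_classes(),
        Rule.SPLICE_CORE: record.consequence is Consequence.SPLICE_CORE,
        Rule.SPLICE_CONSENSUS: (
            record.consequence is Consequence.SPLICE_REGION
            and splice_consensus_deleterious(record.predictors, config)
        ),
        Rule.MISSENSE_CONSENSUS: (
            record.consequence is Consequence.MISSENSE
            and missense_consensus_deleterious(record.predictors, config)
        ),
    }
    audit = {rule.value: fired for rule, fired in checks.items()}
    rule = next((r for r, fired in checks.items() if fired), Rule.NONE)
    if rule is Rule.NONE:
        return ClassificationResult(pathogenic=False, rule=rule, status="not_pathogenic", audit=audit)
    if entry is not None:
        return ClassificationResult(
            pathogenic=True,
            rule=rule,
            status="reported",
            vwd_type=entry.vwd_type,
            inheritance=entry.inheritance,
            audit=audit,
        )
    return ClassificationResult(pathogenic=True, rule=rule, status="novel", audit=audit)


@dataclass
class CohortSummary:
    """Counts over the pathogenic subset of a classified cohort."""

    n_records: int = 0
    n_pathogenic: int = 0
    n_reported: int = 0
    n_novel: int = 0
    by_rule: Counter = field(default_factory=Counter)
    by_consequence: Counter = field(default_factory=Counter)
    by_vwd_type: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_pathogenic": self.n_pathogenic,
            "n_reported": self.n_reported,
            "n_novel": self.n_novel,
            "by_rule": dict(self.by_rule),
            "by_consequence": dict(self.by_consequence),
            "by_vwd_type": dict(self.by_vwd_type),
        }


def classify_cohort(
    records: Sequence[VariantRecord],
    db: KnownVariantDB,
    config: CascadeConfig = CascadeConfig(),
) -> tuple[list[ClassificationResult], CohortSummary]:
    """Classify every record and summarize the pathogenic subset.

    The consequence and rule distributions are computed over pathogenic
    records only, so ``sum(by_rule.values()) == n_pathogenic`` and
    ``n_reported + n_novel == n_pathogenic``.
    """
    results = [classify_variant(record, db, config) for record in records]
    summary = CohortSummary(n_records=len(records))
    for record, result in zip(records, results):
        if not result.pathogenic:
            continue
        summary.n_pathogenic += 1
        if result.status == "reported":
            summary.n_reported += 1
        else:
            summary.n_novel += 1
        summary.by_rule[result.rule.value] += 1
        summary.by_consequence[record.consequence.value] += 1
        if result.vwd_type is not None:
            summary.by_vwd_type[result.vwd_type] += 1
    return results, summary
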