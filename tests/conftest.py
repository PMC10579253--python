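import pytest

from vwdprev.cohort import (
    MISSENSE_TOOLS,
    SPLICE_TOOLS,
    AlleleCounts,
    Consequence,
    PopulationLabel,
    PredictorProfile,
    SpliceScores,
    VariantKey,
    VariantRecord,
)
from vwdprev.knowledge_base import KnownVariantDB


@pytest.fixture
def pops():
    return (
        PopulationLabel("afr", "African/African American", 100),
        PopulationLabel("nfe", "European (non-Finnish)", 200),
        PopulationLabel("eas", "East Asian", 50),
    )


@pytest.fixture
def empty_db():
    return KnownVariantDB()


def make_record(
    index=0,
    consequence=Consequence.MISSENSE,
    counts=None,
    hgvs_c=None,
    hgvs_p="p.Arg854Gln",
    predictors=None,
    intronic_offset=None,
    mean_depth=35.0,
    rsid=None,
):
    """Small hand-rolled record builder for unit tests."""
    if consequence in (Consequence.SPLICE_CORE, Consequence.SPLICE_REGION):
        hgvs_p = None
        if intronic_offset is None:
            intronic_offset = 2 if consequence is Consequence.SPLICE_CORE else 5
    if consequence in (Consequence.SYNONYMOUS, Consequence.OTHER):
        hgvs_p = None
    return VariantRecord(
        key=VariantKey("12", 6_060_000 + 10 * index, "G", "A"),
        hgvs_c=hgvs_c or f"c.{100 + index}G>A",
        hgvs_p=hgvs_p,
        rsid=rsid,
        consequence=consequence,
        intronic_offset=intronic_offset,
        predictors=predictors or PredictorProfile(),
        counts=counts or {},
        mean_depth=mean_depth,
    )


def consensus_missense_profile(cadd=28.0, n_deleterious=6):
    calls = {}
    for i, tool in enumerate(MISSENSE_TOOLS):
        calls[tool] = "deleterious" if i < n_deleterious else "tolerated"
    return PredictorProfile(cadd_phred=cadd, missense_calls=calls)


def consensus_splice_profile(cadd=26.0, n_pass=3):
    scores = {}
    for i, tool in enumerate(SPLICE_TOOLS):
        if i < n_pass:
            scores[tool] = SpliceScores(wild_type=10.0, variant=0.0, site_abolished=True)
        else:
            scores[tool] = SpliceScores(wild_type=10.0, variant=9.0, site_abolished=False)
    return PredictorProfile(cadd_phred=cadd, splice_scores=scores)


def ac(code_to_ac, pops, an=None):
    """Counts mapping with an defaulting to each population's an_ref."""
    return {
        p.code: AlleleCounts(ac=code_to_ac.get(p.code, 0), an=an or p.an_ref, n_hom=0)
        for p in pops
    }
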