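"""Hardy-Weinberg models, collective frequencies, exclusions, full report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ac, make_record
from vwdprev.cohort import AlleleCounts, Consequence, PopulationLabel
from vwdprev.knowledge_base import KnownVariantDB, KnownVariantEntry
from vwdprev.pathogenicity import classify_cohort
from vwdprev.prevalence import (
    PrevalenceConfig,
    carrier_frequency,
    cohort_collective_q,
    collective_q,
    compound_recessive_prevalence,
    dominant_prevalence,
    pooled_recessive_prevalence,
    prevalence_report,
    recessive_prevalence,
    type_specific_q,
)

qs = st.floats(0.0, 1.0, allow_nan=False)


class TestCollectiveQ:
    def test_reference_totals(self):
        cf = collective_q(19_693, 282_912)
        assert cf.q == pytest.approx(0.0696, abs=5e-5)
        cf_afr = collective_q(2_366, 24_974)
        assert cf_afr.q == pytest.approx(0.0947, abs=5e-5)

    def test_zero_numerator(self):
        assert collective_q(0, 1000).q == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            collective_q(5, 0)
        with pytest.raises(ValueError):
            collective_q(10, 5)


class TestClosedForms:
    def test_reference_recessive_value(self):
        q = 19_693 / 282_912
        assert 100 * recessive_prevalence(q) == pytest.approx(0.48, abs=5e-3)

    def test_reference_dominant_value(self):
        q = 3_673 / 35_440
        assert 100 * dominant_prevalence(q) == pytest.approx(18.6, abs=5e-2)

    def test_limits(self):
        assert carrier_frequency(0) == dominant_prevalence(0) == recessive_prevalence(0) == 0
        assert recessive_prevalence(1) == 1
        assert dominant_prevalence(1) == 0
        assert carrier_frequency(1) == 2  # dosage, not a probability, beyond q=0.5

    def test_q_outside_unit_interval_rejected(self):
        for fn in (carrier_frequency, dominant_prevalence, recessive_prevalence):
            with pytest.raises(ValueError):
                fn(1.5)

    @settings(max_examples=200, derandomize=True)
    @given(q=qs)
    def test_hwe_identity(self, q):
        assert (1 - q) ** 2 + dominant_prevalence(q) + recessive_prevalence(q) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(q=st.floats(0.0, 0.5, allow_nan=False))
    def test_model_ordering_below_half(self, q):
        assert recessive_prevalence(q) <= dominant_prevalence(q) <= carrier_frequency(q)

    def test_dominant_maximal_at_half(self):
        grid = np.linspace(0, 1, 1001)
        values = [dominant_prevalence(q) for q in grid]
        assert grid[int(np.argmax(values))] == pytest.approx(0.5)


class TestCompoundAndPooled:
    def test_zero_null_reduces_to_recessive(self):
        for q in (0.0, 0.01, 0.3):
            assert compound_recessive_prevalence(q, 0.0) == recessive_prevalence(q)

    def test_zero_primary_is_zero(self):
        assert compound_recessive_prevalence(0.0, 0.2) == 0.0

    def test_hand_arithmetic(self):
        assert compound_recessive_prevalence(0.01, 0.02) == pytest.approx(0.0005)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            compound_recessive_prevalence(0.6, 0.5)

    def test_pooled_hand_arithmetic(self):
        assert pooled_recessive_prevalence([0.01, 0.015]) == pytest.approx(0.000625)

    def test_pooled_single_component_equals_recessive(self):
        assert pooled_recessive_prevalence([0.07]) == recessive_prevalence(0.07)

    def test_pooled_empty_is_zero(self):
        assert pooled_recessive_prevalence([]) == 0.0

    def test_pooled_overflow_rejected(self):
        with pytest.raises(ValueError):
            pooled_recessive_prevalence([0.6, 0.6])


POP1 = (PopulationLabel("afr", "African", 10_000),)


def typed_cohort(pops=None):
    """Three reported variants (types 1, 1, 2N) and one novel frameshift."""
    records = [
        make_record(0, counts={"afr": AlleleCounts(200, 20_000, 0)}, hgvs_c="c.1001G>A"),
        make_record(1, counts={"afr": AlleleCounts(400, 20_000, 0)}, hgvs_c="c.1002G>A"),
        make_record(2, counts={"afr": AlleleCounts(100, 20_000, 0)}, hgvs_c="c.1003G>A"),
        make_record(3, consequence=Consequence.FRAMESHIFT, hgvs_p=None,
                    counts={"afr": AlleleCounts(50, 20_000, 0)}, hgvs_c="c.1004del"),
    ]
    entries = [
        KnownVariantEntry(hgvs_c="c.1001G>A", vwd_type="1"),
        KnownVariantEntry(hgvs_c="c.1002G>A", vwd_type="1"),
        KnownVariantEntry(hgvs_c="c.1003G>A", vwd_type="2N", inheritance="recessive"),
    ]
    results, _ = classify_cohort(records, KnownVariantDB.from_entries(entries))
    return records, results


class TestTypeSpecificQ:
    def test_sums_per_variant_mafs(self, pops):
        records, results = typed_cohort(pops)
        cf = type_specific_q(records, results, "afr", ["1"])
        assert cf.q == pytest.approx(0.01 + 0.02)

    def test_exclusion_list_drops_named_variant(self, pops):
        records, results = typed_cohort(pops)
        cf = type_specific_q(records, results, "afr", ["1"], exclusions=["c.1002 G > A"])
        assert cf.q == pytest.approx(0.01)
        assert cf.exclusions == ("c.1002G>A",)

    def test_maf_cutoff_drops_common_variant(self, pops):
        records, results = typed_cohort(pops)
        cf = type_specific_q(records, results, "afr", ["1"], maf_cutoff=0.015)
        assert cf.q == pytest.approx(0.01)
        assert cf.exclusions == ("c.1002G>A",)
        assert cf.maf_cutoff_applied == 0.015

    def test_novel_variants_never_enter_type_sets(self, pops):
        records, results = typed_cohort(pops)
        cf = type_specific_q(records, results, "afr", ["1", "2N", "3"])
        assert cf.q == pytest.approx(0.035)  # frameshift (novel) contributes nothing

    def test_empty_type_set_rejected(self, pops):
        with pytest.raises(ValueError):
            type_specific_q([], [], "afr", [])

    def test_exclusion_monotonicity(self, pops):
        records, results = typed_cohort(pops)
        base = type_specific_q(records, results, "afr", ["1", "2N"]).q
        for extra in ("c.1001G>A", "c.1002G>A", "c.1003G>A", "c.9999G>A"):
            smaller = type_specific_q(records, results, "afr", ["1", "2N"], exclusions=[extra]).q
            assert smaller <= base


class TestCohortCollectiveQ:
    def test_fixed_denominator_and_per_population_exclusion(self):
        pops = (PopulationLabel("afr", "African", 10_000), PopulationLabel("nfe", "European", 40_000))
        records = [
            make_record(0, consequence=Consequence.FRAMESHIFT, hgvs_p=None,
                        counts={"afr": AlleleCounts(500, 18_000, 0), "nfe": AlleleCounts(100, 80_000, 0)}),
            make_record(1, consequence=Consequence.FRAMESHIFT, hgvs_p=None,
                        counts={"afr": AlleleCounts(300, 20_000, 0)}, hgvs_c="c.2000del"),
        ]
        results, _ = classify_cohort(records, KnownVariantDB())
        qs_plain = cohort_collective_q(records, results, pops)
        # an_ref denominators, not per-variant an
        assert qs_plain["afr"].q == pytest.approx(800 / 20_000)
        assert qs_plain["all"].q == pytest.approx(900 / 100_000)
        qs_excl = cohort_collective_q(
            records, results, pops, exclusions_by_population={"afr": ("c.2000del",)}
        )
        assert qs_excl["afr"].q == pytest.approx(500 / 20_000)
        # the exclusion is per-stratum: nfe and the grand total keep other strata intact
        assert qs_excl["all"].q == pytest.approx(600 / 100_000)
        assert qs_excl["afr"].exclusions == ("c.2000del",)


class TestPrevalenceReport:
    def test_per_type_grid_matches_closed_forms(self, pops):
        records, results = typed_cohort(pops)
        config = PrevalenceConfig(type_maf_cutoff=None, scale="per100", type_scale="per1000")
        estimates = prevalence_report(records, results, POP1, config)
        by = {(e.population, e.label, e.model): e for e in estimates}
        q1, q2n = 0.03, 0.005
        assert by[("afr", "type_1", "dominant_2pq")].value == pytest.approx(1000 * dominant_prevalence(q1))
        assert by[("afr", "type_2N", "recessive_compound")].value == pytest.approx(
            1000 * compound_recessive_prevalence(q2n, q1)
        )
        assert by[("afr", "type_3", "recessive_q2")].value == pytest.approx(
            1000 * pooled_recessive_prevalence([0.0, q1])
        )

    def test_audit_differs_exactly_by_configured_exclusions(self, pops):
        records, results = typed_cohort(pops)
        plain = PrevalenceConfig(type_maf_cutoff=None)
        excl = PrevalenceConfig(
            type_maf_cutoff=None,
            type_exclusions_by_population={"afr": ("c.1001G>A",)},
        )
        get = lambda ests: {e.q_inputs[0].exclusions for e in ests if e.label == "type_1" and e.population == "afr"}
        assert get(prevalence_report(records, results, POP1, plain)) == {()}
        assert get(prevalence_report(records, results, POP1, excl)) == {("c.1001G>A",)}

    def test_carrier_and_dominant_models_are_distinct_columns(self, pops):
        records, results = typed_cohort(pops)
        estimates = prevalence_report(records, results, POP1, PrevalenceConfig())
        models = {e.model for e in estimates if e.label == "all_variants"}
        assert models == {"carrier_2q", "dominant_2pq", "recessive_q2"}


class TestParameterRecovery:
    @pytest.mark.parametrize("q_star", [0.001, 0.01, 0.1])
    def test_simulated_cohorts_recover_collective_q(self, q_star):
        """Estimated q on HWE-simulated cohorts stays within 4 binomial SE of
        the planted collective frequency, and prevalence tracks the closed
        forms within the induced bound."""
        from vwdprev.simulate import SimulationSpec, simulate_cohort

        n_individuals = 50_000
        n_variants = 20
        spec = SimulationSpec(
            populations=(PopulationLabel("pop", "synthetic stratum", n_individuals),),
            n_variants=n_variants,
            pathogenic_fraction=1.0,
            reported_fraction=1.0,
            consequence_mix={Consequence.MISSENSE: 1.0},
            vwd_type_mix={"1": 1.0},
            recurrent_variants=(),
            singleton_fraction=0.0,
            rare_q_range=(q_star / n_variants, q_star / n_variants),
            seed=123,
        )
        records, db, truth = simulate_cohort(spec)
        results, _ = classify_cohort(records, db)
        qs_est = cohort_collective_q(records, results, spec.populations)
        an = 2 * n_individuals
        bound = 4 * np.sqrt(q_star * (1 - q_star) / an)
        q_hat = qs_est["pop"].q
        assert abs(q_hat - q_star) < bound
        assert abs(dominant_prevalence(q_hat) - dominant_prevalence(q_star)) < 2 * bound
        assert abs(recessive_prevalence(q_hat) - recessive_prevalence(q_star)) < 2 * bound * q_star + bound**2
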