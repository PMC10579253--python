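"""Cohort table I/O: parsing, validation, dialect round trips, multi-allelic split."""

import pytest

from conftest import ac, make_record
from vwdprev.cohort import (
    AlleleCounts,
    CohortValidationError,
    Consequence,
    PopulationLabel,
    PredictorProfile,
    SpliceScores,
    VariantKey,
    VariantRecord,
    read_variant_table,
    validate_cohort,
    write_variant_table,
)
from vwdprev.simulate import SimulationSpec, simulate_cohort

HEADER = (
    "chrom\tpos\tref\talt\thgvs_c\thgvs_p\trsid\tconsequence\tintronic_offset\tmean_depth\t"
    "cadd_phred\tsift\tpolyphen2\tlrt\tmutationtaster\tmutationassessor\tfathmm\t"
    "varseak_wt\tvarseak_var\tvarseak_abolished\tesefinder_wt\tesefinder_var\tesefinder_abolished\t"
    "bdgp_wt\tbdgp_var\tbdgp_abolished\tac_afr\tan_afr\tnhom_afr"
)


def write_tsv(tmp_path, *rows):
    path = tmp_path / "variants.tsv"
    path.write_text("\n".join([HEADER, *rows]) + "\n")
    return str(path)


class TestTsvParsing:
    def test_single_row_maps_fields_and_maf_is_derivable(self, tmp_path):
        path = write_tsv(tmp_path, "12\t6060000\tG\tA\tc.100G>A\tp.Arg854Gln\t\tmissense\t\t35\t" + "\t" * 16 + "2\t100\t0")
        (rec,) = read_variant_table(path)
        assert rec.key == VariantKey("12", 6060000, "G", "A")
        counts = rec.allele_counts("afr")
        assert (counts.ac, counts.an) == (2, 100)
        assert counts.ac / counts.an == pytest.approx(0.02)

    def test_identifiers_kept_verbatim(self, tmp_path):
        """HGVS c./p. strings and the rsid survive parsing untouched."""
        path = write_tsv(
            tmp_path,
            "12\t6128442\tC\tT\tc.6554 G > A\tp.Arg2185Gln\trs2229446\tmissense\t\t35\t" + "\t" * 16 + "2\t100\t0",
        )
        (rec,) = read_variant_table(path)
        assert rec.hgvs_c == "c.6554 G > A"
        assert rec.hgvs_p == "p.Arg2185Gln"
        assert rec.rsid == "rs2229446"
        assert rec.consequence is Consequence.MISSENSE

    def test_ac_exceeding_an_is_rejected_with_line_and_field(self, tmp_path):
        path = write_tsv(tmp_path, "12\t6060000\tG\tA\tc.100G>A\tp.Arg854Gln\t\tmissense\t\t35\t" + "\t" * 16 + "5\t4\t0")
        with pytest.raises(CohortValidationError, match=r"line 2.*ac_afr.*AC<=AN"):
            read_variant_table(path)

    def test_unknown_population_code_lists_known_codes(self, tmp_path, pops):
        path = write_tsv(tmp_path, "12\t6060000\tG\tA\tc.100G>A\tp.Arg854Gln\t\tmissense\t\t35\t" + "\t" * 16 + "2\t100\t0")
        with pytest.raises(CohortValidationError, match="afr"):
            read_variant_table(path, populations=(PopulationLabel("fin", "Finnish", 10),))

    def test_malformed_position_names_line_and_field(self, tmp_path):
        path = write_tsv(tmp_path, "12\txyz\tG\tA\tc.100G>A\tp.Arg854Gln\t\tmissense\t\t35\t" + "\t" * 16 + "2\t100\t0")
        with pytest.raises(CohortValidationError, match=r"line 2.*pos"):
            read_variant_table(path)

    def test_missing_predictor_parses_to_missing_not_default(self, tmp_path):
        path = write_tsv(tmp_path, "12\t6060000\tG\tA\tc.100G>A\tp.Arg854Gln\t\tmissense\t\t35\t" + "\t" * 16 + "2\t100\t0")
        (rec,) = read_variant_table(path)
        assert rec.predictors.cadd_phred is None
        assert rec.predictors.missense_call("SIFT") == "missing"
        assert rec.predictors.splice_scores == {}


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["tsv", "vcf"])
    def test_empty_cohort_round_trips_to_header_only_file(self, tmp_path, dialect):
        path = str(tmp_path / f"empty.{dialect}")
        write_variant_table([], path, dialect=dialect)
        assert read_variant_table(path, dialect=dialect) == []

    @pytest.mark.parametrize("dialect", ["tsv", "vcf"])
    def test_simulated_cohort_round_trips_field_for_field(self, tmp_path, dialect):
        spec = SimulationSpec(
            n_variants=60,
            populations=(PopulationLabel("afr", "African", 300), PopulationLabel("eas", "East Asian", 150)),
            seed=11,
        )
        records, _db, _truth = simulate_cohort(spec)
        path = str(tmp_path / f"cohort.{dialect}")
        write_variant_table(records, path, dialect=dialect, populations=spec.populations)
        assert read_variant_table(path, dialect=dialect, populations=spec.populations) == records

    def test_handwritten_record_round_trips_through_both_dialects(self, tmp_path, pops):
        rec = VariantRecord(
            key=VariantKey("12", 6128442, "C", "T"),
            hgvs_c="c.6554 G > A",
            hgvs_p="p.Arg2185Gln",
            rsid="rs2229446",
            consequence=Consequence.MISSENSE,
            predictors=PredictorProfile(
                cadd_phred=23.5,
                missense_calls={"SIFT": "deleterious", "PolyPhen2": "tolerated"},
                splice_scores={"BDGP": SpliceScores(wild_type=8.25, variant=3.5, site_abolished=False)},
            ),
            counts={"afr": AlleleCounts(38, 200, 2), "nfe": AlleleCounts(1, 400, 0)},
            mean_depth=35.0,
        )
        for dialect in ("tsv", "vcf"):
            path = str(tmp_path / f"one.{dialect}")
            write_variant_table([rec], path, dialect=dialect, populations=pops)
            assert read_variant_table(path, dialect=dialect) == [rec]


class TestVcfDialect:
    def test_written_vcf_carries_per_population_info_keys(self, tmp_path, pops):
        rec = make_record(counts=ac({"afr": 3}, pops))
        path = str(tmp_path / "out.vcf")
        write_variant_table([rec], path, dialect="vcf", populations=pops)
        text = open(path).read()
        for code in ("afr", "nfe", "eas"):
            for key in (f"AC_{code}", f"AN_{code}", f"nhomalt_{code}"):
                assert f"##INFO=<ID={key}," in text
                assert f"{key}=" in text.splitlines()[-1]

    def test_written_data_line_matches_expected_fixture(self, tmp_path):
        pops = (PopulationLabel("afr", "African", 100),)
        rec = VariantRecord(
            key=VariantKey("12", 6128442, "C", "T"),
            hgvs_c="c.6554G>A",
            hgvs_p="p.Arg2185Gln",
            rsid="rs2229446",
            consequence=Consequence.MISSENSE,
            predictors=PredictorProfile(cadd_phred=23.5, missense_calls={"SIFT": "deleterious"}),
            counts={"afr": AlleleCounts(38, 200, 2)},
            mean_depth=35.0,
        )
        path = str(tmp_path / "one.vcf")
        write_variant_table([rec], path, dialect="vcf", populations=pops)
        # 21 pipe-separated CSQ sub-fields: consequence, offset, c., p., CADD,
        # six categorical tools, nine splice score fields, mean depth
        expected = (
            "12\t6128442\trs2229446\tC\tT\t.\t.\t"
            "AC_afr=38;AN_afr=200;nhomalt_afr=2;"
            "CSQ=missense||c.6554G>A|p.Arg2185Gln|23.5|deleterious" + "|" * 14 + "|35.0"
        )
        assert open(path).read().splitlines()[-1] == expected

    def test_multiallelic_site_splits_and_conserves_allele_counts(self, tmp_path):
        vcf = "\n".join(
            [
                "##fileformat=VCFv4.2",
                "##contig=<ID=12>",
                '##INFO=<ID=AC_afr,Number=A,Type=Integer,Description="x">',
                '##INFO=<ID=AN_afr,Number=1,Type=Integer,Description="x">',
                '##INFO=<ID=nhomalt_afr,Number=A,Type=Integer,Description="x">',
                '##INFO=<ID=CSQ,Number=A,Type=String,Description="x">',
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
                "12\t6060000\t.\tG\tA,T\t.\t.\t"
                "AC_afr=5,2;AN_afr=200;nhomalt_afr=1,0;"
                "CSQ=missense||c.100G>A|p.Gly34Ser" + "|" * 17 + ","
                "missense||c.100G>T|p.Gly34Cys" + "|" * 17,
            ]
        )
        path = tmp_path / "multi.vcf"
        path.write_text(vcf + "\n")
        records = read_variant_table(str(path), dialect="vcf")
        assert [r.key.alt for r in records] == ["A", "T"]
        assert [r.allele_counts("afr").ac for r in records] == [5, 2]
        assert sum(r.allele_counts("afr").ac for r in records) == 7
        assert [r.allele_counts("afr").n_hom for r in records] == [1, 0]
        assert all(r.allele_counts("afr").an == 200 for r in records)


class TestValidateCohort:
    def test_clean_cohort_yields_empty_violation_list(self, pops):
        records = [make_record(i, counts=ac({"afr": 1}, pops)) for i in range(3)]
        report = validate_cohort(records, pops)
        assert report.ok and report.low_coverage == []

    def test_low_coverage_record_is_flagged_and_retained(self, pops):
        records = [make_record(0, counts=ac({"afr": 1}, pops), mean_depth=8.0)]
        report = validate_cohort(records, pops)
        assert report.ok
        assert report.low_coverage == [records[0].key]

    def test_population_absent_from_spec_is_a_violation(self, pops):
        rec = make_record(0, counts={"fin": AlleleCounts(1, 10, 0)})
        report = validate_cohort([rec], pops)
        assert not report.ok
        assert "fin" in report.violations[0]

    def test_an_beyond_stratum_size_is_a_violation(self, pops):
        rec = make_record(0, counts={"afr": AlleleCounts(1, 500, 0)})
        report = validate_cohort([rec], pops)
        assert any("2*n_individuals" in v for v in report.violations)


class TestInvariants:
    def test_variant_key_rejects_bad_alleles(self):
        with pytest.raises(CohortValidationError):
            VariantKey("12", 0, "G", "A")
        with pytest.raises(CohortValidationError):
            VariantKey("12", 5, "G", "G")
        with pytest.raises(CohortValidationError):
            VariantKey("12", 5, "G", "N")

    def test_homozygote_count_bounded_by_allele_count(self):
        with pytest.raises(CohortValidationError):
            AlleleCounts(ac=3, an=100, n_hom=2)

    def test_splice_offsets_must_match_consequence_class(self):
        with pytest.raises(CohortValidationError):
            make_record(consequence=Consequence.SPLICE_CORE, intronic_offset=5)
        with pytest.raises(CohortValidationError):
            make_record(consequence=Consequence.SPLICE_REGION, intronic_offset=2)

    def test_protein_hgvs_required_for_coding_classes(self):
        with pytest.raises(CohortValidationError):
            make_record(consequence=Consequence.MISSENSE, hgvs_p=None)
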