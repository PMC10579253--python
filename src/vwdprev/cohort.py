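"""Typed variant records and gnomAD-style cohort table I/O.

A cohort is a sequence of biallelic :class:`VariantRecord` objects, each
carrying per-population allele counts (``ac``/``an``/``n_hom``), a consequence
class, verbatim HGVS strings, and an in-silico predictor profile.  Two on-disk
dialects are supported:

* **TSV** (canonical fixture format): one row per variant, one column per
  scalar field, plus ``ac_<pop>``/``an_<pop>``/``nhom_<pop>`` triples per
  population.  Column names are fixed (see :data:`TSV_SCALAR_COLUMNS`).
* **VCF 4.2** (interoperability): per-population ``AC_<pop>`` / ``AN_<pop>`` /
  ``nhomalt_<pop>`` INFO keys and a ``CSQ`` annotation string whose
  pipe-separated sub-fields follow :data:`CSQ_FIELDS`.  Multi-allelic sites
  are split into biallelic records on read.

Coordinates are VCF 1-based.  HGVS strings are stored verbatim and never
recomputed from genomic coordinates (VWF lies on the minus strand of
chromosome 12; reconciling c. and genomic coordinates is annotation-tool
territory).  Missing predictor values parse to an explicit missing state,
never to a default call, so that consensus rules fail closed.
"""

from __future__ import annotations

import csv
import math
import urllib.parse
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pysam

__all__ = [
    "MISSENSE_TOOLS",
    "SPLICE_TOOLS",
    "AlleleCounts",
    "CohortValidationError",
    "Consequence",
    "PopulationLabel",
    "PredictorProfile",
    "SpliceScores",
    "ValidationReport",
    "VariantKey",
    "VariantRecord",
    "read_variant_table",
    "validate_cohort",
    "write_variant_table",
]

#: Categorical missense predictors consumed by the 7/7 consensus rule
#: (the seventh tool is the CADD PHRED score).
MISSENSE_TOOLS = ("SIFT", "PolyPhen2", "LRT", "MutationTaster", "MutationAssessor", "FATHMM")

#: Splice-score predictors consumed by the 4/4 consensus rule
#: (the fourth tool is again CADD).
SPLICE_TOOLS = ("Varseak", "ESEFinder", "BDGP")

_DNA = frozenset("ACGT")

MISSENSE_CALLS = ("deleterious", "tolerated", "missing")


class CohortValidationError(ValueError):
    """Raised when a cohort table violates a structural invariant."""


class Consequence(str, Enum):
    """Functional consequence class of a variant allele.

    ``splice_core`` denotes the first/last 2 intronic nucleotides of an
    exon boundary, ``splice_region`` intronic offsets 3..8.
    """

    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_CORE = "splice_core"
    SPLICE_REGION = "splice_region"
    OTHER = "other"


#: Consequences for which a protein-level HGVS string is required.
_PROTEIN_CODING = frozenset(
    {Consequence.MISSENSE, Consequence.STOP_GAINED, Consequence.STOP_LOST, Consequence.INFRAME_INDEL}
)


@dataclass(frozen=True)
class PopulationLabel:
    """One gnomAD-style population stratum.

    Parameters
    ----------
    code:
        Short identifier, e.g. ``afr``, ``nfe``.
    display_name:
        Human-readable name, e.g. "African/African American".
    n_individuals:
        Number of sequenced individuals; the reference allele number of the
        stratum is ``an_ref = 2 * n_individuals``.
    """

    code: str
    display_name: str
    n_individuals: int

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise CohortValidationError(f"population {self.code!r}: n_individuals < 0")

    @property
    def an_ref(self) -> int:
        return 2 * self.n_individuals


@dataclass(frozen=True)
class VariantKey:
    """Site/allele key in VCF convention (1-based position, explicit ref/alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CohortValidationError(f"{self}: pos must be >= 1")
        if not self.ref or not self.alt:
            raise CohortValidationError(f"{self}: empty ref/alt")
        if self.ref == self.alt:
            raise CohortValidationError(f"{self}: ref == alt")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _DNA:
                raise CohortValidationError(f"{self}: non-ACGT allele {allele!r}")

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class SpliceScores:
    """Wild-type vs variant splice-site score pair for one prediction tool."""

    wild_type: float
    variant: float
    site_abolished: bool

    def __post_init__(self) -> None:
        for score in (self.wild_type, self.variant):
            if not math.isfinite(score) or score < 0:
                raise CohortValidationError(f"splice score must be finite and >= 0, got {score}")


@dataclass(frozen=True)
class PredictorProfile:
    """Precomputed in-silico predictor calls for one variant.

    ``cadd_phred`` is ``None`` when CADD was not scored — distinct from 0.
    ``missense_calls`` maps each tool in :data:`MISSENSE_TOOLS` to
    ``deleterious`` / ``tolerated`` / ``missing``; absent keys are treated
    as ``missing``.  ``splice_scores`` holds one :class:`SpliceScores` pair
    per tool in :data:`SPLICE_TOOLS`; an absent tool means no prediction.
    """

    cadd_phred: Optional[float] = None
    missense_calls: Mapping[str, str] = field(default_factory=dict)
    splice_scores: Mapping[str, SpliceScores] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cadd_phred is not None:
            if not math.isfinite(self.cadd_phred) or self.cadd_phred < 0:
                raise CohortValidationError(f"cadd_phred must be finite and >= 0, got {self.cadd_phred}")
        for tool, call in self.missense_calls.items():
            if tool not in MISSENSE_TOOLS:
                raise CohortValidationError(f"unknown missense tool {tool!r}")
            if call not in MISSENSE_CALLS:
                raise CohortValidationError(f"unknown call {call!r} for {tool}")
        for tool in self.splice_scores:
            if tool not in SPLICE_TOOLS:
                raise CohortValidationError(f"unknown splice tool {tool!r}")

    def missense_call(self, tool: str) -> str:
        return self.missense_calls.get(tool, "missing")


@dataclass(frozen=True)
class AlleleCounts:
    """Alt-allele count, genotyped allele number and homozygote count."""

    ac: int = 0
    an: int = 0
    n_hom: int = 0

    def __post_init__(self) -> None:
        if min(self.ac, self.an, self.n_hom) < 0:
            raise CohortValidationError(f"negative allele counts: {self}")
        if self.ac > self.an:
            raise CohortValidationError(f"ac ({self.ac}) > an ({self.an}) violates AC<=AN")
        if 2 * self.n_hom > self.ac:
            raise CohortValidationError(f"2*n_hom ({2 * self.n_hom}) > ac ({self.ac})")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic VWF variant with per-population allele summaries."""

    key: VariantKey
    hgvs_c: str
    consequence: Consequence
    counts: Mapping[str, AlleleCounts]
    hgvs_p: Optional[str] = None
    rsid: Optional[str] = None
    intronic_offset: Optional[int] = None
    predictors: PredictorProfile = field(default_factory=PredictorProfile)
    mean_depth: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.hgvs_c:
            raise CohortValidationError(f"{self.key}: hgvs_c required")
        if self.consequence in _PROTEIN_CODING and not self.hgvs_p:
            raise CohortValidationError(f"{self.key}: hgvs_p required for {self.consequence.value} variants")
        off = self.intronic_offset
        if self.consequence is Consequence.SPLICE_CORE:
            if off is None or abs(off) not in (1, 2):
                raise CohortValidationError(f"{self.key}: splice_core requires |intronic_offset| in {{1,2}}, got {off}")
        elif self.consequence is Consequence.SPLICE_REGION:
            if off is None or not 3 <= abs(off) <= 8:
                raise CohortValidationError(f"{self.key}: splice_region requires 3<=|intronic_offset|<=8, got {off}")

    def allele_counts(self, population: str) -> AlleleCounts:
        return self.counts.get(population, AlleleCounts())

    def pooled_counts(self) -> AlleleCounts:
        """Counts summed over all populations present on the record."""
        ac = sum(c.ac for c in self.counts.values())
        an = sum(c.an for c in self.counts.values())
        n_hom = sum(c.n_hom for c in self.counts.values())
        return AlleleCounts(ac=ac, an=an, n_hom=n_hom)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

TSV_SCALAR_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "hgvs_c",
    "hgvs_p",
    "rsid",
    "consequence",
    "intronic_offset",
    "mean_depth",
    "cadd_phred",
    "sift",
    "polyphen2",
    "lrt",
    "mutationtaster",
    "mutationassessor",
    "fathmm",
    "varseak_wt",
    "varseak_var",
    "varseak_abolished",
    "esefinder_wt",
    "esefinder_var",
    "esefinder_abolished",
    "bdgp_wt",
    "bdgp_var",
    "bdgp_abolished",
)

_TOOL_COLUMNS = {
    "SIFT": "sift",
    "PolyPhen2": "polyphen2",
    "LRT": "lrt",
    "MutationTaster": "mutationtaster",
    "MutationAssessor": "mutationassessor",
    "FATHMM": "fathmm",
}

_SPLICE_COLUMNS = {"Varseak": "varseak", "ESEFinder": "esefinder", "BDGP": "bdgp"}


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _population_codes_from_header(columns: Sequence[str]) -> list[str]:
    codes = [c[3:] for c in columns if c.startswith("ac_")]
    for code in codes:
        for prefix in ("an_", "nhom_"):
            if f"{prefix}{code}" not in columns:
                raise CohortValidationError(f"missing column {prefix}{code} for population {code!r}")
    return codes


def _check_population_codes(codes: Iterable[str], populations: Optional[Sequence[PopulationLabel]]) -> None:
    if populations is None:
        return
    known = {p.code for p in populations}
    unknown = sorted(set(codes) - known)
    if unknown:
        raise CohortValidationError(f"unknown population code(s) {unknown}; known codes: {sorted(known)}")


def _parse_row(row: Mapping[str, str], codes: Sequence[str], line_no: int) -> VariantRecord:
    def fail(field_name: str, message: str) -> CohortValidationError:
        return CohortValidationError(f"line {line_no}, field {field_name!r}: {message}")

    def get_int(name: str, required: bool = True) -> Optional[int]:
        raw = row.get(name, "").strip()
        if raw == "":
            if required:
                raise fail(name, "required integer missing")
            return None
        try:
            return int(raw)
        except ValueError:
            raise fail(name, f"not an integer: {raw!r}") from None

    def get_float(name: str) -> Optional[float]:
        raw = row.get(name, "").strip()
        if raw == "":
            return None
        try:
            return float(raw)
        except ValueError:
            raise fail(name, f"not a number: {raw!r}") from None

    try:
        key = VariantKey(
            chrom=row.get("chrom", "").strip(),
            pos=get_int("pos"),
            ref=row.get("ref", "").strip(),
            alt=row.get("alt", "").strip(),
        )
    except CohortValidationError as exc:
        if "line" in str(exc):
            raise
        raise CohortValidationError(f"line {line_no}: {exc}") from None

    raw_csq = row.get("consequence", "").strip()
    try:
        consequence = Consequence(raw_csq)
    except ValueError:
        raise fail("consequence", f"unknown consequence class {raw_csq!r}") from None

    missense_calls = {}
    for tool, col in _TOOL_COLUMNS.items():
        raw = row.get(col, "").strip()
        if raw == "" or raw == "missing":
            continue
        if raw not in MISSENSE_CALLS:
            raise fail(col, f"unknown predictor call {raw!r}")
        missense_calls[tool] = raw

    splice_scores = {}
    for tool, prefix in _SPLICE_COLUMNS.items():
        wt = get_float(f"{prefix}_wt")
        var = get_float(f"{prefix}_var")
        ab_raw = row.get(f"{prefix}_abolished", "").strip()
        if wt is None and var is None and ab_raw == "":
            continue
        if wt is None or var is None or ab_raw == "":
            raise fail(f"{prefix}_wt", f"incomplete splice score triple for {tool}")
        splice_scores[tool] = SpliceScores(wild_type=wt, variant=var, site_abolished=ab_raw == "1")

    counts = {}
    for code in codes:
        ac = get_int(f"ac_{code}")
        an = get_int(f"an_{code}")
        n_hom = get_int(f"nhom_{code}")
        if ac == an == n_hom == 0:
            # a fully-zero triple means the stratum was not genotyped here;
            # absent and all-zero are the same state (allele_counts() returns
            # zeros for missing strata), so keep round trips exact
            continue
        try:
            counts[code] = AlleleCounts(ac=ac, an=an, n_hom=n_hom)
        except CohortValidationError as exc:
            raise fail(f"ac_{code}", str(exc)) from None

    try:
        return VariantRecord(
            key=key,
            hgvs_c=row.get("hgvs_c", "").strip(),
            hgvs_p=row.get("hgvs_p", "").strip() or None,
            rsid=row.get("rsid", "").strip() or None,
            consequence=consequence,
            intronic_offset=get_int("intronic_offset", required=False),
            predictors=PredictorProfile(
                cadd_phred=get_float("cadd_phred"),
                missense_calls=missense_calls,
                splice_scores=splice_scores,
            ),
            counts=counts,
            mean_depth=get_float("mean_depth"),
        )
    except CohortValidationError as exc:
        raise CohortValidationError(f"line {line_no}: {exc}") from None


def _read_tsv(path: str, populations: Optional[Sequence[PopulationLabel]]) -> list[VariantRecord]:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise CohortValidationError(f"{path}: empty file, header expected")
        missing = [c for c in TSV_SCALAR_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CohortValidationError(f"{path}: missing required column(s) {missing}")
        codes = _population_codes_from_header(reader.fieldnames)
        _check_population_codes(codes, populations)
        return [_parse_row(row, codes, line_no) for line_no, row in enumerate(reader, start=2)]


def _record_to_tsv_row(record: VariantRecord, codes: Sequence[str]) -> list[str]:
    pred = record.predictors
    row = [
        record.key.chrom,
        str(record.key.pos),
        record.key.ref,
        record.key.alt,
        record.hgvs_c,
        _fmt(record.hgvs_p),
        _fmt(record.rsid),
        record.consequence.value,
        _fmt(record.intronic_offset),
        _fmt(record.mean_depth),
        _fmt(pred.cadd_phred),
    ]
    for tool in MISSENSE_TOOLS:
        call = pred.missense_calls.get(tool)
        row.append("" if call is None else call)
    for tool in SPLICE_TOOLS:
        scores = pred.splice_scores.get(tool)
        if scores is None:
            row.extend(["", "", ""])
        else:
            row.extend([_fmt(scores.wild_type), _fmt(scores.variant), _fmt(scores.site_abolished)])
    for code in codes:
        c = record.allele_counts(code)
        row.extend([str(c.ac), str(c.an), str(c.n_hom)])
    return row


def _cohort_codes(records: Sequence[VariantRecord], populations: Optional[Sequence[PopulationLabel]]) -> list[str]:
    if populations is not None:
        return [p.code for p in populations]
    codes: list[str] = []
    for record in records:
        for code in record.counts:
            if code not in codes:
                codes.append(code)
    return codes


def _write_tsv(records: Sequence[VariantRecord], path: str, codes: Sequence[str]) -> None:
    header = list(TSV_SCALAR_COLUMNS)
    for code in codes:
        header.extend([f"ac_{code}", f"an_{code}", f"nhom_{code}"])
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for record in records:
            writer.writerow(_record_to_tsv_row(record, codes))


# ---------------------------------------------------------------------------
# VCF dialect
# ---------------------------------------------------------------------------

#: Pipe-separated sub-fields of the per-allele CSQ annotation string.
CSQ_FIELDS = (
    "consequence",
    "intronic_offset",
    "hgvs_c",
    "hgvs_p",
    "cadd_phred",
    "sift",
    "polyphen2",
    "lrt",
    "mutationtaster",
    "mutationassessor",
    "fathmm",
    "varseak_wt",
    "varseak_var",
    "varseak_abolished",
    "esefinder_wt",
    "esefinder_var",
    "esefinder_abolished",
    "bdgp_wt",
    "bdgp_var",
    "bdgp_abolished",
    "mean_depth",
)

# VCF INFO strings may not contain whitespace/;/,/| — percent-encode them
# (VCF 4.3 convention) so HGVS strings survive verbatim.
_VCF_UNSAFE = " ;,|=%"


def _vcf_encode(value: str) -> str:
    return urllib.parse.quote(value, safe="".join(c for c in map(chr, range(33, 127)) if c not in _VCF_UNSAFE))


def _vcf_decode(value: str) -> str:
    return urllib.parse.unquote(value)


def _csq_entry(record: VariantRecord) -> str:
    pred = record.predictors
    parts = [
        record.consequence.value,
        _fmt(record.intronic_offset),
        _vcf_encode(record.hgvs_c),
        _vcf_encode(record.hgvs_p) if record.hgvs_p else "",
        _fmt(pred.cadd_phred),
    ]
    for tool in MISSENSE_TOOLS:
        call = pred.missense_calls.get(tool)
        parts.append("" if call is None else call)
    for tool in SPLICE_TOOLS:
        scores = pred.splice_scores.get(tool)
        if scores is None:
            parts.extend(["", "", ""])
        else:
            parts.extend([_fmt(scores.wild_type), _fmt(scores.variant), _fmt(scores.site_abolished)])
    parts.append(_fmt(record.mean_depth))
    return "|".join(parts)


def _write_vcf(records: Sequence[VariantRecord], path: str, codes: Sequence[str]) -> None:
    header = pysam.VariantHeader()
    header.add_meta("source", "vwdprev")
    for chrom in dict.fromkeys(r.key.chrom for r in records):
        header.contigs.add(chrom)
    if not records:
        header.contigs.add("12")
    for code in codes:
        header.add_meta(
            "INFO",
            items=[("ID", f"AC_{code}"), ("Number", "A"), ("Type", "Integer"), ("Description", f"Alt allele count in {code}")],
        )
        header.add_meta(
            "INFO",
            items=[("ID", f"AN_{code}"), ("Number", "1"), ("Type", "Integer"), ("Description", f"Allele number in {code}")],
        )
        header.add_meta(
            "INFO",
            items=[
                ("ID", f"nhomalt_{code}"),
                ("Number", "A"),
                ("Type", "Integer"),
                ("Description", f"Homozygous-alt individuals in {code}"),
            ],
        )
    header.add_meta(
        "INFO",
        items=[
            ("ID", "CSQ"),
            ("Number", "A"),
            ("Type", "String"),
            ("Description", "Annotation per alt allele. Format: " + "|".join(CSQ_FIELDS)),
        ],
    )
    with pysam.VariantFile(path, "w", header=header) as out:
        for record in records:
            rec = out.new_record(
                contig=record.key.chrom,
                start=record.key.pos - 1,
                alleles=(record.key.ref, record.key.alt),
                id=record.rsid,
            )
            for code in codes:
                c = record.allele_counts(code)
                rec.info[f"AC_{code}"] = (c.ac,)
                rec.info[f"AN_{code}"] = c.an
                rec.info[f"nhomalt_{code}"] = (c.n_hom,)
            rec.info["CSQ"] = (_csq_entry(record),)
            out.write(rec)


def _parse_csq_entry(entry: str, key: VariantKey, rsid: Optional[str], counts: Mapping[str, AlleleCounts]) -> VariantRecord:
    parts = entry.split("|")
    if len(parts) != len(CSQ_FIELDS):
        raise CohortValidationError(f"{key}: CSQ entry has {len(parts)} sub-fields, expected {len(CSQ_FIELDS)}")
    values = dict(zip(CSQ_FIELDS, parts))

    def opt_float(name: str) -> Optional[float]:
        return float(values[name]) if values[name] != "" else None

    missense_calls = {}
    for tool, col in _TOOL_COLUMNS.items():
        if values[col] not in ("", "missing"):
            missense_calls[tool] = values[col]
    splice_scores = {}
    for tool, prefix in _SPLICE_COLUMNS.items():
        wt, var, ab = (values[f"{prefix}_wt"], values[f"{prefix}_var"], values[f"{prefix}_abolished"])
        if wt == "" and var == "" and ab == "":
            continue
        splice_scores[tool] = SpliceScores(wild_type=float(wt), variant=float(var), site_abolished=ab == "1")

    try:
        return VariantRecord(
            key=key,
            hgvs_c=_vcf_decode(values["hgvs_c"]),
            hgvs_p=_vcf_decode(values["hgvs_p"]) or None,
            rsid=rsid,
            consequence=Consequence(values["consequence"]),
            intronic_offset=int(values["intronic_offset"]) if values["intronic_offset"] != "" else None,
            predictors=PredictorProfile(
                cadd_phred=opt_float("cadd_phred"),
                missense_calls=missense_calls,
                splice_scores=splice_scores,
            ),
            counts=dict(counts),
            mean_depth=opt_float("mean_depth"),
        )
    except (ValueError, CohortValidationError) as exc:
        raise CohortValidationError(f"{key}: {exc}") from None


def _read_vcf(path: str, populations: Optional[Sequence[PopulationLabel]]) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with pysam.VariantFile(path) as vcf:
        codes = sorted({k[3:] for k in vcf.header.info.keys() if k.startswith("AC_")})
        _check_population_codes(codes, populations)
        for site in vcf:
            alts = site.alts or ()
            csq = site.info.get("CSQ", ())
            if len(csq) != len(alts):
                raise CohortValidationError(
                    f"{site.chrom}:{site.pos}: {len(csq)} CSQ entries for {len(alts)} alt allele(s)"
                )
            for i, alt in enumerate(alts):
                counts = {}
                for code in codes:
                    ac_val = site.info.get(f"AC_{code}")
                    an_val = site.info.get(f"AN_{code}")
                    hom_val = site.info.get(f"nhomalt_{code}")
                    if ac_val is None or an_val is None:
                        continue
                    if int(ac_val[i]) == int(an_val) == 0 and (hom_val is None or int(hom_val[i]) == 0):
                        continue
                    try:
                        counts[code] = AlleleCounts(
                            ac=int(ac_val[i]),
                            an=int(an_val),
                            n_hom=int(hom_val[i]) if hom_val is not None else 0,
                        )
                    except CohortValidationError as exc:
                        raise CohortValidationError(f"{site.chrom}:{site.pos} alt {alt}, population {code}: {exc}") from None
                key = VariantKey(chrom=site.chrom, pos=site.pos, ref=site.ref, alt=alt)
                records.append(_parse_csq_entry(csq[i], key, site.id, counts))
    return records


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def read_variant_table(
    path: str,
    dialect: str = "tsv",
    populations: Optional[Sequence[PopulationLabel]] = None,
) -> list[VariantRecord]:
    """Read a cohort variant table.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"tsv"`` or ``"vcf"``.
    populations:
        Optional cohort population spec; when given, population codes found
        in the file must be a subset of the spec (unknown codes raise a
        :class:`CohortValidationError` listing the known codes).

    Returns
    -------
    One :class:`VariantRecord` per alt allele, in input order; multi-allelic
    VCF sites are split into biallelic records.
    """
    if dialect == "tsv":
        return _read_tsv(path, populations)
    if dialect == "vcf":
        return _read_vcf(path, populations)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")


def write_variant_table(
    records: Sequence[VariantRecord],
    path: str,
    dialect: str = "tsv",
    populations: Optional[Sequence[PopulationLabel]] = None,
) -> None:
    """Write records to ``path``; ``read_variant_table`` round-trips exactly."""
    codes = _cohort_codes(records, populations)
    if dialect == "tsv":
        _write_tsv(records, path, codes)
    elif dialect == "vcf":
        _write_vcf(records, path, codes)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")


@dataclass
class ValidationReport:
    """Report-only cohort validation outcome.

    ``violations`` lists invariant breaches (record kept, message recorded);
    ``low_coverage`` lists keys of records whose mean depth falls below the
    threshold — they are flagged, never removed, mirroring the DP>=10
    genotype-inclusion convention of gnomAD.
    """

    violations: list[str] = field(default_factory=list)
    low_coverage: list[VariantKey] = field(default_factory=list)
    min_depth: float = 10.0

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_cohort(
    records: Sequence[VariantRecord],
    populations: Sequence[PopulationLabel],
    min_depth: float = 10.0,
) -> ValidationReport:
    """Check cohort-level invariants without mutating or dropping records."""
    report = ValidationReport(min_depth=min_depth)
    known = {p.code: p for p in populations}
    seen: set[VariantKey] = set()
    for record in records:
        if record.key in seen:
            report.violations.append(f"{record.key}: duplicate variant key")
        seen.add(record.key)
        for code, counts in record.counts.items():
            pop = known.get(code)
            if pop is None:
                report.violations.append(
                    f"{record.key}: population {code!r} not in cohort spec (known: {sorted(known)})"
                )
                continue
            if counts.an > pop.an_ref:
                report.violations.append(
                    f"{record.key}: an ({counts.an}) exceeds 2*n_individuals ({pop.an_ref}) for {code}"
                )
        if record.mean_depth is not None and record.mean_depth < min_depth:
            report.low_coverage.append(record.key)
    return report
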