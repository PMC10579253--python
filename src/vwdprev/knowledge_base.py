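"""HGMD/LOVD-style known-variant knowledge base.

Disease-variant databases key their VWF entries by cDNA HGVS notation, so the
primary match key here is the ``hgvs_c`` string (whitespace-normalized,
case-preserved); a genomic :class:`~vwdprev.cohort.VariantKey` is an optional
fallback.  Entries carry the VWD type (1, 2A, 2B, 2M, 2N, 3 or UC for
unclassified), the inheritance mode, and a ``clear_association`` flag —
entries without a clear disease association never contribute to
pathogenicity classification or prevalence.

When two sources disagree on the VWD type, the merge policy follows the
curation convention of deferring to the primary literature: a
``literature_override`` on either entry wins; otherwise the merged type is
UC (unclassified).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from vwdprev.cohort import VariantKey, VariantRecord

__all__ = [
    "VWD_TYPES",
    "KnownVariantDB",
    "KnownVariantEntry",
    "load_known_variants",
    "lookup",
    "merge_sources",
    "normalize_hgvs",
    "normalize_vwd_type",
]

VWD_TYPES = ("1", "2A", "2B", "2M", "2N", "3", "UC")
INHERITANCE_MODES = ("dominant", "recessive", "unknown")
SOURCES = ("HGMD", "LOVD")

_WS = re.compile(r"\s+")


def normalize_hgvs(hgvs: str) -> str:
    """Collapse internal whitespace so "c.6554 G > A" and "c.6554G>A" match."""
    return _WS.sub("", hgvs)


def normalize_vwd_type(token: str) -> str:
    """Normalize a VWD type token ("type 2 N" -> "2N"); raise on unknown types."""
    cleaned = _WS.sub("", token).upper()
    cleaned = cleaned.removeprefix("TYPE")
    if cleaned not in VWD_TYPES:
        raise ValueError(f"unknown VWD type {token!r}; expected one of {VWD_TYPES}")
    return cleaned


@dataclass(frozen=True)
class KnownVariantEntry:
    """One curated disease-variant record."""

    hgvs_c: str
    vwd_type: str
    inheritance: str = "unknown"
    sources: frozenset[str] = frozenset({"HGMD"})
    clear_association: bool = True
    key: Optional[VariantKey] = None
    literature_override: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError(f"{self.hgvs_c}: entry must name at least one source")
        unknown = self.sources - set(SOURCES)
        if unknown:
            raise ValueError(f"{self.hgvs_c}: unknown source(s) {sorted(unknown)}")
        if self.vwd_type not in VWD_TYPES:
            raise ValueError(f"{self.hgvs_c}: invalid vwd_type {self.vwd_type!r}")
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(f"{self.hgvs_c}: invalid inheritance {self.inheritance!r}")
        if self.literature_override is not None and self.literature_override not in VWD_TYPES:
            raise ValueError(f"{self.hgvs_c}: invalid literature_override {self.literature_override!r}")

    @property
    def match_key(self) -> str:
        return normalize_hgvs(self.hgvs_c)


@dataclass
class KnownVariantDB:
    """Merged known-variant lookup keyed by normalized hgvs_c."""

    entries: dict[str, KnownVariantEntry] = field(default_factory=dict)
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def _by_genomic_key(self, key: VariantKey) -> Optional[KnownVariantEntry]:
        for entry in self.entries.values():
            if entry.key == key:
                return entry
        return None

    @classmethod
    def from_entries(cls, entries: Iterable[KnownVariantEntry]) -> "KnownVariantDB":
        db = cls()
        for entry in entries:
            db.entries[entry.match_key] = entry
        db.provenance = _source_counts(db.entries.values())
        return db


def _source_counts(entries: Iterable[KnownVariantEntry]) -> dict[str, int]:
    counts = {s: 0 for s in SOURCES}
    for entry in entries:
        for source in entry.sources:
            counts[source] += 1
    return counts


# ---------------------------------------------------------------------------
# TSV loading
# ---------------------------------------------------------------------------

KB_COLUMNS = (
    "hgvs_c",
    "chrom",
    "pos",
    "ref",
    "alt",
    "vwd_type",
    "inheritance",
    "sources",
    "clear_association",
    "literature_override",
)


def load_known_variants(path: str) -> list[KnownVariantEntry]:
    """Load a knowledge-base TSV (columns per :data:`KB_COLUMNS`).

    ``sources`` is a semicolon-separated subset of HGMD;LOVD,
    ``clear_association`` is 0/1, genomic key columns are optional.
    """
    entries: list[KnownVariantEntry] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [c for c in ("hgvs_c", "vwd_type", "inheritance", "sources", "clear_association") if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        for line_no, row in enumerate(reader, start=2):
            try:
                key = None
                if row.get("chrom", "").strip() and row.get("pos", "").strip():
                    key = VariantKey(
                        chrom=row["chrom"].strip(),
                        pos=int(row["pos"]),
                        ref=row["ref"].strip(),
                        alt=row["alt"].strip(),
                    )
                override = row.get("literature_override", "").strip()
                entries.append(
                    KnownVariantEntry(
                        hgvs_c=row["hgvs_c"].strip(),
                        vwd_type=normalize_vwd_type(row["vwd_type"]),
                        inheritance=row["inheritance"].strip() or "unknown",
                        sources=frozenset(s.strip() for s in row["sources"].split(";") if s.strip()),
                        clear_association=row["clear_association"].strip() == "1",
                        key=key,
                        literature_override=normalize_vwd_type(override) if override else None,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}, line {line_no}: {exc}") from None
    return entries


def write_known_variants(entries: Sequence[KnownVariantEntry], path: str) -> None:
    """Write entries to the knowledge-base TSV schema."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(KB_COLUMNS)
        for e in entries:
            writer.writerow(
                [
                    e.hgvs_c,
                    e.key.chrom if e.key else "",
                    e.key.pos if e.key else "",
                    e.key.ref if e.key else "",
                    e.key.alt if e.key else "",
                    e.vwd_type,
                    e.inheritance,
                    ";".join(sorted(e.sources)),
                    "1" if e.clear_association else "0",
                    e.literature_override or "",
                ]
            )


# ---------------------------------------------------------------------------
# Merging and lookup
# ---------------------------------------------------------------------------


def _keyed(entries: Sequence[KnownVariantEntry], label: str) -> dict[str, KnownVariantEntry]:
    keyed: dict[str, KnownVariantEntry] = {}
    for entry in entries:
        if entry.match_key in keyed:
            raise ValueError(f"{label}: duplicate match key {entry.match_key!r}")
        keyed[entry.match_key] = entry
    return keyed


def _merge_pair(a: KnownVariantEntry, b: KnownVariantEntry) -> KnownVariantEntry:
    sources = a.sources | b.sources
    override = a.literature_override or b.literature_override
    if a.vwd_type == b.vwd_type:
        vwd_type = a.vwd_type
    elif override is not None:
        vwd_type = override
    else:
        vwd_type = "UC"
    clear = (a.clear_association and b.clear_association) or override is not None
    inheritance = a.inheritance if a.inheritance != "unknown" else b.inheritance
    return replace(
        a,
        vwd_type=vwd_type,
        inheritance=inheritance,
        sources=sources,
        clear_association=clear,
        key=a.key or b.key,
        literature_override=override,
    )


def merge_sources(
    hgmd: Sequence[KnownVariantEntry],
    lovd: Sequence[KnownVariantEntry],
) -> KnownVariantDB:
    """Union two source tables by match key.

    Agreement on VWD type is kept; disagreement resolves to the
    literature override when one is present, else to UC.  Sources are
    unioned and ``clear_association`` is the conjunction unless an override
    asserts a type (an override implies the literature settled the call).
    """
    merged = _keyed(hgmd, "hgmd")
    for match_key, entry in _keyed(lovd, "lovd").items():
        if match_key in merged:
            merged[match_key] = _merge_pair(merged[match_key], entry)
        else:
            merged[match_key] = entry
    db = KnownVariantDB(entries=merged, provenance=_source_counts(merged.values()))
    return db


def lookup(db: KnownVariantDB, record: VariantRecord) -> Optional[KnownVariantEntry]:
    """Find the known-variant entry for a cohort record, if clearly associated.

    Matches by normalized hgvs_c first, then by genomic key.  Entries with
    ``clear_association=False`` are never returned.
    """
    entry = db.entries.get(normalize_hgvs(record.hgvs_c))
    if entry is None:
        entry = db._by_genomic_key(record.key)
    if entry is None or not entry.clear_association:
        return None
    return entry
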