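"""VWF protein-domain mapping and VWD-type/domain distribution crosstabs.

The VWF pre-pro-monomer is 2813 amino acids: a 22-aa signal peptide, the
741-aa propeptide (domains D1-D2, residues 23..763), and the 2050-aa mature
subunit with domain order D'-D3-A1-A2-A3-D4-C1-C2-C3-C4-C5-C6-CK.

Residue-level domain boundaries vary between annotation schemes, so the
:class:`DomainMap` is configuration data: the shipped default
(:func:`default_domain_map`) covers 1..2813 contiguously with commonly used
boundaries, and any ordered, gap-free list of ``(label, start, end)``
intervals can be supplied instead.  A position belongs to exactly one
domain; junction annotations are not modelled.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from vwdprev.cohort import VariantRecord
from vwdprev.pathogenicity import ClassificationResult

__all__ = [
    "VWF_LENGTH",
    "DomainMap",
    "default_domain_map",
    "distribution_report",
    "domain_of",
    "parse_protein_position",
]

VWF_LENGTH = 2813
SIGNAL_PEPTIDE_END = 22
PROPEPTIDE_END = 763  # 22 + 741

DOMAIN_ORDER = ("SP", "D1", "D2", "D'", "D3", "A1", "A2", "A3", "D4", "C1", "C2", "C3", "C4", "C5", "C6", "CK")

# Default residue boundaries. SP/propeptide/mature spans are fixed by the
# precursor architecture; internal boundaries follow commonly used VWF
# annotation and are overridable via DomainMap configuration.
_DEFAULT_INTERVALS = (
    ("SP", 1, 22),
    ("D1", 23, 386),
    ("D2", 387, 763),
    ("D'", 764, 865),
    ("D3", 866, 1270),
    ("A1", 1271, 1479),
    ("A2", 1480, 1672),
    ("A3", 1673, 1874),
    ("D4", 1875, 2255),
    ("C1", 2256, 2328),
    ("C2", 2329, 2399),
    ("C3", 2400, 2516),
    ("C4", 2517, 2577),
    ("C5", 2578, 2646),
    ("C6", 2647, 2722),
    ("CK", 2723, 2813),
)


@dataclass(frozen=True)
class DomainMap:
    """Ordered, contiguous partition of residues 1..2813 into domain labels."""

    intervals: tuple[tuple[str, int, int], ...]
    provenance: str = "default"

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("domain map must contain at least one interval")
        labels = [label for label, _s, _e in self.intervals]
        order = [l for l in DOMAIN_ORDER if l in labels]
        if labels != order:
            raise ValueError(f"domain labels must follow the order {DOMAIN_ORDER}, got {labels}")
        expected_start = 1
        for label, start, end in self.intervals:
            if start != expected_start:
                raise ValueError(f"domain {label}: starts at {start}, expected {expected_start} (gap/overlap)")
            if end < start:
                raise ValueError(f"domain {label}: end {end} < start {start}")
            expected_start = end + 1
        if expected_start != VWF_LENGTH + 1:
            raise ValueError(f"domain map covers 1..{expected_start - 1}, expected 1..{VWF_LENGTH}")
        if self.intervals[0][0] == "SP" and self.intervals[0][2] != SIGNAL_PEPTIDE_END:
            raise ValueError(f"signal peptide must span 1..{SIGNAL_PEPTIDE_END}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _s, _e in self.intervals)

    @classmethod
    def from_config(cls, intervals: Sequence[Sequence], provenance: str = "config") -> "DomainMap":
        return cls(tuple((str(l), int(s), int(e)) for l, s, e in intervals), provenance=provenance)


def default_domain_map() -> DomainMap:
    return DomainMap(_DEFAULT_INTERVALS, provenance="default")


_HGVS_P = re.compile(r"^p\.(?:\()?([A-Z][a-z]{2}|\*)(\d+)")


def parse_protein_position(hgvs_p: str) -> int:
    """First affected residue of a p. HGVS string.

    Handles substitutions (p.Arg854Gln), deletions/duplications
    (p.Thr1034del — the start of the range is returned), frameshifts and
    stop changes.  Raises ValueError on unparseable strings.
    """
    match = _HGVS_P.match(hgvs_p.strip())
    if not match:
        raise ValueError(f"cannot parse protein position from {hgvs_p!r}")
    return int(match.group(2))


def domain_of(domain_map: DomainMap, aa_position: int) -> str:
    """Label of the unique domain interval covering a residue position."""
    if not 1 <= aa_position <= VWF_LENGTH:
        raise ValueError(f"aa position must be in 1..{VWF_LENGTH}, got {aa_position}")
    starts = [start for _l, start, _e in domain_map.intervals]
    idx = bisect.bisect_right(starts, aa_position) - 1
    return domain_map.intervals[idx][0]


def distribution_report(
    records: Sequence[VariantRecord],
    results: Sequence[ClassificationResult],
    domain_map: Optional[DomainMap] = None,
) -> dict[str, pd.DataFrame]:
    """Distribution crosstabs over the pathogenic subset of a cohort.

    Returns:

    * ``consequence_by_status`` — consequence class × novel/reported;
    * ``vwd_type_marginal`` — counts per VWD type (reported variants only;
      novel variants have no established type);
    * ``vwd_type_by_domain`` — VWD type × VWF domain; variants without a
      protein-level HGVS string (e.g. pure intronic) are binned as
      ``non-coding``.

    Marginals are conserved: each table's grand total equals the number of
    pathogenic records contributing to it.
    """
    domain_map = domain_map or default_domain_map()
    rows = []
    for rec, res in zip(records, results):
        if not res.pathogenic:
            continue
        if rec.hgvs_p:
            domain = domain_of(domain_map, parse_protein_position(rec.hgvs_p))
        else:
            domain = "non-coding"
        rows.append(
            {
                "consequence": rec.consequence.value,
                "status": res.status,
                "vwd_type": res.vwd_type,
                "domain": domain,
            }
        )
    frame = pd.DataFrame(rows, columns=["consequence", "status", "vwd_type", "domain"])
    typed = frame.dropna(subset=["vwd_type"])
    return {
        "consequence_by_status": pd.crosstab(frame["consequence"], frame["status"]) if len(frame) else pd.DataFrame(),
        "vwd_type_marginal": typed["vwd_type"].value_counts().to_frame("n") if len(typed) else pd.DataFrame(),
        "vwd_type_by_domain": pd.crosstab(typed["vwd_type"], typed["domain"]) if len(typed) else pd.DataFrame(),
    }
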