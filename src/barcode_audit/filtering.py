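"""Reference-library inclusion rules and pseudogene screening.

A curated COI reference library keeps only records that are usable as
species-level references: long enough (> 300 bp by default), carrying a
species name and a cluster (BIN) assignment, free of contamination /
stop-codon / indel flags, not tag-coded (informal lineage suffixes such
as "Tharyx sp. CIRR-IK-2019-1" inflate apparent species counts), and
free of internal stop codons under the invertebrate mitochondrial code
(a NUMT/pseudogene signal).  Rules are applied in a fixed order and each
rejected record is charged to the first rule it fails, so the rejection
accounting always balances.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from Bio.Data.IUPACData import ambiguous_dna_values

from .errors import BarcodeAuditError
from .io import AsvRecord, BarcodeRecord

#: Tag-code pattern: " sp." followed by a code token, or a trailing token
#: of >= 2 characters mixing uppercase letters / digits / hyphens after the
#: epithet.  Exposed so users can tighten it per dataset.
TAG_CODE_PATTERN = (
    r"(\bsp\.\s*\S+)|(\s(?=[A-Z0-9-]*[A-Z0-9])[A-Z0-9-]{2,}$)"
)

_DEFAULT_EXCLUDE_FLAGS = frozenset({"contamination", "stop_codon", "indel"})

#: Order in which the exclusion rules are applied.
RULE_ORDER = ("length", "species", "bin", "flags", "tag_code", "pseudogene")


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion thresholds for the reference library.

    ``genetic_code`` is an NCBI translation-table id; the default (5) is
    the invertebrate mitochondrial code used for COI.
    """

    min_length_bp: int = 300
    require_species_name: bool = True
    require_bin: bool = True
    exclude_flags: frozenset[str] = _DEFAULT_EXCLUDE_FLAGS
    exclude_tag_codes: bool = True
    genetic_code: int = 5
    screen_pseudogenes: bool = True
    any_frame: bool = False
    tag_code_pattern: str = TAG_CODE_PATTERN

    def __post_init__(self) -> None:
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")


@dataclass
class FilterReport:
    """Accounting of a filtering pass: kept + sum(rejections) = input size."""

    kept: int = 0
    rejected_by_rule: dict[str, int] = field(default_factory=dict)
    rejected_ids: dict[str, list[str]] = field(default_factory=dict)

    def charge(self, rule: str, record_id: str) -> None:
        self.rejected_by_rule[rule] = self.rejected_by_rule.get(rule, 0) + 1
        self.rejected_ids.setdefault(rule, []).append(record_id)

    @property
    def total_rejected(self) -> int:
        return sum(self.rejected_by_rule.values())

    def as_dict(self) -> dict:
        return {
            "kept": self.kept,
            "rejected_by_rule": dict(self.rejected_by_rule),
            "rejected_ids": {k: list(v) for k, v in self.rejected_ids.items()},
        }


def detect_tag_code(species_name: str, pattern: str = TAG_CODE_PATTERN) -> bool:
    """True when a species name carries an informal lineage/population code.

    Plain binomials ("Hydroides elegans") are not tag-coded; names such as
    "Tharyx sp. CIRR-IK-2019-1" or "Syllis gracilis LINEAGE-B2" are.
    """
    if not species_name:
        raise ValueError("species name must be non-empty")
    name = species_name.strip()
    return re.search(pattern, name) is not None


def _codon_is_forced_stop(codon: str, stop_codons: frozenset[str]) -> bool:
    """True iff every resolution of the (possibly ambiguous) codon is a stop.

    An ambiguous codon that *cannot* be forced to a stop (e.g. NNN) is
    treated as coding.
    """
    resolutions = [""]
    for base in codon:
        choices = ambiguous_dna_values.get(base)
        if choices is None:  # gap or unknown symbol: cannot be a stop
            return False
        resolutions = [r + c for r in resolutions for c in choices]
    return all(r in stop_codons for r in resolutions)


def screen_pseudogene(
    sequence: str, frame: int = 1, genetic_code: int = 5
) -> str:
    """Classify a sequence as ``"clean"`` or ``"internal_stop"``.

    Translation is performed in the given frame (1..3) under the given
    NCBI table; a stop codon before the final complete codon marks the
    sequence as a putative pseudogene.  Gaps are removed first; ambiguous
    codons count as stops only when every resolution is a stop.
    """
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame!r}")
    seq = sequence.replace("-", "").upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon after gap removal")
    stops = frozenset(CodonTable.unambiguous_dna_by_id[genetic_code].stop_codons)
    coding = seq[frame - 1 :]
    n_codons = len(coding) // 3
    for i in range(n_codons - 1):  # internal: everything before the final codon
        if _codon_is_forced_stop(coding[3 * i : 3 * i + 3], stops):
            return "internal_stop"
    return "clean"


def _fails_pseudogene(record: BarcodeRecord, criteria: FilterCriteria) -> bool:
    seq = record.sequence.replace("-", "")
    if len(seq) < 3:
        return False
    frames = (1, 2, 3) if criteria.any_frame else (1,)
    results = [
        screen_pseudogene(seq, frame=f, genetic_code=criteria.genetic_code)
        for f in frames
    ]
    # --any-frame accepts the record if any frame is stop-free.
    return all(r == "internal_stop" for r in results)


def _first_failing_rule(
    record: BarcodeRecord, criteria: FilterCriteria
) -> str | None:
    if record.length_bp <= criteria.min_length_bp:
        return "length"
    if criteria.require_species_name and record.species_name is None:
        return "species"
    if criteria.require_bin and record.bin_id is None:
        return "bin"
    if record.flags & criteria.exclude_flags:
        return "flags"
    if (
        criteria.exclude_tag_codes
        and record.species_name is not None
        and detect_tag_code(record.species_name, criteria.tag_code_pattern)
    ):
        return "tag_code"
    if criteria.screen_pseudogenes and _fails_pseudogene(record, criteria):
        return "pseudogene"
    return None


def filter_library(
    records: Sequence[BarcodeRecord], criteria: FilterCriteria | None = None
) -> tuple[list[BarcodeRecord], FilterReport]:
    """Apply the inclusion rules in fixed order; return kept records and
    a rejection report charging each record to its first failing rule."""
    criteria = criteria or FilterCriteria()
    report = FilterReport()
    kept: list[BarcodeRecord] = []
    for record in records:
        rule = _first_failing_rule(record, criteria)
        if rule is None:
            kept.append(record)
        else:
            report.charge(rule, record.record_id)
    report.kept = len(kept)
    assert report.kept + report.total_rejected == len(records)
    return kept, report


def filter_asvs(asvs: Iterable[AsvRecord], min_reads: int = 10) -> list[AsvRecord]:
    """Drop low-abundance ASVs: keep those with total_reads >= min_reads.

    The default 10 removes ASVs with fewer than 10 reads across all
    samples, the conventional noise floor for COI metabarcoding tables.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    return [a for a in asvs if a.total_reads >= min_reads]


class FilterError(BarcodeAuditError):
    pass


__all__ = [
    "FilterCriteria",
    "FilterReport",
    "TAG_CODE_PATTERN",
    "RULE_ORDER",
    "detect_tag_code",
    "screen_pseudogene",
    "filter_library",
    "filter_asvs",
]
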