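"""Checklist gap analysis: which regionally reported taxa are barcoded.

A checklist species counts as barcoded when its canonical name (or any
of its synonyms) appears among the species names of the filtered
reference library.  A genus or family counts as barcoded when at least
one of its checklist species is barcoded, or when the library holds any
record of that genus/family (the rank value being part of the
checklist's vocabulary) - this is why rank-level coverage typically
exceeds species-level coverage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .audit import round_half_up
from .io import BarcodeRecord, ChecklistEntry

_SUBGENUS = re.compile(r"\s*\([^)]*\)")
_WS = re.compile(r"\s+")


def canonicalise(name: str, synonym_map: Mapping[str, str] | None = None) -> str:
    """Normalise a species name for comparison.

    Trims and collapses whitespace, removes parenthesised chunks
    (subgenera like "(P.)" and authorships like "(Haswell, 1883)"), and
    truncates at a bare authorship - the first capitalised token after
    the genus, e.g. "Linnaeus, 1758" (epithets are always lowercase).
    Finally maps through *synonym_map* when present.
    """
    if not name:
        raise ValueError("name must be non-empty")
    text = _SUBGENUS.sub(" ", name)
    text = _WS.sub(" ", text).strip()
    tokens = text.split(" ")
    kept = tokens[:1]
    for token in tokens[1:]:
        if token[:1].isupper():
            break
        kept.append(token)
    text = " ".join(kept)
    if synonym_map and text in synonym_map:
        text = synonym_map[text]
    return text


@dataclass
class RankCoverage:
    total_in_checklist: int
    n_barcoded: int
    percent_barcoded: float


@dataclass
class CoverageReport:
    """Coverage at species/genus/family rank plus a per-family breakdown."""

    species: RankCoverage
    genus: RankCoverage
    family: RankCoverage
    by_family: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    #: family -> (n_species_total, n_species_barcoded, n_sequences)

    def as_dict(self) -> dict:
        return {
            rank: vars(getattr(self, rank))
            for rank in ("species", "genus", "family")
        } | {"by_family": {k: list(v) for k, v in self.by_family.items()}}


def _percent(n: int, total: int, digits: int) -> float:
    return round_half_up(100.0 * n / total, digits) if total else 0.0


def coverage(
    checklist: Sequence[ChecklistEntry],
    library: Iterable[BarcodeRecord],
    synonym_map: Mapping[str, str] | None = None,
    percent_digits: int = 0,
) -> CoverageReport:
    """Cross-reference a checklist against a filtered reference library."""
    if not checklist:
        raise ValueError("checklist must be non-empty")
    library = list(library)

    # Canonical species names present in the library, plus the genus/family
    # vocabulary observed on library records.
    library_species = {
        canonicalise(r.species_name, synonym_map)
        for r in library
        if r.species_name
    }
    library_genera = {r.taxonomy.genus for r in library if r.taxonomy.genus}
    library_families = {r.taxonomy.family for r in library if r.taxonomy.family}

    checklist_genera = {e.genus for e in checklist if e.genus}
    checklist_families = {e.family for e in checklist if e.family}

    barcoded_species: set[str] = set()
    barcoded_genera: set[str] = set()
    barcoded_families: set[str] = set()
    species_seen: set[str] = set()
    fam_species: dict[str, set[str]] = {}
    fam_barcoded: dict[str, set[str]] = {}
    for entry in checklist:
        names = {canonicalise(entry.species_name, synonym_map)} | {
            canonicalise(s, synonym_map) for s in entry.synonyms
        }
        canonical = canonicalise(entry.species_name, synonym_map)
        species_seen.add(canonical)
        fam_species.setdefault(entry.family, set()).add(canonical)
        if names & library_species:
            barcoded_species.add(canonical)
            fam_barcoded.setdefault(entry.family, set()).add(canonical)
            if entry.genus:
                barcoded_genera.add(entry.genus)
            if entry.family:
                barcoded_families.add(entry.family)
    # Rank-level evidence straight from library records.
    barcoded_genera |= checklist_genera & library_genera
    barcoded_families |= checklist_families & library_families

    by_family: dict[str, tuple[int, int, int]] = {}
    for family in sorted(fam_species):
        n_seq = sum(1 for r in library if r.taxonomy.family == family)
        by_family[family] = (
            len(fam_species[family]),
            len(fam_barcoded.get(family, set())),
            n_seq,
        )

    return CoverageReport(
        species=RankCoverage(
            len(species_seen),
            len(barcoded_species),
            _percent(len(barcoded_species), len(species_seen), percent_digits),
        ),
        genus=RankCoverage(
            len(checklist_genera),
            len(barcoded_genera),
            _percent(len(barcoded_genera), len(checklist_genera), percent_digits),
        ),
        family=RankCoverage(
            len(checklist_families),
            len(barcoded_families),
            _percent(len(barcoded_families), len(checklist_families), percent_digits),
        ),
        by_family=by_family,
    )


__all__ = ["canonicalise", "RankCoverage", "CoverageReport", "coverage"]
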