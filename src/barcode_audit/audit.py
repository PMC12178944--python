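"""Cluster discordance reporting and BAGS A-E species grading.

Works over any cluster labelling: BOLD BIN ids carried on the records,
or a computed MOTU partition.

Cluster status
    singleton   exactly one record in the cluster
    discordant  more than one nominal species name in the cluster
    concordant  otherwise (one named species; the same species may well
                occur in several clusters without being discordant)

BAGS grades, decided per nominal species in this order:
    E  any of its clusters also contains another species (misidentification
       or para/polyphyly signal)
    D  fewer than 3 specimens (insufficient data)
    C  more than one cluster, each exclusive to the species (cryptic
       species complex candidate)
    A  one exclusive cluster and more than 10 specimens
    B  one exclusive cluster and 10 or fewer specimens

D is tested before C so that a data-poor species split over several
clusters is reported as insufficient-data rather than cryptic; the
order is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError

#: (record_id, cluster_id, species_name or None)
Assignment = tuple[str, str, str | None]

GRADES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class ClusterStatus:
    cluster_id: str
    status: str  # singleton | concordant | discordant
    species_in_cluster: frozenset[str]
    n_records: int


@dataclass(frozen=True)
class SpeciesGrade:
    species_name: str
    grade: str
    n_specimens: int
    n_clusters: int
    clusters_exclusive: bool
    rationale: str


@dataclass
class AuditSummary:
    """Counts (and half-up rounded percentages) per status and per grade."""

    status_counts: dict[str, int] = field(default_factory=dict)
    status_percent: dict[str, float] = field(default_factory=dict)
    grade_counts: dict[str, int] = field(default_factory=dict)
    grade_percent: dict[str, float] = field(default_factory=dict)
    n_clusters: int = 0
    n_species: int = 0
    ratio_clusters_to_species: float | None = None

    def as_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "n_species": self.n_species,
            "status_counts": dict(self.status_counts),
            "status_percent": dict(self.status_percent),
            "grade_counts": dict(self.grade_counts),
            "grade_percent": dict(self.grade_percent),
            "ratio_clusters_to_species": self.ratio_clusters_to_species,
        }


def round_half_up(value: float, digits: int = 0) -> float:
    """Round with ties away from zero, as printed reports conventionally do."""
    factor = 10**digits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


def assignments_from_records(
    records: Iterable, membership: Mapping[str, str] | None = None
) -> list[Assignment]:
    """Build (id, cluster, species) triples from records.

    *membership* maps record id to a computed cluster id; without it the
    record's own ``bin_id`` is used as the cluster label.
    """
    triples: list[Assignment] = []
    for r in records:
        cluster = membership.get(r.record_id) if membership else r.bin_id
        if cluster is None:
            raise ValidationError(f"record {r.record_id} has no cluster label")
        triples.append((r.record_id, str(cluster), r.species_name))
    return triples


def discordance_report(
    assignments: Sequence[Assignment], percent_digits: int = 0
) -> tuple[list[ClusterStatus], AuditSummary]:
    """Per-cluster singleton/concordant/discordant statuses with a summary.

    Percentages are shares of the total cluster count, rounded half-up at
    *percent_digits* (integer precision by default).
    """
    clusters: dict[str, list[Assignment]] = {}
    for triple in assignments:
        record_id, cluster_id, _ = triple
        if cluster_id is None or cluster_id == "":
            raise ValidationError(f"record {record_id} has no cluster label")
        clusters.setdefault(cluster_id, []).append(triple)

    statuses: list[ClusterStatus] = []
    for cluster_id in sorted(clusters):
        members = clusters[cluster_id]
        names = frozenset(s for _, _, s in members if s is not None)
        if len(members) == 1:
            status = "singleton"
        elif len(names) > 1:
            status = "discordant"
        else:
            status = "concordant"
        statuses.append(
            ClusterStatus(
                cluster_id=cluster_id,
                status=status,
                species_in_cluster=names,
                n_records=len(members),
            )
        )

    summary = AuditSummary(n_clusters=len(statuses))
    for st in ("concordant", "discordant", "singleton"):
        count = sum(1 for c in statuses if c.status == st)
        summary.status_counts[st] = count
        if statuses:
            summary.status_percent[st] = round_half_up(
                100.0 * count / len(statuses), percent_digits
            )
    return statuses, summary


_DEFAULT_GRADE_ORDER = ("E", "D", "C", "AB")


def grade_species(
    assignments: Sequence[Assignment],
    grade_order: Sequence[str] = _DEFAULT_GRADE_ORDER,
) -> list[SpeciesGrade]:
    """Grade every named species A-E from its specimen and cluster profile.

    All records must carry species names (tag-coded and unnamed records
    are removed by upstream filtering).
    """
    unnamed = [rid for rid, _, sp in assignments if sp is None]
    if unnamed:
        raise ValidationError(f"unnamed records reached grading: {unnamed[:5]!r}")

    cluster_species: dict[str, set[str]] = {}
    species_clusters: dict[str, set[str]] = {}
    species_count: dict[str, int] = {}
    for _, cluster_id, species in assignments:
        cluster_species.setdefault(cluster_id, set()).add(species)
        species_clusters.setdefault(species, set()).add(cluster_id)
        species_count[species] = species_count.get(species, 0) + 1

    grades: list[SpeciesGrade] = []
    for species in sorted(species_count):
        n = species_count[species]
        own_clusters = species_clusters[species]
        exclusive = all(cluster_species[c] == {species} for c in own_clusters)

        grade = rationale = None
        for rule in grade_order:
            if rule == "E" and not exclusive:
                grade, rationale = "E", "shares a cluster with another species"
            elif rule == "D" and n < 3:
                grade, rationale = "D", f"only {n} specimen(s) available"
            elif rule == "C" and len(own_clusters) > 1:
                grade, rationale = "C", (
                    f"split over {len(own_clusters)} exclusive clusters"
                )
            elif rule == "AB":
                if n > 10:
                    grade, rationale = "A", f"{n} specimens in one exclusive cluster"
                else:
                    grade, rationale = "B", f"{n} specimens in one exclusive cluster"
            if grade:
                break
        grades.append(
            SpeciesGrade(
                species_name=species,
                grade=grade,
                n_specimens=n,
                n_clusters=len(own_clusters),
                clusters_exclusive=exclusive,
                rationale=rationale,
            )
        )
    return grades


def summarise_grades(
    grades: Sequence[SpeciesGrade], percent_digits: int = 1
) -> tuple[dict[str, int], dict[str, float]]:
    """Grade counts and half-up percentages over species (one decimal
    by default, the precision such reports conventionally print)."""
    counts = {g: 0 for g in GRADES}
    for sg in grades:
        counts[sg.grade] += 1
    total = len(grades)
    percents = {
        g: round_half_up(100.0 * c / total, percent_digits) if total else 0.0
        for g, c in counts.items()
    }
    return counts, percents


def ratio_clusters_to_species(
    n_clusters: int, n_species: int, precision_mode: str = "full"
) -> float:
    """Cluster-to-species ratio; ``truncate2`` truncates (not rounds) to two
    decimals, matching how such ratios are conventionally quoted."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    ratio = n_clusters / n_species
    if precision_mode == "truncate2":
        return math.floor(ratio * 100) / 100
    if precision_mode == "full":
        return ratio
    raise ValueError(f"unknown precision mode {precision_mode!r}")


def motus_per_group(
    memberships: Iterable[tuple[str, str]]
) -> tuple[dict[str, int], int]:
    """Distinct-MOTU count per taxonomic group from (motu, group) pairs.

    A discordant MOTU (members labelled to different groups) is counted
    once under each group it touches, so the per-group counts can sum to
    more than the number of distinct MOTUs.  Returns the per-group map
    and the distinct-MOTU total.
    """
    groups: dict[str, set[str]] = {}
    all_motus: set[str] = set()
    for motu, group in memberships:
        groups.setdefault(group, set()).add(motu)
        all_motus.add(motu)
    return {g: len(m) for g, m in sorted(groups.items())}, len(all_motus)


def audit_summary(
    assignments: Sequence[Assignment],
    status_percent_digits: int = 0,
    grade_percent_digits: int = 1,
) -> tuple[list[ClusterStatus], list[SpeciesGrade], AuditSummary]:
    """Full audit: statuses, grades (over named records) and one summary."""
    statuses, summary = discordance_report(assignments, status_percent_digits)
    named = [t for t in assignments if t[2] is not None]
    grades = grade_species(named) if named else []
    summary.grade_counts, summary.grade_percent = summarise_grades(
        grades, grade_percent_digits
    )
    summary.n_species = len(grades)
    if grades:
        summary.ratio_clusters_to_species = ratio_clusters_to_species(
            summary.n_clusters, summary.n_species, "full"
        )
    return statuses, grades, summary


__all__ = [
    "Assignment",
    "ClusterStatus",
    "SpeciesGrade",
    "AuditSummary",
    "GRADES",
    "round_half_up",
    "assignments_from_records",
    "discordance_report",
    "grade_species",
    "summarise_grades",
    "ratio_clusters_to_species",
    "motus_per_group",
    "audit_summary",
]
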