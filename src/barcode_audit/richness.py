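"""Species-richness extrapolation and MOTU taxonomy refinement.

Richness: when a metabarcoding dataset yields MOTUs but few species-level
identifications, the MOTU/species ratio observed in a fully identified
reference library calibrates an extrapolation:

    X = n_query_motus * n_ref_species / n_ref_motus
      = n_query_motus / ratio,   ratio = n_ref_motus / n_ref_species

Consensus refinement: ASVs inside one MOTU often carry taxonomic labels
of uneven depth and occasional misassignments.  A weighted majority-rule
walk down the ranks keeps the deepest label supported by at least
``min_share`` of the (labelled) members; members conflicting with the
consensus path are flagged as outliers and optionally excluded once.
The strict-unanimity special case coincides with the lowest common
ancestor (LCA) of the member taxonomies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import single_linkage_partition
from .distances import DistanceMatrix
from .errors import ValidationError
from .io import RANKS, Taxonomy


@dataclass
class RichnessEstimate:
    n_query_motus: int
    n_ref_motus: int
    n_ref_species: int
    ratio: float
    estimate: int
    precision_mode: str
    bootstrap_interval: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        return {
            "n_query_motus": self.n_query_motus,
            "n_ref_motus": self.n_ref_motus,
            "n_ref_species": self.n_ref_species,
            "ratio": self.ratio,
            "estimate": self.estimate,
            "precision_mode": self.precision_mode,
            "bootstrap_interval": list(self.bootstrap_interval)
            if self.bootstrap_interval
            else None,
        }


def estimate_richness(
    n_query_motus: int,
    n_ref_motus: int,
    n_ref_species: int,
    precision_mode: str = "truncate2",
    motus_per_species: Sequence[int] | None = None,
    bootstrap: int = 0,
    seed: int | None = None,
) -> RichnessEstimate:
    """Extrapolate species richness from a MOTU count via a reference ratio.

    ``truncate2`` (default) truncates the ratio to two decimals before
    dividing, mirroring how such ratios are quoted; ``full`` keeps the
    exact ratio.  The estimate itself is truncated to an integer.

    With *bootstrap* > 0 and *motus_per_species* (per-reference-species
    MOTU counts), species are resampled with replacement and a 95%
    percentile interval of the estimate is attached.
    """
    if min(n_query_motus, n_ref_motus, n_ref_species) < 1:
        raise ValueError("all counts must be >= 1")
    if precision_mode == "truncate2":
        ratio = math.floor(100 * n_ref_motus / n_ref_species) / 100
        estimate = int(n_query_motus / ratio)
    elif precision_mode == "full":
        ratio = n_ref_motus / n_ref_species
        estimate = int(n_query_motus * n_ref_species / n_ref_motus)
    else:
        raise ValueError(f"unknown precision mode {precision_mode!r}")

    interval = None
    if bootstrap > 0:
        if motus_per_species is None:
            raise ValueError(
                "bootstrap requires per-species MOTU counts (motus_per_species)"
            )
        counts = np.asarray(motus_per_species, dtype=float)
        if len(counts) != n_ref_species:
            raise ValueError("motus_per_species length must equal n_ref_species")
        rng = np.random.default_rng(seed)
        estimates = np.empty(bootstrap)
        for b in range(bootstrap):
            resampled = counts[rng.integers(0, len(counts), len(counts))]
            r = resampled.sum() / len(counts)
            if precision_mode == "truncate2":
                r = math.floor(100 * r) / 100
            estimates[b] = int(n_query_motus / r) if r > 0 else float("nan")
        low, high = np.nanpercentile(estimates, [2.5, 97.5])
        interval = (float(low), float(high))

    return RichnessEstimate(
        n_query_motus=n_query_motus,
        n_ref_motus=n_ref_motus,
        n_ref_species=n_ref_species,
        ratio=ratio,
        estimate=estimate,
        precision_mode=precision_mode,
        bootstrap_interval=interval,
    )


# ---------------------------------------------------------------------------
# Consensus taxonomy


@dataclass
class ConsensusAssignment:
    motu_id: str
    consensus_taxonomy: Taxonomy
    agreement_rank: str | None
    support_share: float
    flags: frozenset[str]
    matched_species: str | None = None


def lca_taxonomy(taxonomies: Sequence[Taxonomy]) -> Taxonomy:
    """Lowest common ancestor: deepest rank on which all inputs agree.

    An input lacking a label at a rank counts as disagreement at that
    rank; fully disjoint inputs yield an empty taxonomy.
    """
    if not taxonomies:
        raise ValueError("need at least one taxonomy")
    agreed: str | None = None
    for rank in RANKS:
        labels = {t.get(rank) for t in taxonomies}
        if len(labels) == 1 and None not in labels:
            agreed = rank
        else:
            break
    return taxonomies[0].truncated_to(agreed)


def _rank_shares(
    members: Sequence[tuple[Taxonomy, float]], rank: str
) -> dict[str, float]:
    """Weighted share of each label at a rank.

    The denominator is the total member weight: a member with no label at
    this rank counts against consensus, so strict unanimity (min_share=1)
    coincides with the lowest common ancestor.
    """
    weights: dict[str, float] = {}
    total = 0.0
    for taxonomy, weight in members:
        total += weight
        label = taxonomy.get(rank)
        if label is not None:
            weights[label] = weights.get(label, 0.0) + weight
    return {label: w / total for label, w in weights.items()} if total else {}


def consensus_taxonomy(
    motu_id: str,
    members: Sequence[tuple[Taxonomy, float]],
    min_share: float = 0.6,
    outlier_rule: str = "exclude",
) -> ConsensusAssignment:
    """Majority-rule consensus taxonomy of one MOTU's members.

    Walks ranks from phylum down; at each rank the label with weighted
    share >= *min_share* of the total member weight is kept, otherwise
    the walk stops.  Members that conflict with the consensus
    path at a rank where consensus held are flagged as outliers; under
    ``outlier_rule="exclude"`` they are removed and shares recomputed
    once (a single round keeps the operation order-independent).
    """
    if not members:
        raise ValueError("MOTU has no members")
    if not (0.5 < min_share <= 1.0):
        raise ValueError("min_share must lie in (0.5, 1]")
    if outlier_rule not in ("exclude", "keep"):
        raise ValueError(f"unknown outlier rule {outlier_rule!r}")

    # Discordance is judged before any exclusion, at family rank or above.
    discordant = False
    for rank in RANKS[: RANKS.index("family") + 1]:
        labels = {t.get(rank) for t, _ in members if t.get(rank) is not None}
        if len(labels) > 1:
            discordant = True
            break

    def walk(current: Sequence[tuple[Taxonomy, float]]):
        path: dict[str, str] = {}
        share_at: dict[str, float] = {}
        for rank in RANKS:
            shares = _rank_shares(current, rank)
            winners = sorted(
                (label for label, s in shares.items() if s >= min_share)
            )
            if not winners:
                break
            label = winners[0]  # lexicographic tie-break, logged upstream
            path[rank] = label
            share_at[rank] = shares[label]
        return path, share_at

    path, share_at = walk(members)

    def conflicts(taxonomy: Taxonomy) -> bool:
        return any(
            taxonomy.get(rank) is not None and taxonomy.get(rank) != label
            for rank, label in path.items()
        )

    outliers = [m for m in members if conflicts(m[0])]
    flags = set()
    if discordant:
        flags.add("discordant")
    if outliers:
        flags.add("outliers_excluded")
        if outlier_rule == "exclude":
            retained = [m for m in members if not conflicts(m[0])]
            if retained:
                path, share_at = walk(retained)

    deepest = None
    for rank in RANKS:
        if rank in path:
            deepest = rank
    consensus = Taxonomy.from_labels({r: path.get(r) for r in RANKS})
    return ConsensusAssignment(
        motu_id=motu_id,
        consensus_taxonomy=consensus,
        agreement_rank=deepest,
        support_share=share_at.get(deepest, 0.0) if deepest else 0.0,
        flags=frozenset(flags),
    )


def consensus_for_partition(
    membership: Mapping[str, str],
    taxonomy_of: Mapping[str, Taxonomy],
    weights: Mapping[str, float] | None = None,
    min_share: float = 0.6,
    outlier_rule: str = "exclude",
) -> list[ConsensusAssignment]:
    """Consensus assignment for every MOTU of a partition.

    Weights default to 1 per ASV: read abundance is not evidence of
    identification quality.  MOTUs whose consensus species label recurs
    in other MOTUs are flagged ``cryptic_candidate``.
    """
    motus: dict[str, list[tuple[Taxonomy, float]]] = {}
    for member, motu in membership.items():
        weight = 1.0 if weights is None else float(weights.get(member, 1.0))
        motus.setdefault(motu, []).append((taxonomy_of[member], weight))
    results = [
        consensus_taxonomy(motu, members, min_share, outlier_rule)
        for motu, members in sorted(motus.items())
    ]
    species_motus: dict[str, int] = {}
    for res in results:
        sp = res.consensus_taxonomy.species
        if sp:
            species_motus[sp] = species_motus.get(sp, 0) + 1
    for i, res in enumerate(results):
        sp = res.consensus_taxonomy.species
        if sp and species_motus[sp] > 1:
            results[i] = ConsensusAssignment(
                motu_id=res.motu_id,
                consensus_taxonomy=res.consensus_taxonomy,
                agreement_rank=res.agreement_rank,
                support_share=res.support_share,
                flags=res.flags | {"cryptic_candidate"},
                matched_species=res.matched_species,
            )
    return results


# ---------------------------------------------------------------------------
# Similarity-hit filtering and distance-based reference matching


def filter_hits(
    hits: pd.DataFrame, min_identity: float = 95.0, min_cover: float = 90.0
) -> pd.DataFrame:
    """Keep similarity-search hits with identity and query cover above the
    thresholds (defaults 95% / 90%, the standard species-assignment cut)."""
    required = {"query", "subject", "identity", "query_cover"}
    missing = required - set(hits.columns)
    if missing:
        raise ValidationError(f"hit table missing columns {sorted(missing)!r}")
    ident = pd.to_numeric(hits["identity"], errors="coerce")
    cover = pd.to_numeric(hits["query_cover"], errors="coerce")
    bad = hits.index[ident.isna() | cover.isna()]
    if len(bad):
        raise ValidationError(f"malformed hit rows at index {list(bad[:5])!r}")
    if ((ident < 0) | (ident > 100) | (cover < 0) | (cover > 100)).any():
        raise ValidationError("identity/cover percentages must lie in [0, 100]")
    return hits[(ident >= min_identity) & (cover >= min_cover)].copy()


@dataclass(frozen=True)
class ReferenceMatch:
    query_id: str
    species: tuple[str, ...]  # empty = no match; >1 = ambiguous
    min_distance: float | None
    ambiguous: bool


def match_to_reference(
    query_ids: Sequence[str],
    reference_species: Mapping[str, str],
    matrix: DistanceMatrix,
    max_distance: float = 0.05,
    reference_priority: Mapping[str, tuple[bool, bool]] | None = None,
) -> dict[str, ReferenceMatch]:
    """Match queries to reference species by < *max_distance* K2P linkage.

    A query matches a species when single-linkage clustering at the
    (strict) distance cut places it in a cluster containing references of
    that species; several species in the cluster yield an ambiguous match
    listing all names.  *reference_priority* maps reference id to
    (published, in_region) flags; among ambiguous matches, species backed
    by published and in-region references are listed first.
    """
    # Strict "<" cut: shrink the inclusive threshold just below max_distance.
    finite = matrix.d[np.isfinite(matrix.d)]
    below = finite[finite < max_distance]
    threshold = float(below.max()) if below.size else 0.0
    partition = single_linkage_partition(matrix, threshold)
    member_of = partition.membership()

    matches: dict[str, ReferenceMatch] = {}
    for query in query_ids:
        cluster = partition.clusters[member_of[query]]
        refs_here = [r for r in cluster if r in reference_species]
        species = sorted({reference_species[r] for r in refs_here})
        if not species:
            matches[query] = ReferenceMatch(query, (), None, False)
            continue
        qi = matrix.index(query)
        dist_to: dict[str, float] = {}
        best_priority: dict[str, tuple[int, int]] = {}
        for ref in refs_here:
            sp = reference_species[ref]
            d = float(matrix.d[qi, matrix.index(ref)])
            dist_to[sp] = min(dist_to.get(sp, float("inf")), d)
            if reference_priority is not None:
                published, in_region = reference_priority.get(ref, (False, False))
                prio = (0 if published else 1, 0 if in_region else 1)
                best_priority[sp] = min(best_priority.get(sp, (1, 1)), prio)
        if reference_priority is not None:
            species = sorted(
                species, key=lambda sp: (best_priority.get(sp, (1, 1)), sp)
            )
        matches[query] = ReferenceMatch(
            query_id=query,
            species=tuple(species),
            min_distance=min(dist_to.values()),
            ambiguous=len(species) > 1,
        )
    return matches


__all__ = [
    "RichnessEstimate",
    "estimate_richness",
    "ConsensusAssignment",
    "lca_taxonomy",
    "consensus_taxonomy",
    "consensus_for_partition",
    "filter_hits",
    "ReferenceMatch",
    "match_to_reference",
]
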