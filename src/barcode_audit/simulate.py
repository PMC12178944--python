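"""Synthetic reference libraries, checklists and ASV datasets with planted truth.

The generator emulates the statistical structure of a curated COI
library: species composed of one or more deeply divergent lineages
(cryptic complexes), small within-lineage divergence (< 2% K2P by
default) separated from between-lineage divergence (> 8% K2P) by a
clear barcode gap, plus planted faults - misidentifications (a record
carrying another species' name), tag-coded names, pseudogene records
with an in-frame stop codon, and singleton species.  ASV datasets add
read-count structure (including a low-read fraction destined for the
abundance filter) and taxonomy labels of mixed depth.

Sequences evolve under a K80 substitution process (transition /
transversion ratio 2 by default), so realised K2P distances concentrate
near their targets; divergence targets are enforced by post-hoc
verification of the realised distance matrix with rejection sampling.
Everything is reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .distances import pairwise_matrix
from .errors import GenerationError
from .io import AsvRecord, BarcodeRecord, ChecklistEntry, Taxonomy

_BASES = np.array(list("ACGT"))
#: transition partner of each base index (A<->G, C<->T)
_TRANSITION = {0: 2, 1: 3, 2: 0, 3: 1}


def _draw_count(rng: np.random.Generator, spec) -> int:
    """Draw from a count specification: int, (lo, hi) inclusive, or
    {value: probability} map."""
    if isinstance(spec, int):
        return spec
    if isinstance(spec, tuple):
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    if isinstance(spec, dict):
        values = sorted(spec)
        probs = np.array([spec[v] for v in values], dtype=float)
        return int(rng.choice(values, p=probs / probs.sum()))
    raise ValueError(f"unsupported count specification {spec!r}")


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for a synthetic reference library.

    Divergences are K2P targets: within-lineage pairwise distances stay
    at or below ``within_lineage_divergence`` and between-lineage
    distances at or above ``between_species_divergence``, so any
    clustering threshold inside the gap recovers the planted partition.
    The 313 bp default matches the standard COI metabarcoding fragment.
    """

    n_species: int = 20
    lineages_per_species: int | tuple | dict = 1
    within_lineage_divergence: float = 0.02
    between_species_divergence: float = 0.08
    n_records_per_species: int | tuple | dict = (3, 12)
    fraction_singleton: float = 0.0
    fraction_mislabelled: float = 0.0
    fraction_tag_coded: float = 0.0
    fraction_pseudogene: float = 0.0
    sequence_length: int = 313
    kappa: float = 2.0
    genera_per_family: int = 4
    species_per_genus: int = 3

    def __post_init__(self) -> None:
        for name in (
            "fraction_singleton",
            "fraction_mislabelled",
            "fraction_tag_coded",
            "fraction_pseudogene",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.within_lineage_divergence < self.between_species_divergence:
            raise ValueError("within-lineage divergence must be below between-species")
        if self.n_species < 1 or self.sequence_length < 30:
            raise ValueError("need n_species >= 1 and sequence_length >= 30")


@dataclass
class Truth:
    """Planted ground truth accompanying a simulated dataset."""

    record_species: dict[str, str] = field(default_factory=dict)
    record_lineage: dict[str, str] = field(default_factory=dict)
    partition: dict[str, frozenset[str]] = field(default_factory=dict)
    mislabels: dict[str, tuple[str, str]] = field(default_factory=dict)
    grades: dict[str, str] = field(default_factory=dict)
    tag_coded_species: set[str] = field(default_factory=set)
    pseudogene_records: set[str] = field(default_factory=set)
    singleton_species: set[str] = field(default_factory=set)
    lineage_taxonomy: dict[str, Taxonomy] = field(default_factory=dict)
    low_read_asvs: set[str] = field(default_factory=set)
    asv_true_taxonomy: dict[str, Taxonomy] = field(default_factory=dict)
    mislabelled_asvs: set[str] = field(default_factory=set)


def _mutate(
    rng: np.random.Generator, seq: np.ndarray, n_sub: int, kappa: float
) -> np.ndarray:
    """Apply n_sub substitutions at distinct sites under a K80 process."""
    out = seq.copy()
    if n_sub == 0:
        return out
    sites = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    p_transition = kappa / (kappa + 2.0)
    for site in sites:
        if rng.random() < p_transition:
            out[site] = _TRANSITION[int(out[site])]
        else:
            # two transversion partners, equally likely
            current = int(out[site])
            options = [b for b in range(4) if b != current and b != _TRANSITION[current]]
            out[site] = options[int(rng.integers(0, 2))]
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def _remove_stops(seq: np.ndarray) -> np.ndarray:
    """Repair incidental frame-1 stop codons so generated sequences are
    open reading frames, as real protein-coding COI barcodes are.

    TAA/TAG third positions are flipped to C (-> TAC, tyrosine).  Applied
    after every mutation step and before divergence verification, so the
    realised distance targets account for the repair.
    """
    out = seq.copy()
    # encoded: A=0, C=1, G=2, T=3; stops under table 5 are TAA and TAG
    for i in range(0, len(out) - 2, 3):
        if out[i] == 3 and out[i + 1] == 0 and out[i + 2] in (0, 2):
            out[i + 2] = 1
    return out


def _species_names(params: SimulationParams) -> list[tuple[str, Taxonomy]]:
    """Deterministic binomials arranged in a genus/family/order hierarchy."""
    names = []
    for i in range(params.n_species):
        genus_i = i // params.species_per_genus
        family_i = genus_i // params.genera_per_family
        order_i = family_i // 3
        genus = f"Simgenus{genus_i:03d}"
        taxonomy = Taxonomy(
            phylum="Annelida",
            class_="Polychaeta",
            order=f"Simorder{order_i:02d}",
            family=f"Simfam{family_i:02d}",
            genus=genus,
            species=f"{genus} simsp{i:03d}",
        )
        names.append((taxonomy.species, taxonomy))
    return names


def _generate_lineage_ancestors(
    rng: np.random.Generator,
    n_lineages: int,
    params: SimulationParams,
    max_retries: int = 100,
) -> list[np.ndarray]:
    """Ancestor sequences pairwise >= the between-species target.

    Each ancestor evolves from a common random root; violators of the
    realised-distance check are resampled up to *max_retries* times.
    """
    length = params.sequence_length
    root = rng.integers(0, 4, size=length)
    # Enough substitutions that two ancestors sit well beyond the gap even
    # after within-lineage noise is added on both sides.
    n_sub = math.ceil(0.75 * params.between_species_divergence * length) + 2
    floor = params.between_species_divergence + params.within_lineage_divergence

    ancestors: list[np.ndarray] = []
    for _ in range(n_lineages):
        for attempt in range(max_retries):
            candidate = _remove_stops(_mutate(rng, root, n_sub, params.kappa))
            if all(
                _k2p_of(candidate, other) >= floor for other in ancestors
            ):
                ancestors.append(candidate)
                break
        else:
            raise GenerationError(
                "could not place a lineage ancestor beyond the divergence "
                f"floor after {max_retries} retries (alphabet saturation?)"
            )
    return ancestors


def _k2p_of(a: np.ndarray, b: np.ndarray) -> float:
    from .distances import k2p_distance

    d, _ = k2p_distance(_decode(a), _decode(b))
    return d


def simulate_library(
    params: SimulationParams | None = None,
    seed: int = 0,
    max_retries: int = 100,
) -> tuple[list[BarcodeRecord], Truth]:
    """Generate a reference library with planted truth.

    The realised distance matrix is verified: all within-lineage pairwise
    K2P <= within target, all between-lineage >= between target; the
    library is regenerated on violation (bounded retries).
    """
    params = params or SimulationParams()
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        records, truth = _simulate_once(rng, params, max_retries)
        if _verify_gap(records, truth, params):
            return records, truth
    raise GenerationError(
        f"library violated its divergence targets in {max_retries} attempts"
    )


def _simulate_once(
    rng: np.random.Generator, params: SimulationParams, max_retries: int
) -> tuple[list[BarcodeRecord], Truth]:
    truth = Truth()
    species = _species_names(params)
    lineage_counts = [
        max(1, _draw_count(rng, params.lineages_per_species)) for _ in species
    ]
    ancestors = _generate_lineage_ancestors(
        rng, sum(lineage_counts), params, max_retries
    )

    n_singleton = round(params.fraction_singleton * params.n_species)
    singleton_idx = set(
        rng.choice(params.n_species, size=n_singleton, replace=False).tolist()
    ) if n_singleton else set()

    max_rec_sub = int(params.within_lineage_divergence * params.sequence_length / 2)

    records: list[BarcodeRecord] = []
    cursor = 0
    record_no = 0
    for sp_i, ((name, taxonomy), n_lin) in enumerate(zip(species, lineage_counts)):
        lineage_ids = [f"L{cursor + j:04d}" for j in range(n_lin)]
        lineage_anc = ancestors[cursor : cursor + n_lin]
        cursor += n_lin
        if sp_i in singleton_idx:
            n_rec = 1
            truth.singleton_species.add(name)
        else:
            n_rec = max(1, _draw_count(rng, params.n_records_per_species))
            n_rec = max(n_rec, n_lin)  # every lineage gets at least one record
        # round-robin over lineages so multi-lineage species are realised
        assignment = [lineage_ids[j % n_lin] for j in range(n_rec)]
        for lineage_id in assignment:
            anc = lineage_anc[lineage_ids.index(lineage_id)]
            n_sub = int(rng.integers(0, max_rec_sub + 1)) if max_rec_sub else 0
            seq = _remove_stops(_mutate(rng, anc, n_sub, params.kappa))
            record_id = f"SIM{record_no:05d}"
            record_no += 1
            records.append(
                BarcodeRecord(
                    record_id=record_id,
                    sequence=_decode(seq),
                    species_name=name,
                    taxonomy=taxonomy,
                    bin_id=lineage_id,
                    region="simulated",
                )
            )
            truth.record_species[record_id] = name
            truth.record_lineage[record_id] = lineage_id
            truth.lineage_taxonomy[lineage_id] = taxonomy

    for lineage_id in set(truth.record_lineage.values()):
        truth.partition[lineage_id] = frozenset(
            r for r, l in truth.record_lineage.items() if l == lineage_id
        )

    records = _plant_faults(rng, records, truth, params)
    _assign_planted_grades(records, truth)
    return records, truth


def _plant_faults(
    rng: np.random.Generator,
    records: list[BarcodeRecord],
    truth: Truth,
    params: SimulationParams,
) -> list[BarcodeRecord]:
    from .io import replace

    species_records: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        species_records.setdefault(r.species_name, []).append(i)
    all_species = sorted(species_records)

    # Tag codes: a fraction of species carry informal lineage codes.
    n_tag = round(params.fraction_tag_coded * len(all_species))
    if n_tag:
        for name in rng.choice(all_species, size=n_tag, replace=False):
            truth.tag_coded_species.add(str(name))
            genus = name.split()[0]
            coded = f"{genus} sp. SIM-{all_species.index(name):03d}-1"
            for i in species_records[name]:
                records[i] = replace(records[i], species_name=coded)

    # Misidentifications: one record of a donor species takes the name of a
    # distinct recipient species; both become discordant.
    eligible = [
        s
        for s in all_species
        if s not in truth.tag_coded_species and len(species_records[s]) >= 2
    ]
    n_mis = round(params.fraction_mislabelled * len(all_species))
    if n_mis and len(eligible) >= 2:
        donors = [
            str(s)
            for s in rng.choice(eligible, size=min(n_mis, len(eligible)), replace=False)
        ]
        for donor in donors:
            recipients = [s for s in eligible if s != donor]
            recipient = str(recipients[int(rng.integers(0, len(recipients)))])
            i = species_records[donor][int(rng.integers(0, len(species_records[donor])))]
            records[i] = replace(records[i], species_name=recipient)
            truth.mislabels[records[i].record_id] = (donor, recipient)

    # Pseudogenes: plant an internal in-frame stop codon (TAA).
    n_pseudo = round(params.fraction_pseudogene * len(records))
    if n_pseudo:
        for i in rng.choice(len(records), size=n_pseudo, replace=False):
            r = records[int(i)]
            n_codons = len(r.sequence) // 3
            codon = int(rng.integers(1, n_codons - 1))
            seq = r.sequence[: 3 * codon] + "TAA" + r.sequence[3 * codon + 3 :]
            records[int(i)] = replace(r, sequence=seq)
            truth.pseudogene_records.add(r.record_id)
    return records


def _assign_planted_grades(records: Sequence[BarcodeRecord], truth: Truth) -> None:
    """Grades implied by the construction, over final (post-fault) names.

    Tag-coded species and pseudogene records are removed by upstream
    filtering, so they are left out of the grading truth.
    """
    usable = [
        r
        for r in records
        if r.record_id not in truth.pseudogene_records
    ]
    by_name: dict[str, list[BarcodeRecord]] = {}
    for r in usable:
        by_name.setdefault(r.species_name, []).append(r)
    lineage_names: dict[str, set[str]] = {}
    for r in usable:
        lineage_names.setdefault(truth.record_lineage[r.record_id], set()).add(
            r.species_name
        )
    for name, recs in by_name.items():
        if " sp. " in name:  # tag-coded, never graded
            continue
        lineages = {truth.record_lineage[r.record_id] for r in recs}
        exclusive = all(lineage_names[l] == {name} for l in lineages)
        if not exclusive:
            grade = "E"
        elif len(recs) < 3:
            grade = "D"
        elif len(lineages) > 1:
            grade = "C"
        elif len(recs) > 10:
            grade = "A"
        else:
            grade = "B"
        truth.grades[name] = grade


def _verify_gap(
    records: Sequence[BarcodeRecord], truth: Truth, params: SimulationParams
) -> bool:
    """Realised-distance check: the planted partition is recoverable at any
    threshold inside (within, between).  Pseudogene-planted records are
    excluded (they leave via filtering before any distance is computed)."""
    usable = [r for r in records if r.record_id not in truth.pseudogene_records]
    if len(usable) < 2:
        return True
    matrix = pairwise_matrix({r.record_id: r.sequence for r in usable})
    lineage = np.array([truth.record_lineage[r.record_id] for r in usable], dtype=object)
    n = len(usable)
    iu = np.triu_indices(n, k=1)
    same = lineage[iu[0]] == lineage[iu[1]]
    d = matrix.d[iu]
    if same.any() and d[same].max() > params.within_lineage_divergence:
        return False
    if (~same).any() and d[~same].min() < params.between_species_divergence:
        return False
    return True


def checklist_from_truth(
    records: Sequence[BarcodeRecord], extra_species: int = 0
) -> list[ChecklistEntry]:
    """A checklist covering the simulated species, optionally padded with
    unbarcoded species in the same genera (coverage < 100%)."""
    entries: dict[str, ChecklistEntry] = {}
    for r in records:
        t = r.taxonomy
        if t.species and " sp. " not in t.species:
            entries[t.species] = ChecklistEntry(
                species_name=t.species, genus=t.genus or "", family=t.family or ""
            )
    for i in range(extra_species):
        name = f"Simgenus000 unbarcoded{i:03d}"
        entries[name] = ChecklistEntry(
            species_name=name, genus="Simgenus000", family="Simfam00"
        )
    return list(entries.values())


# ---------------------------------------------------------------------------
# ASV datasets


@dataclass(frozen=True)
class AsvSimulationParams:
    """Study conditions for a synthetic metabarcoding (ASV) dataset.

    Defaults emulate a singleton-heavy community table: most molecular
    lineages are represented by a single ASV, a stated fraction of ASVs
    falls below the 10-read abundance floor, and taxonomy labels come at
    mixed depths (class-only through genus) as classifier output does.
    """

    n_lineages: int = 40
    asvs_per_lineage: int | tuple | dict = field(
        default_factory=lambda: {1: 0.70, 2: 0.12, 3: 0.08, 4: 0.05, 6: 0.03, 10: 0.02}
    )
    within_lineage_divergence: float = 0.02
    between_species_divergence: float = 0.08
    sequence_length: int = 313
    kappa: float = 2.0
    low_read_fraction: float = 2931 / 8306
    n_samples: int = 135
    #: probability that an ASV's label terminates at each depth
    label_depths: Mapping[str, float] = field(
        default_factory=lambda: {
            "class": 0.55,
            "order": 0.12,
            "family": 0.20,
            "genus": 0.13,
        }
    )
    label_mislabel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_read_fraction <= 1.0:
            raise ValueError("low_read_fraction must lie in [0, 1]")
        if not 0.0 <= self.label_mislabel_rate <= 1.0:
            raise ValueError("label_mislabel_rate must lie in [0, 1]")
        if not self.within_lineage_divergence < self.between_species_divergence:
            raise ValueError("within-lineage divergence must be below between-species")


def simulate_asvs(
    params: AsvSimulationParams | None = None,
    seed: int = 0,
    max_retries: int = 100,
) -> tuple[list[AsvRecord], Truth]:
    """Generate an ASV table with planted lineage structure and read counts.

    ASVs are noisy copies (within the within-lineage divergence) of
    planted lineage sequences; ``low_read_fraction`` of them receive
    total read counts below 10 so the abundance filter has work to do.
    Labels follow the lineage's true taxonomy truncated at a random
    depth; mislabelled ASVs take another family's taxonomy instead.
    """
    params = params or AsvSimulationParams()
    lib_params = SimulationParams(
        n_species=params.n_lineages,
        lineages_per_species=1,
        within_lineage_divergence=params.within_lineage_divergence,
        between_species_divergence=params.between_species_divergence,
        n_records_per_species=1,
        sequence_length=params.sequence_length,
        kappa=params.kappa,
    )

    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1, attempt]))
        asvs, truth = _simulate_asvs_once(rng, params, lib_params, max_retries)
        usable = {a.asv_id: a.sequence for a in asvs}
        if len(usable) < 2 or _verify_asv_gap(asvs, truth, params):
            return asvs, truth
    raise GenerationError(
        f"ASV dataset violated its divergence targets in {max_retries} attempts"
    )


def _simulate_asvs_once(
    rng: np.random.Generator,
    params: AsvSimulationParams,
    lib_params: SimulationParams,
    max_retries: int,
) -> tuple[list[AsvRecord], Truth]:
    truth = Truth()
    species = _species_names(lib_params)
    ancestors = _generate_lineage_ancestors(
        rng, params.n_lineages, lib_params, max_retries
    )
    families = sorted({t.family for _, t in species})
    max_sub = int(params.within_lineage_divergence * params.sequence_length / 2)
    depths = list(params.label_depths)
    depth_probs = np.array([params.label_depths[d] for d in depths], dtype=float)
    depth_probs = depth_probs / depth_probs.sum()

    asvs: list[AsvRecord] = []
    asv_no = 0
    for lineage_i, ((_, taxonomy), anc) in enumerate(zip(species, ancestors)):
        lineage_id = f"L{lineage_i:04d}"
        truth.lineage_taxonomy[lineage_id] = taxonomy
        n_asvs = max(1, _draw_count(rng, params.asvs_per_lineage))
        for _ in range(n_asvs):
            asv_id = f"ASV_{asv_no:05d}"
            asv_no += 1
            n_sub = int(rng.integers(0, max_sub + 1)) if max_sub else 0
            seq = _decode(_remove_stops(_mutate(rng, anc, n_sub, params.kappa)))
            depth = depths[int(rng.choice(len(depths), p=depth_probs))]
            if rng.random() < params.label_mislabel_rate:
                # wrong family from the same class, truncated at the same depth
                other = [f for f in families if f != taxonomy.family]
                wrong_family = other[int(rng.integers(0, len(other)))] if other else taxonomy.family
                label_source = Taxonomy(
                    phylum=taxonomy.phylum,
                    class_=taxonomy.class_,
                    order="Simorder99",
                    family=wrong_family,
                    genus=f"{wrong_family}_genus",
                    species=f"{wrong_family}_genus simspX",
                )
                truth.mislabelled_asvs.add(asv_id)
            else:
                label_source = taxonomy
            assigned = label_source.truncated_to(depth)
            truth.asv_true_taxonomy[asv_id] = taxonomy
            truth.record_lineage[asv_id] = lineage_id

            low = rng.random() < params.low_read_fraction
            if low:
                total = int(rng.integers(1, 10))
                truth.low_read_asvs.add(asv_id)
            else:
                total = 10 + int(rng.lognormal(mean=3.0, sigma=1.5))
            n_occupied = int(rng.integers(1, min(5, params.n_samples) + 1))
            samples = rng.choice(params.n_samples, size=n_occupied, replace=False)
            split = rng.multinomial(total, np.ones(n_occupied) / n_occupied)
            reads = {
                f"ARMS{int(s):03d}": int(c)
                for s, c in zip(samples, split)
                if int(c) > 0
            }
            if not reads:  # multinomial cannot empty a positive total, but guard
                reads = {f"ARMS{int(samples[0]):03d}": total}
            asvs.append(
                AsvRecord(
                    asv_id=asv_id,
                    sequence=seq,
                    reads_per_sample=reads,
                    assigned_taxonomy=assigned,
                )
            )
    for lineage_id in set(truth.record_lineage.values()):
        truth.partition[lineage_id] = frozenset(
            a for a, l in truth.record_lineage.items() if l == lineage_id
        )
    return asvs, truth


def _verify_asv_gap(
    asvs: Sequence[AsvRecord], truth: Truth, params: AsvSimulationParams
) -> bool:
    matrix = pairwise_matrix({a.asv_id: a.sequence for a in asvs})
    lineage = np.array(
        [truth.record_lineage[a.asv_id] for a in asvs], dtype=object
    )
    iu = np.triu_indices(len(asvs), k=1)
    same = lineage[iu[0]] == lineage[iu[1]]
    d = matrix.d[iu]
    if same.any() and d[same].max() > params.within_lineage_divergence:
        return False
    if (~same).any() and d[~same].min() < params.between_species_divergence:
        return False
    return True


__all__ = [
    "SimulationParams",
    "AsvSimulationParams",
    "Truth",
    "simulate_library",
    "simulate_asvs",
    "checklist_from_truth",
]
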