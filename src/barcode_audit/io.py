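"""Domain types and file formats.

The pipeline consumes BOLD-style barcode record tables (TSV), sequence
FASTA files, regional species checklists (CSV/TSV) and ASV tables, and
emits JSON reports plus newick trees.  This module defines the shared
vocabulary (:class:`Taxonomy`, :class:`BarcodeRecord`,
:class:`ChecklistEntry`, :class:`AsvRecord`) and all readers/writers.

Column layouts vary between BOLD exports, so table readers take a
*dialect*: a mapping from logical field names to the header names used in
the file.  The defaults follow the BOLD public-data TSV.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

#: Taxonomic ranks used throughout, ordered from the most inclusive down.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")

#: Valid sequence symbols after normalisation: IUPAC DNA plus the gap.
IUPAC_DNA = frozenset("ACGTMRWSYKVHDBNX-")

#: Closed vocabulary for checklist taxonomic status.
CHECKLIST_STATUSES = frozenset(
    {
        "accepted",
        "nomen_nudum",
        "interim_unpublished",
        "temporary_name",
        "uncertain",
        "taxon_inquirendum",
    }
)

#: Record-level quality flags carried by reference databases.
RECORD_FLAGS = frozenset({"contamination", "stop_codon", "indel"})


@dataclass(frozen=True)
class Taxonomy:
    """An ordered path of taxonomic labels; any suffix may be absent.

    Present ranks form a prefix-closed path: a species label implies the
    shallower ranks are either known or explicitly unknown (``None``).
    """

    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None

    def get(self, rank: str) -> str | None:
        return getattr(self, "class_" if rank == "class" else rank)

    def as_tuple(self) -> tuple[str | None, ...]:
        return tuple(self.get(r) for r in RANKS)

    def deepest_rank(self) -> str | None:
        """The deepest rank that carries a label, or ``None`` if empty."""
        deepest = None
        for rank in RANKS:
            if self.get(rank) is not None:
                deepest = rank
        return deepest

    def truncated_to(self, rank: str | None) -> "Taxonomy":
        """Copy with every rank below *rank* dropped (all dropped if None)."""
        if rank is None:
            return Taxonomy()
        keep = RANKS[: RANKS.index(rank) + 1]
        kwargs = {
            ("class_" if r == "class" else r): self.get(r) for r in keep
        }
        return Taxonomy(**kwargs)

    @classmethod
    def from_labels(cls, labels: Mapping[str, str | None]) -> "Taxonomy":
        kwargs = {}
        for rank in RANKS:
            value = labels.get(rank)
            if value is not None:
                value = str(value).strip()
                if not value:
                    value = None
            kwargs["class_" if rank == "class" else rank] = value
        return cls(**kwargs)


@dataclass(frozen=True)
class BarcodeRecord:
    """One reference sequence with its name, taxonomy and QC metadata."""

    record_id: str
    sequence: str
    species_name: str | None = None
    taxonomy: Taxonomy = field(default_factory=Taxonomy)
    bin_id: str | None = None
    flags: frozenset[str] = frozenset()
    region: str | None = None
    mined_from_genbank: bool = False

    @property
    def length_bp(self) -> int:
        """Number of non-gap characters in the stored sequence."""
        return len(self.sequence) - self.sequence.count("-")


@dataclass(frozen=True)
class ChecklistEntry:
    """One species row from a regional checklist."""

    species_name: str
    genus: str
    family: str
    status: str = "accepted"
    synonyms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.species_name:
            raise ValidationError("checklist entry with empty species name")
        if self.status not in CHECKLIST_STATUSES:
            raise ValidationError(f"unknown checklist status token: {self.status!r}")


@dataclass(frozen=True)
class AsvRecord:
    """A denoised amplicon sequence variant with per-sample read counts."""

    asv_id: str
    sequence: str
    reads_per_sample: Mapping[str, int] = field(default_factory=dict)
    assigned_taxonomy: Taxonomy = field(default_factory=Taxonomy)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValidationError(f"ASV {self.asv_id} has an empty sequence")

    @property
    def total_reads(self) -> int:
        return sum(self.reads_per_sample.values())


def normalise_sequence(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T and reject any non-IUPAC character."""
    seq = raw.strip().upper().replace("U", "T")
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise ValidationError(
            f"{context}: invalid sequence characters {sorted(bad)!r}"
        )
    return seq


# ---------------------------------------------------------------------------
# Barcode record tables

#: Default dialect: logical field -> BOLD public-data TSV header.
BOLD_DIALECT: dict[str, str] = {
    "id": "processid",
    "species": "species_name",
    "bin": "bin_uri",
    "sequence": "nucleotides",
    "phylum": "phylum_name",
    "class": "class_name",
    "order": "order_name",
    "family": "family_name",
    "genus": "genus_name",
    "flags": "flags",
    "region": "region",
    "mined_from_genbank": "genbank_mined",
}

_REQUIRED_FIELDS = ("id", "species", "bin", "sequence")


def _cell(row: pd.Series, column: str | None) -> str | None:
    if column is None or column not in row.index:
        return None
    value = row[column]
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def read_barcode_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[BarcodeRecord]:
    """Read a BOLD-style TSV of barcode records.

    *dialect* maps logical columns (``id``, ``species``, ``bin``,
    ``sequence`` required; taxonomy ranks, ``flags``, ``region``,
    ``mined_from_genbank`` optional) to header names; defaults to
    :data:`BOLD_DIALECT`.  Missing species/BIN cells yield absent fields.
    """
    dia = dict(BOLD_DIALECT)
    if dialect:
        dia.update(dialect)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=True)
    for logical in _REQUIRED_FIELDS:
        if dia[logical] not in frame.columns:
            raise FormatError(
                f"barcode table {path}: missing required column "
                f"{dia[logical]!r} (for field {logical!r})"
            )
    records: list[BarcodeRecord] = []
    for _, row in frame.iterrows():
        record_id = _cell(row, dia["id"])
        if record_id is None:
            raise ValidationError(f"barcode table {path}: row with empty record id")
        raw_seq = _cell(row, dia["sequence"]) or ""
        sequence = normalise_sequence(raw_seq, context=f"record {record_id}")
        flags_cell = _cell(row, dia.get("flags"))
        flags = frozenset(
            f.strip() for f in flags_cell.split(",") if f.strip()
        ) if flags_cell else frozenset()
        unknown = flags - RECORD_FLAGS
        if unknown:
            raise ValidationError(
                f"record {record_id}: unknown flags {sorted(unknown)!r}"
            )
        mined_cell = _cell(row, dia.get("mined_from_genbank"))
        mined = (mined_cell or "").lower() in {"1", "true", "yes"}
        taxonomy = Taxonomy.from_labels(
            {rank: _cell(row, dia.get(rank)) for rank in RANKS[:-1]}
            | {"species": _cell(row, dia["species"])}
        )
        records.append(
            BarcodeRecord(
                record_id=record_id,
                sequence=sequence,
                species_name=_cell(row, dia["species"]),
                taxonomy=taxonomy,
                bin_id=_cell(row, dia["bin"]),
                flags=flags,
                region=_cell(row, dia.get("region")),
                mined_from_genbank=mined,
            )
        )
    ids = [r.record_id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"duplicate record ids: {dupes!r}")
    return records


def write_barcode_table(
    records: Iterable[BarcodeRecord],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write records back to a TSV in the same (dialect-mapped) layout."""
    dia = dict(BOLD_DIALECT)
    if dialect:
        dia.update(dialect)
    rows = []
    for r in records:
        row = {
            dia["id"]: r.record_id,
            dia["species"]: r.species_name or "",
            dia["bin"]: r.bin_id or "",
            dia["sequence"]: r.sequence,
            dia["flags"]: ",".join(sorted(r.flags)),
            dia["region"]: r.region or "",
            dia["mined_from_genbank"]: "true" if r.mined_from_genbank else "false",
        }
        for rank in RANKS[:-1]:
            row[dia[rank]] = r.taxonomy.get(rank) or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> normalised sequence map.

    Duplicate headers and empty sequences are rejected.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValidationError(f"FASTA {path}: duplicate header {rec.id!r}")
        seq = normalise_sequence(str(rec.seq), context=f"FASTA record {rec.id}")
        if not seq:
            raise ValidationError(f"FASTA {path}: empty sequence for {rec.id!r}")
        sequences[rec.id] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write an id -> sequence map; inverse of :func:`read_fasta`."""
    records = []
    for name, seq in sequences.items():
        if not seq:
            raise ValidationError(f"refusing to write empty sequence for {name!r}")
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Checklists

_CHECKLIST_COLUMNS = ("species", "genus", "family", "status")


def _parse_synonyms(cell: str | None) -> frozenset[str]:
    if not cell:
        return frozenset()
    # Accept "A = B", "B; C" and "|"-separated lists; the name left of a
    # single "=" is the entry's own name and is dropped.
    text = cell
    if "=" in text:
        text = text.split("=", 1)[1]
    parts = [p.strip() for chunk in text.split(";") for p in chunk.split("|")]
    return frozenset(p for p in parts if p)


def read_checklist(
    path: str | Path,
    status_filter: Iterable[str] | None = None,
    sep: str | None = None,
) -> list[ChecklistEntry]:
    """Read a species checklist, keeping entries whose status passes the filter.

    The default filter keeps only ``accepted`` names: taxa flagged nomen
    nudum, interim unpublished, temporary, uncertain or taxon inquirendum
    are dropped, as is standard practice when a checklist is cross-checked
    against a sequence library.  An unknown status token raises.
    """
    wanted = frozenset(status_filter) if status_filter is not None else frozenset({"accepted"})
    unknown = wanted - CHECKLIST_STATUSES
    if unknown:
        raise ValidationError(f"unknown status tokens in filter: {sorted(unknown)!r}")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    for col in _CHECKLIST_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"checklist {path}: missing required column {col!r}")
    entries: list[ChecklistEntry] = []
    for _, row in frame.iterrows():
        status = (_cell(row, "status") or "accepted").strip().lower()
        if status not in CHECKLIST_STATUSES:
            raise ValidationError(f"checklist {path}: unknown status token {status!r}")
        if status not in wanted:
            continue
        entries.append(
            ChecklistEntry(
                species_name=_cell(row, "species") or "",
                genus=_cell(row, "genus") or "",
                family=_cell(row, "family") or "",
                status=status,
                synonyms=_parse_synonyms(_cell(row, "synonyms")),
            )
        )
    return entries


def write_checklist(entries: Iterable[ChecklistEntry], path: str | Path) -> None:
    rows = [
        {
            "species": e.species_name,
            "genus": e.genus,
            "family": e.family,
            "status": e.status,
            "synonyms": ";".join(sorted(e.synonyms)),
        }
        for e in entries
    ]
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# ASV tables


def read_asv_table(
    path: str | Path,
    sequences: Mapping[str, str] | None = None,
) -> list[AsvRecord]:
    """Read an ASV table: ``asv_id`` column, optional rank columns, and one
    column of integer read counts per sample.

    Sequences may be supplied separately (FASTA map); rows without a
    matching sequence raise.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "asv_id" not in frame.columns:
        raise FormatError(f"ASV table {path}: missing required column 'asv_id'")
    rank_cols = [r for r in RANKS if r in frame.columns]
    seq_col = "sequence" if "sequence" in frame.columns else None
    sample_cols = [
        c for c in frame.columns if c not in rank_cols and c not in ("asv_id", "sequence")
    ]
    records: list[AsvRecord] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        asv_id = _cell(row, "asv_id")
        if asv_id is None:
            raise ValidationError(f"ASV table {path}: row with empty asv_id")
        if asv_id in seen:
            raise ValidationError(f"ASV table {path}: duplicate asv_id {asv_id!r}")
        seen.add(asv_id)
        if seq_col:
            seq = normalise_sequence(_cell(row, seq_col) or "", context=f"ASV {asv_id}")
        elif sequences is not None and asv_id in sequences:
            seq = normalise_sequence(sequences[asv_id], context=f"ASV {asv_id}")
        else:
            raise ValidationError(f"ASV {asv_id}: no sequence available")
        reads = {}
        for col in sample_cols:
            cell = _cell(row, col)
            count = int(cell) if cell else 0
            if count < 0:
                raise ValidationError(f"ASV {asv_id}: negative read count in {col!r}")
            reads[col] = count
        records.append(
            AsvRecord(
                asv_id=asv_id,
                sequence=seq,
                reads_per_sample=reads,
                assigned_taxonomy=Taxonomy.from_labels(
                    {r: _cell(row, r) for r in rank_cols}
                ),
            )
        )
    return records


def write_asv_table(asvs: Sequence[AsvRecord], path: str | Path) -> None:
    samples = sorted({s for a in asvs for s in a.reads_per_sample})
    rows = []
    for a in asvs:
        row: dict[str, object] = {"asv_id": a.asv_id, "sequence": a.sequence}
        for rank in RANKS:
            row[rank] = a.assigned_taxonomy.get(rank) or ""
        for s in samples:
            row[s] = a.reads_per_sample.get(s, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree) -> str:
    """Serialise a scikit-bio ``TreeNode`` to a newick string.

    Leaf labels must be unique; the emitted string parses back to a
    topologically identical tree.
    """
    labels = [tip.name for tip in tree.tips()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValidationError(f"duplicate leaf labels: {dupes!r}")
    buffer = _stdio.StringIO()
    tree.write(buffer, format="newick")
    return buffer.getvalue().strip()


def read_newick(text: str):
    """Parse a newick string into a scikit-bio ``TreeNode``."""
    from skbio import TreeNode

    return TreeNode.read(_stdio.StringIO(text), format="newick")


__all__ = [
    "RANKS",
    "Taxonomy",
    "BarcodeRecord",
    "ChecklistEntry",
    "AsvRecord",
    "BOLD_DIALECT",
    "normalise_sequence",
    "read_barcode_table",
    "write_barcode_table",
    "read_fasta",
    "write_fasta",
    "read_checklist",
    "write_checklist",
    "read_asv_table",
    "write_asv_table",
    "write_newick",
    "read_newick",
    "replace",
]
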