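import numpy as np
import pytest

from barcode_audit.io import BarcodeRecord, Taxonomy


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


def make_record(
    record_id="R1",
    sequence="ACGT" * 80,
    species="Simgenus000 simsp000",
    bin_id="BIN1",
    flags=(),
    genus=None,
    family=None,
):
    """Minimal well-formed reference record for unit tests."""
    genus = genus or (species.split()[0] if species else None)
    return BarcodeRecord(
        record_id=record_id,
        sequence=sequence,
        species_name=species,
        taxonomy=Taxonomy(
            phylum="Annelida",
            class_="Polychaeta",
            genus=genus,
            family=family,
            species=species,
        ),
        bin_id=bin_id,
        flags=frozenset(flags),
    )


def random_dna(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
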