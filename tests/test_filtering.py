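"""Inclusion rules, tag-code detection and the stop-codon pseudogene screen."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcode_audit.filtering import (
    FilterCriteria,
    detect_tag_code,
    filter_asvs,
    filter_library,
    screen_pseudogene,
)
from barcode_audit.io import AsvRecord, BarcodeRecord, Taxonomy

from conftest import make_record

STOPS_TABLE5 = {"TAA", "TAG"}
AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "N": "ACGT",
    "W": "AT", "S": "CG", "K": "GT", "M": "AC",
}


@pytest.mark.parametrize(
    "name,expected",
    [
        ("Tharyx sp. CIRR-IK-2019-1", True),
        ("Hydroides elegans", False),
        ("Syllis gracilis LINEAGE-B2", True),
        ("Platynereis dumerilii", False),
        ("Nereis sp. A1", True),
    ],
)
def test_tag_code_detection(name, expected):
    assert detect_tag_code(name) is expected


class TestPseudogeneScreen:
    @pytest.mark.parametrize(
        "seq,frame,verdict",
        [
            ("ATGTAAGGG", 1, "internal_stop"),  # TAA at codon 2 of 3
            ("ATGGGGGGG", 1, "clean"),
            ("ATGNNNGGG", 1, "clean"),  # NNN cannot be forced to a stop
            ("ATGTARGGG", 1, "internal_stop"),  # TAR resolves only to TAA/TAG
            ("GGGTAA", 1, "clean"),  # stop only at the final codon
            ("AATGTAAGGG", 2, "internal_stop"),  # frame shift exposes TAA
        ],
    )
    def test_examples(self, seq, frame, verdict):
        assert screen_pseudogene(seq, frame=frame) == verdict

    def test_frame_out_of_range(self):
        with pytest.raises(ValueError):
            screen_pseudogene("ATGGGG", frame=4)

    def brute_force(self, seq, frame):
        """Enumerate every resolution of each internal codon."""
        coding = seq.replace("-", "")[frame - 1 :]
        n_codons = len(coding) // 3
        for i in range(n_codons - 1):
            codon = coding[3 * i : 3 * i + 3]
            resolutions = [
                "".join(c) for c in itertools.product(*(AMBIG[b] for b in codon))
            ]
            if all(r in STOPS_TABLE5 for r in resolutions):
                return "internal_stop"
        return "clean"

    @settings(max_examples=200, deadline=None)
    @given(
        seq=st.text(alphabet="ACGTNRYWSKM", min_size=3, max_size=30),
        frame=st.integers(1, 3),
    )
    def test_agrees_with_enumeration_oracle(self, seq, frame):
        assert screen_pseudogene(seq, frame=frame) == self.brute_force(seq, frame)


class TestFilterLibrary:
    def test_rules_charge_and_keep(self):
        records = [
            make_record("short", sequence="ACGT" * 60),  # 240 bp <= 300
            make_record("unnamed", species=None),
            make_record("ok1"),
            make_record("ok2"),
            make_record("ok3"),
        ]
        kept, report = filter_library(records)
        assert report.kept == 3
        assert report.rejected_by_rule == {"length": 1, "species": 1}
        assert [r.record_id for r in kept] == ["ok1", "ok2", "ok3"]

    def test_multi_fault_charged_to_first_rule(self):
        record = make_record("bad", species=None, flags={"contamination"})
        _, report = filter_library([record])
        assert report.rejected_by_rule == {"species": 1}

    def test_length_strictly_greater_than_300(self):
        exactly = make_record("edge", sequence="A" * 300)
        over = make_record("over", sequence="A" * 301)
        kept, report = filter_library([exactly, over])
        assert [r.record_id for r in kept] == ["over"]
        assert report.rejected_by_rule == {"length": 1}

    def test_tag_code_and_pseudogene_rules(self):
        tagged = make_record("tagged", species="Tharyx sp. CIRR-IK-2019-1")
        stop_seq = "ATG" + "TAA" + "GGG" * 100
        pseudo = make_record("pseudo", sequence=stop_seq)
        kept, report = filter_library([tagged, pseudo])
        assert kept == []
        assert report.rejected_by_rule == {"tag_code": 1, "pseudogene": 1}

    def test_any_frame_accepts_one_clean_frame(self):
        # frame 1 has TAA, frame 2 is stop-free
        seq = "ATGTAACCC" + "CCA" * 100
        record = make_record("shifty", sequence=seq)
        _, strict = filter_library([record])
        kept, _ = filter_library([record], FilterCriteria(any_frame=True))
        assert strict.rejected_by_rule == {"pseudogene": 1}
        assert len(kept) == 1

    def test_empty_input(self):
        kept, report = filter_library([])
        assert kept == [] and report.kept == 0 and report.rejected_by_rule == {}

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_accounting_balance_and_idempotence(self, data):
        n = data.draw(st.integers(0, 25))
        records = []
        for i in range(n):
            length = data.draw(st.sampled_from([120, 301, 400]))
            species = data.draw(
                st.sampled_from(
                    [None, "Hydroides elegans", "Tharyx sp. CIRR-IK-2019-1"]
                )
            )
            bin_id = data.draw(st.sampled_from([None, "BIN1"]))
            flags = data.draw(
                st.sets(st.sampled_from(["contamination", "stop_codon", "indel"]))
            )
            records.append(
                BarcodeRecord(
                    record_id=f"R{i}",
                    sequence="ACA" * (length // 3) + "A" * (length % 3),
                    species_name=species,
                    bin_id=bin_id,
                    flags=frozenset(flags),
                )
            )
        kept, report = filter_library(records)
        assert report.kept + report.total_rejected == len(records)
        kept_again, report_again = filter_library(kept)
        assert kept_again == kept
        assert report_again.rejected_by_rule == {}


class TestFilterAsvs:
    def make_asv(self, asv_id, total):
        return AsvRecord(
            asv_id=asv_id, sequence="ACGT", reads_per_sample={"s1": total}
        )

    def test_strict_below_ten_boundary(self):
        asvs = [self.make_asv(f"a{t}", t) for t in (9, 10, 11)]
        kept = filter_asvs(asvs, 10)
        assert [a.asv_id for a in kept] == ["a10", "a11"]

    def test_min_zero_is_identity(self):
        asvs = [self.make_asv("a", 1), self.make_asv("b", 0)]
        assert filter_asvs(asvs, 0) == asvs

    def test_negative_floor_rejected(self):
        with pytest.raises(ValueError):
            filter_asvs([], -1)

    def test_total_is_sum_over_samples(self):
        asv = AsvRecord(
            asv_id="a", sequence="ACGT", reads_per_sample={"s1": 4, "s2": 6}
        )
        assert asv.total_reads == 10
        assert filter_asvs([asv], 10) == [asv]
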