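"""Richness extrapolation, consensus taxonomy, LCA and reference matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcode_audit.distances import DistanceMatrix
from barcode_audit.errors import ValidationError
from barcode_audit.io import RANKS, Taxonomy
from barcode_audit.richness import (
    consensus_taxonomy,
    estimate_richness,
    filter_hits,
    lca_taxonomy,
    match_to_reference,
)


def taxon(**kwargs):
    return Taxonomy(phylum="Annelida", class_="Polychaeta", **kwargs)


class TestRichness:
    def test_truncated_ratio_arithmetic(self):
        est = estimate_richness(1350, 3131, 2291, "truncate2")
        assert est.ratio == 1.36
        assert est.estimate == 992

    def test_full_precision_arithmetic(self):
        est = estimate_richness(1350, 3131, 2291, "full")
        assert est.estimate == int(1350 * 2291 / 3131) == 987

    def test_unit_ratio_identity(self):
        est = estimate_richness(77, 50, 50, "truncate2")
        assert est.ratio == 1.0 and est.estimate == 77

    @settings(max_examples=100, deadline=None)
    @given(
        q=st.integers(1, 10_000), m=st.integers(1, 10_000), s=st.integers(1, 10_000)
    )
    def test_full_mode_matches_formula_to_truncation(self, q, m, s):
        est = estimate_richness(q, m, s, "full")
        assert est.estimate == int(q * s / m)

    def test_bootstrap_interval_brackets_estimate(self):
        counts = [1] * 40 + [2] * 8 + [3] * 2
        est = estimate_richness(
            100, sum(counts), len(counts), "full",
            motus_per_species=counts, bootstrap=200, seed=7,
        )
        low, high = est.bootstrap_interval
        assert low <= est.estimate <= high

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_richness(0, 1, 1)


class TestLca:
    def test_family_conflict_stops_at_class(self):
        t = lca_taxonomy(
            [taxon(order="Phyllodocida", family="Syllidae"),
             taxon(order="Eunicida", family="Dorvilleidae")]
        )
        assert t.deepest_rank() == "class" and t.class_ == "Polychaeta"

    def test_single_input_is_identity(self):
        t = taxon(order="Phyllodocida", family="Syllidae", genus="Syllis")
        assert lca_taxonomy([t]) == t

    def test_disjoint_phyla_empty(self):
        a = Taxonomy(phylum="Annelida")
        b = Taxonomy(phylum="Mollusca")
        assert lca_taxonomy([a, b]).deepest_rank() is None


class TestConsensus:
    def test_majority_beats_outlier_and_flags(self):
        members = [
            (taxon(order="Phyllodocida", family="Syllidae"), 1.0),
            (taxon(order="Phyllodocida", family="Syllidae"), 1.0),
            (taxon(order="Eunicida", family="Dorvilleidae"), 1.0),
        ]
        res = consensus_taxonomy("M", members, min_share=0.6)
        assert res.consensus_taxonomy.family == "Syllidae"
        assert res.flags == {"discordant", "outliers_excluded"}

    def test_identical_members_full_depth_support_one(self):
        t = taxon(order="Phyllodocida", family="Syllidae",
                  genus="Syllis", species="Syllis gracilis")
        res = consensus_taxonomy("M", [(t, 1.0)] * 4, min_share=0.6)
        assert res.consensus_taxonomy == t
        assert res.agreement_rank == "species"
        assert res.support_share == 1.0

    def test_even_split_stops_at_last_agreeing_rank(self):
        members = [
            (taxon(order="Phyllodocida", family="Syllidae"), 1.0),
            (taxon(order="Eunicida", family="Dorvilleidae"), 1.0),
        ]
        res = consensus_taxonomy("M", members, min_share=0.6)
        assert res.agreement_rank == "class"
        assert res.consensus_taxonomy.class_ == "Polychaeta"

    def test_weights_shift_the_majority(self):
        members = [
            (taxon(order="Phyllodocida", family="Syllidae"), 1.0),
            (taxon(order="Eunicida", family="Dorvilleidae"), 3.0),
        ]
        res = consensus_taxonomy("M", members, min_share=0.6)
        assert res.consensus_taxonomy.family == "Dorvilleidae"

    def test_min_share_must_exceed_half(self):
        with pytest.raises(ValueError):
            consensus_taxonomy("M", [(taxon(), 1.0)], min_share=0.5)

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            consensus_taxonomy("M", [], min_share=0.6)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_unanimity_equals_lca(self, data):
        """With min_share = 1 the consensus never goes deeper than the LCA."""
        n = data.draw(st.integers(1, 5))
        members = []
        for _ in range(n):
            depth = data.draw(st.integers(0, len(RANKS)))
            labels = {
                rank: data.draw(st.sampled_from(["x", "y"])) + rank
                for rank in RANKS[:depth]
            }
            members.append((Taxonomy.from_labels(labels), 1.0))
        res = consensus_taxonomy("M", members, min_share=1.0, outlier_rule="keep")
        lca = lca_taxonomy([t for t, _ in members])
        assert res.consensus_taxonomy == lca


class TestFilterHits:
    def frame(self, rows):
        return pd.DataFrame(
            rows, columns=["query", "subject", "identity", "query_cover"]
        )

    def test_default_thresholds(self):
        hits = self.frame(
            [("q", "s1", 96, 91), ("q", "s2", 96, 89), ("q", "s3", 94, 99)]
        )
        kept = filter_hits(hits)
        assert list(kept["subject"]) == ["s1"]

    def test_zero_thresholds_noop(self):
        hits = self.frame([("q", "s", 10, 10)])
        assert len(filter_hits(hits, 0, 0)) == 1

    def test_empty_table(self):
        assert len(filter_hits(self.frame([]))) == 0

    def test_malformed_row_rejected(self):
        hits = self.frame([("q", "s", "high", 90)])
        with pytest.raises(ValidationError):
            filter_hits(hits)

    def test_out_of_range_percent_rejected(self):
        with pytest.raises(ValidationError):
            filter_hits(self.frame([("q", "s", 120, 90)]))


class TestMatchToReference:
    def matrix(self, labels, entries):
        n = len(labels)
        d = np.zeros((n, n))
        for (a, b), value in entries.items():
            i, j = labels.index(a), labels.index(b)
            d[i, j] = d[j, i] = value
        return DistanceMatrix(labels, d, np.ones((n, n), int))

    def test_close_query_matches_species(self):
        m = self.matrix(["q", "r1"], {("q", "r1"): 0.03})
        matches = match_to_reference(["q"], {"r1": "spA"}, m)
        assert matches["q"].species == ("spA",)
        assert matches["q"].min_distance == pytest.approx(0.03)

    def test_far_query_no_match_strict_cut(self):
        m = self.matrix(["q", "r1"], {("q", "r1"): 0.06})
        matches = match_to_reference(["q"], {"r1": "spA"}, m, max_distance=0.05)
        assert matches["q"].species == ()

    def test_exactly_at_cut_is_no_match(self):
        m = self.matrix(["q", "r1"], {("q", "r1"): 0.05})
        matches = match_to_reference(["q"], {"r1": "spA"}, m, max_distance=0.05)
        assert matches["q"].species == ()

    def test_two_species_in_cluster_ambiguous(self):
        m = self.matrix(
            ["q", "r1", "r2"],
            {("q", "r1"): 0.02, ("q", "r2"): 0.03, ("r1", "r2"): 0.04},
        )
        matches = match_to_reference(["q"], {"r1": "spA", "r2": "spB"}, m)
        assert matches["q"].ambiguous
        assert matches["q"].species == ("spA", "spB")

    def test_published_in_region_references_listed_first(self):
        m = self.matrix(
            ["q", "r1", "r2"],
            {("q", "r1"): 0.02, ("q", "r2"): 0.03, ("r1", "r2"): 0.04},
        )
        matches = match_to_reference(
            ["q"], {"r1": "spA", "r2": "spB"}, m,
            reference_priority={"r1": (False, False), "r2": (True, True)},
        )
        assert matches["q"].species == ("spB", "spA")
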