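"""K2P distances against closed-form/brute-force oracles; NJ exactness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcode_audit.distances import (
    DistanceMatrix,
    k2p_distance,
    nj_tree,
    pairwise_matrix,
    tree_path_lengths,
)
from barcode_audit.errors import (
    SaturationWarning,
    UndefinedDistanceError,
    ValidationError,
)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def k2p_oracle(a, b):
    """Site-by-site recount and direct evaluation of the closed form."""
    ts = tv = n = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            n += 1
            if x != y:
                if (x, y) in TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    p, q = ts / n, tv / n
    return -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q)), n


class TestK2P:
    def test_identical_sequences_are_zero(self):
        d, n = k2p_distance("ACGT" * 5, "ACGT" * 5)
        assert d == 0.0 and n == 20

    def test_single_transition_closed_form(self):
        # P = 0.1, Q = 0  ->  d = -1/2 ln(0.8)
        d, n = k2p_distance("A" * 10, "G" + "A" * 9)
        assert n == 10
        assert d == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)

    def test_single_transversion_closed_form(self):
        # P = 0, Q = 0.1  ->  d = -1/2 ln(0.9 * sqrt(0.8))
        d, _ = k2p_distance("A" * 10, "C" + "A" * 9)
        assert d == pytest.approx(-0.5 * math.log(0.9 * math.sqrt(0.8)), abs=1e-12)

    def test_pairwise_deletion_of_gaps_and_ambiguity(self):
        d, n = k2p_distance("AC-T", "ACGT")
        assert n == 3 and d == 0.0
        d, n = k2p_distance("ACNT", "ACGT")
        assert n == 3 and d == 0.0

    def test_no_comparable_sites_raises(self):
        with pytest.raises(UndefinedDistanceError):
            k2p_distance("----", "ACGT")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            k2p_distance("ACG", "ACGT")

    def test_saturation_reported_as_infinity_with_warning(self):
        # maximally divergent: every site a transversion (P=0, Q=1)
        with pytest.warns(SaturationWarning):
            d, _ = k2p_distance("A" * 12, "C" * 12)
        assert d == math.inf

    def test_jukes_cantor_reduction(self):
        # with transitions = 1/3 of differences, K2P collapses to JC:
        # d_JC = -3/4 ln(1 - 4p/3)
        a = "A" * 30
        b = "G" + "C" + "T" + "A" * 27  # 1 ts, 2 tv over 30 sites
        p = 3 / 30
        d, _ = k2p_distance(a, b)
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * p / 3), abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_matches_recount_oracle_and_symmetry(self, data):
        length = data.draw(st.integers(10, 60))
        alphabet = "ACGTN-"
        a = "".join(data.draw(st.sampled_from(alphabet)) for _ in range(length))
        # keep divergence low enough to avoid saturation
        b = list(a)
        for i in range(length):
            if data.draw(st.floats(0, 1)) < 0.1:
                b[i] = data.draw(st.sampled_from("ACGT"))
        b = "".join(b)
        comparable = sum(x in "ACGT" and y in "ACGT" for x, y in zip(a, b))
        if comparable == 0:
            return
        d_ab, n_ab = k2p_distance(a, b)
        d_ba, n_ba = k2p_distance(b, a)
        d_exp, n_exp = k2p_oracle(a, b)
        assert n_ab == n_ba == n_exp
        assert d_ab == pytest.approx(d_ba, abs=1e-15)
        assert d_ab == pytest.approx(d_exp, abs=1e-12)


class TestPairwiseMatrix:
    def test_identical_sequences_all_zero(self):
        m = pairwise_matrix({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        assert np.allclose(m.d, 0.0)

    def test_equals_per_pair_recomputation(self, rng):
        from conftest import random_dna

        seqs = {}
        base = random_dna(rng, 60)
        for i in range(5):
            mutated = list(base)
            for j in rng.choice(60, size=5, replace=False):
                mutated[j] = "ACGT"[rng.integers(0, 4)]
            seqs[f"s{i}"] = "".join(mutated)
        m = pairwise_matrix(seqs)
        assert np.allclose(m.d, m.d.T)
        labels = list(seqs)
        for i in range(5):
            for j in range(i + 1, 5):
                d, n = k2p_oracle(seqs[labels[i]], seqs[labels[j]])
                assert m.d[i, j] == pytest.approx(d, abs=1e-12)
                assert m.sites_used[i, j] == n


class TestNeighbourJoining:
    def test_three_taxon_closed_form(self):
        # three-point formulas: x = (dab + dac - dbc) / 2, etc.
        dab, dac, dbc = 0.3, 0.5, 0.6
        d = np.array([[0, dab, dac], [dab, 0, dbc], [dac, dbc, 0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d, np.ones((3, 3), int)))
        paths = tree_path_lengths(tree, ["a", "b", "c"])
        assert np.allclose(paths, d, atol=1e-12)

    def test_four_taxon_additive_recovery(self):
        # hand-built tree: (a:2, b:3):3 with d:4, c:4 at the other end
        d = np.array(
            [[0, 5, 9, 9.0], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]]
        )
        labels = ["a", "b", "c", "d"]
        tree = nj_tree(DistanceMatrix(labels, d, np.ones((4, 4), int)))
        assert np.allclose(tree_path_lengths(tree, labels), d, atol=1e-9)

    def test_five_taxon_ultrametric_additivity(self):
        # balanced ultrametric tree; path lengths must be reproduced
        #     ((a,b),(c,d)),e with heights 1, 2, 3
        d = np.array(
            [
                [0, 2, 4, 4, 6.0],
                [2, 0, 4, 4, 6],
                [4, 4, 0, 2, 6],
                [4, 4, 2, 0, 6],
                [6, 6, 6, 6, 0],
            ]
        )
        labels = list("abcde")
        tree = nj_tree(DistanceMatrix(labels, d, np.ones((5, 5), int)))
        assert np.allclose(tree_path_lengths(tree, labels), d, atol=1e-9)

    def test_infinite_distance_rejected(self):
        d = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        with pytest.raises(ValidationError, match="saturated"):
            nj_tree(DistanceMatrix(["a", "b", "c"], d, np.ones((3, 3), int)))

    def test_fewer_than_three_taxa_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(["a", "b"], d, np.ones((2, 2), int)))
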