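"""Kimura two-parameter (K80) distances and neighbour-joining trees.

The K2P distance between two aligned sequences is

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

where P and Q are the proportions of transition (A<->G, C<->T) and
transversion differences over the sites where both sequences carry an
unambiguous A/C/G/T (pairwise deletion: a gap or ambiguity code in
either sequence excludes the site).  Pairwise deletion matters here
because metabarcoding fragments overlap reference barcodes only
partially.

Saturated pairs (logarithm argument <= 0) are reported as +infinity with
a :class:`~barcode_audit.errors.SaturationWarning` rather than raised,
so clustering can proceed by treating them as always split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .errors import SaturationWarning, UndefinedDistanceError, ValidationError

# Encoding: A=0, C=1, G=2, T=3, anything else (gap/ambiguity) = -1.
_CODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

#: purine/pyrimidine class of each encoded base (A,G -> 0; C,T -> 1)
_CLASS = np.array([0, 1, 0, 1], dtype=np.int8)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair comparable-site counts."""

    labels: list[str]
    d: np.ndarray
    sites_used: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n) or self.sites_used.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(
            list(labels), self.d[np.ix_(idx, idx)], self.sites_used[np.ix_(idx, idx)]
        )

    def to_skbio(self) -> _SkbioDM:
        return _SkbioDM(self.d, ids=self.labels)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, frame) -> "DistanceMatrix":
        labels = [str(c) for c in frame.columns]
        d = frame.to_numpy(dtype=float)
        return cls(labels, d, np.where(np.isfinite(d), 1, 0).astype(int))


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _k2p_from_counts(ts: int, tv: int, n: int) -> float:
    p, q = ts / n, tv / n
    a, b = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if a <= 0.0 or b <= 0.0:
        warnings.warn(
            f"saturated pair (P={p:.3f}, Q={q:.3f}); distance set to +inf",
            SaturationWarning,
            stacklevel=3,
        )
        return float("inf")
    return -0.5 * float(np.log(a * np.sqrt(b)))


def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """K2P distance and number of comparable sites for two aligned sequences.

    Raises :class:`UndefinedDistanceError` when no site is comparable.
    """
    if len(seq_a) != len(seq_b):
        raise ValidationError(
            f"aligned sequences must have equal length ({len(seq_a)} != {len(seq_b)})"
        )
    a, b = _encode(seq_a.upper()), _encode(seq_b.upper())
    usable = (a >= 0) & (b >= 0)
    n = int(usable.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable unambiguous sites")
    av, bv = a[usable], b[usable]
    diff = av != bv
    ts = int((diff & (_CLASS[av] == _CLASS[bv])).sum())
    tv = int(diff.sum()) - ts
    return _k2p_from_counts(ts, tv, n), n


def pairwise_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Full symmetric K2P matrix over a map of equally long aligned sequences."""
    labels = list(sequences)
    if len(labels) < 2:
        raise ValidationError("need at least two sequences")
    lengths = {len(sequences[l]) for l in labels}
    if len(lengths) != 1:
        raise ValidationError("all aligned sequences must have the same length")
    enc = np.stack([_encode(sequences[l].upper()) for l in labels])
    n = len(labels)
    d = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        sites[i, i] = int((enc[i] >= 0).sum())
        for j in range(i + 1, n):
            usable = (enc[i] >= 0) & (enc[j] >= 0)
            m = int(usable.sum())
            if m == 0:
                raise UndefinedDistanceError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            av, bv = enc[i][usable], enc[j][usable]
            diff = av != bv
            ts = int((diff & (_CLASS[av] == _CLASS[bv])).sum())
            tv = int(diff.sum()) - ts
            d[i, j] = d[j, i] = _k2p_from_counts(ts, tv, m)
            sites[i, j] = sites[j, i] = m
    return DistanceMatrix(labels, d, sites)


def nj_tree(matrix: DistanceMatrix):
    """Neighbour-joining tree (Saitou & Nei agglomeration) from a distance
    matrix; returns an unrooted scikit-bio ``TreeNode`` with branch lengths.

    Negative branch-length estimates are clamped to zero.  Infinite
    distances cannot be placed on a tree: cluster the data first and build
    one tree per cluster instead.
    """
    if len(matrix) < 3:
        raise ValidationError("neighbour joining requires at least 3 taxa")
    if not np.all(np.isfinite(matrix.d)):
        raise ValidationError(
            "matrix contains infinite (saturated) distances; "
            "build cluster-wise trees instead"
        )
    return _skbio_nj(matrix.to_skbio(), neg_as_zero=True)


def tree_path_lengths(tree, labels: Sequence[str]) -> np.ndarray:
    """Patristic distances between the named tips (for additivity checks)."""
    dm = tree.tip_tip_distances(endpoints=list(labels))
    idx = [dm.ids.index(l) for l in labels]
    return dm.data[np.ix_(idx, idx)]


__all__ = [
    "DistanceMatrix",
    "k2p_distance",
    "pairwise_matrix",
    "nj_tree",
    "tree_path_lengths",
]
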