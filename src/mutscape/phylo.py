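"""Tamura-Nei (TN93) pairwise distances and neighbor-joining trees.

TN93 estimates substitutions per site from the observed proportions of
purine transitions (A<->G), pyrimidine transitions (C<->T) and transversions,
with empirical (unequal) base frequencies — the two transition classes are
corrected separately, which matters when transitions are in excess.  The
distance-plus-NJ pipeline here is a deterministic, closed-form surrogate for
maximum-likelihood tree inference under the same substitution model: it
supports topology and distance-ordering claims, not branch-length replays of
an ML search.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import skbio
from skbio.tree import nj as _skbio_nj

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric substitutions-per-site matrix; NaN entries mark saturation."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match the label count")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < 0:
                raise ValueError("distances must be >= 0")
        if not np.array_equal(np.isnan(v), np.isnan(v.T)) or not np.allclose(
            np.nan_to_num(v), np.nan_to_num(v.T)
        ):
            raise ValueError("matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    @property
    def saturated_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def to_skbio(self) -> skbio.DistanceMatrix:
        if self.saturated_pairs:
            raise ValueError(f"saturated pairs cannot enter tree building: {self.saturated_pairs}")
        return skbio.DistanceMatrix(self.values, ids=list(self.labels))


def _comparable_sites(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Pairwise deletion: keep sites where both sequences carry A/C/G/T."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal (aligned) length")
    pairs = [
        (x, y)
        for x, y in zip(seq_a.upper(), seq_b.upper())
        if x in _VALID and y in _VALID
    ]
    if not pairs:
        raise ValueError("no comparable (gap-free, unambiguous) sites")
    return "".join(p[0] for p in pairs), "".join(p[1] for p in pairs)


def tn93_distance(seq_a: str, seq_b: str) -> float:
    """TN93 distance in substitutions per site; NaN when saturated.

    Base frequencies are the empirical average over both sequences at the
    comparable sites.  Saturation (a non-positive logarithm argument) is
    reported as NaN rather than capped.
    """
    a, b = _comparable_sites(seq_a, seq_b)
    n = len(a)
    p1 = p2 = q = 0
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for x, y in zip(a, b):
        counts[x] += 1
        counts[y] += 1
        if x == y:
            continue
        pair = {x, y}
        if pair <= _PURINES:
            p1 += 1
        elif pair <= _PYRIMIDINES:
            p2 += 1
        else:
            q += 1
    P1, P2, Q = p1 / n, p2 / n, q / n
    gA, gC, gG, gT = (counts[base] / (2 * n) for base in "ACGT")
    gR, gY = gA + gG, gC + gT

    if gR == 0 or gY == 0:  # single-class composition: nothing to correct
        if P1 == 0 and P2 == 0 and Q == 0:
            return 0.0
        return float("nan")

    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gC * gT / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)

    terms = []
    for coeff, arg in (
        (k1, 1.0 - (P1 / k1 if k1 > 0 else 0.0) - Q / (2.0 * gR)),
        (k2, 1.0 - (P2 / k2 if k2 > 0 else 0.0) - Q / (2.0 * gY)),
        (k3, 1.0 - Q / (2.0 * gR * gY)),
    ):
        if coeff == 0.0:
            # degenerate frequency class: its transition proportion is
            # necessarily 0 and the term vanishes
            terms.append(0.0)
            continue
        if arg <= 0.0:
            return float("nan")
        terms.append(-coeff * math.log(arg))
    return float(sum(terms))


def tn93_matrix(sequences: dict[str, str]) -> DistanceMatrix:
    """All-pairs TN93 distances for a set of equal-length (aligned) sequences."""
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    labels = tuple(sequences)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tn93_distance(sequences[labels[i]], sequences[labels[j]])
    return DistanceMatrix(labels, d)


def nj_tree(dm: DistanceMatrix):
    """Neighbor-joining tree (skbio TreeNode) with branch lengths clamped >= 0."""
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = _skbio_nj(dm.to_skbio())
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def to_newick(tree) -> str:
    import io as _io

    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def tree_path_length(tree, a: str, b: str) -> float:
    """Sum of branch lengths on the path between two leaves."""
    ta = tree.find(a)
    tb = tree.find(b)
    return float(ta.distance(tb))
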