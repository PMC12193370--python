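"""Consensus reconstruction from 1-2x redundant contig tilings.

Resolution rules, in decreasing coverage-2 precedence:

* coverage 1: copy the sole contig's base (``single``);
* coverage 2, agreeing bases: copy the shared base (``agree``);
* coverage 2, disagreeing, exactly one base equals the reference: retain the
  reference base (``ref_retained``);
* coverage 2, disagreeing, neither base equals the reference: take the base
  from the placement with the smaller ref_start and flag the position
  ``unresolved`` so a human can audit it — a deterministic stand-in for
  manual curation.

Coverage 0 anywhere is a gap error; coverage above 2 is rejected rather than
majority-voted because the tilings this stage models never exceed 2x.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ContigPlacement


class CoverageGapError(ValueError):
    """The placements leave part of the reference uncovered."""


class UnsupportedDepthError(ValueError):
    """More than two contigs cover a position."""


DECISION_KINDS = ("single", "agree", "ref_retained", "unresolved")


@dataclass(frozen=True)
class Decision:
    position: int
    kind: str
    base: str
    alternatives: tuple[str, ...] = ()


@dataclass(frozen=True)
class ConsensusResult:
    sequence: str
    coverage: np.ndarray
    decisions: tuple[Decision, ...]

    def decisions_of_kind(self, kind: str) -> list[Decision]:
        if kind not in DECISION_KINDS:
            raise ValueError(f"unknown decision kind {kind!r}")
        return [d for d in self.decisions if d.kind == kind]


def build_consensus(placements: list[ContigPlacement], reference: str) -> ConsensusResult:
    """Resolve a 1-2x contig tiling into a consensus over the reference span."""
    if not placements:
        raise CoverageGapError("no placements given")
    L = len(reference)
    reference = reference.upper()
    ordered = sorted(placements, key=lambda p: (p.ref_start, p.contig_id))
    for p in ordered:
        if p.ref_end > L:
            raise ValueError(f"placement {p.contig_id} extends past the reference end")

    coverage = np.zeros(L, dtype=np.int64)
    for p in ordered:
        coverage[p.ref_start : p.ref_end] += 1
    if coverage.min() == 0:
        gap = int(np.flatnonzero(coverage == 0)[0])
        raise CoverageGapError(f"coverage gap at reference position {gap}")
    if coverage.max() > 2:
        deep = int(np.flatnonzero(coverage > 2)[0])
        raise UnsupportedDepthError(f"coverage {int(coverage[deep])} at position {deep}; only 1-2x supported")

    # first/second base per position, first slot filled by the left-most placement
    first = np.full(L, "", dtype=object)
    second = np.full(L, "", dtype=object)
    for p in ordered:
        seq = p.sequence.upper()
        for pos in range(p.ref_start, p.ref_end):
            if first[pos] == "":
                first[pos] = seq[pos - p.ref_start]
            else:
                second[pos] = seq[pos - p.ref_start]

    out: list[str] = []
    decisions: list[Decision] = []
    for pos in range(L):
        b1 = first[pos]
        if coverage[pos] == 1:
            out.append(b1)
            decisions.append(Decision(pos, "single", b1))
            continue
        b2 = second[pos]
        if b1 == b2:
            out.append(b1)
            decisions.append(Decision(pos, "agree", b1))
            continue
        ref = reference[pos]
        if (b1 == ref) != (b2 == ref):
            alt = b2 if b1 == ref else b1
            out.append(ref)
            decisions.append(Decision(pos, "ref_retained", ref, (alt,)))
        else:  # neither matches the reference (both matching is impossible here)
            out.append(b1)
            decisions.append(Decision(pos, "unresolved", b1, (b2,)))

    return ConsensusResult("".join(out), coverage, tuple(decisions))
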