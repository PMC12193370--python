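"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (consensus building, alignment
conflict marking, MAT statistics, TN93 distances, ΔCt expression analysis)
gets its inputs from here, together with the truth needed for
parameter-recovery tests: annotated gene models, mutated population variants
with their mutated-coordinate lists, spliced transcripts, 1–2× redundant
contig tilings, and Ct tables with group effects, replicate noise and
injected outliers.

All generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import CtDataset, ContigPlacement, GeneModel, Interval, MutationSpec

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def generate_gene_model(
    n_exons: int,
    exon_len_range: tuple[int, int] = (80, 200),
    intron_len_range: tuple[int, int] = (60, 400),
    first_intron_scale: float = 1.0,
    seed: int = 0,
    gene_id: str = "gene",
    first_intron_utr: bool = False,
) -> GeneModel:
    """Draw a random annotated gene: alternating exons and introns.

    Exon and intron lengths are uniform over the given inclusive ranges.  The
    first intron's length is set to
    ``first_intron_scale × mean(intron_len_range) × max(n_introns − 1, 1)``,
    so a large scale reproduces the situation where a single leading (often
    5'UTR) intron dominates the total intron length.
    """
    if n_exons < 2:
        raise ValueError("n_exons must be >= 2 so the gene has at least one intron")
    for name, (lo, hi) in (("exon_len_range", exon_len_range), ("intron_len_range", intron_len_range)):
        if lo <= 0 or hi < lo:
            raise ValueError(f"{name} must be a positive range (lo <= hi), got {(lo, hi)}")
    if first_intron_scale <= 0:
        raise ValueError("first_intron_scale must be > 0")

    rng = np.random.default_rng(seed)
    n_introns = n_exons - 1
    exon_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1, size=n_exons)
    intron_lens = rng.integers(intron_len_range[0], intron_len_range[1] + 1, size=n_introns)
    base_mean = (intron_len_range[0] + intron_len_range[1]) / 2.0
    first_len = int(round(first_intron_scale * base_mean * max(n_introns - 1, 1)))
    intron_lens[0] = max(first_len, 1)

    exons: list[Interval] = []
    introns: list[Interval] = []
    pos = 0
    for i in range(n_exons):
        exons.append(Interval(pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < n_introns:
            introns.append(Interval(pos, pos + int(intron_lens[i])))
            pos += int(intron_lens[i])
    sequence = "".join(rng.choice(_BASES, size=pos))
    intron_utr = [False] * n_introns
    if n_introns and first_intron_utr:
        intron_utr[0] = True
    return GeneModel(gene_id, sequence, exons, introns, intron_utr=intron_utr)


# ---------------------------------------------------------------------------
# population variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutatedVariant:
    """A mutated copy of a gene plus its ground truth.

    truth
        Sorted, unique (reference coordinate, region) pairs: every substituted
        site, every deleted site, and the left-attachment coordinate of every
        insertion.
    ref_map
        Per variant position, the reference coordinate it descends from
        (-1 for inserted bases).
    """

    sequence: str
    truth: tuple[tuple[int, str], ...]
    ref_map: np.ndarray

    @property
    def truth_coordinates(self) -> frozenset[int]:
        return frozenset(c for c, _ in self.truth)


def _substituted_base(base: str, rng: np.random.Generator, kappa: float) -> str:
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[base]
    pair = _TRANSVERSIONS[base]
    return pair[0] if rng.random() < 0.5 else pair[1]


def mutate_population(model: GeneModel, spec: MutationSpec) -> MutatedVariant:
    """Apply region-specific substitutions and intron-restricted indels.

    Substitutions are drawn per site with the exon/intron rate of the site's
    region; the replacement base is a transition with probability
    kappa/(kappa+2), else one of the two transversions with equal probability.
    Indels initiate at intron sites; deletions are truncated at the end of
    their intron, insertions attach to the left (after the initiating site).
    """
    if model.sequence is None:
        raise ValueError("mutate_population requires a gene model with a sequence")
    seq = model.sequence
    L = model.length
    region = model._region  # 0 = exon, 1 = intron
    rng = np.random.default_rng(spec.seed)

    rates = np.where(region == 1, spec.sub_rate_intron, spec.sub_rate_exon)
    sub_mask = rng.random(L) < rates
    if spec.indel_rate_intron > 0:
        indel_mask = (region == 1) & (rng.random(L) < spec.indel_rate_intron)
    else:
        indel_mask = np.zeros(L, dtype=bool)

    out: list[str] = []
    ref_map: list[int] = []
    truth: dict[int, str] = {}
    i = 0
    while i < L:
        label = "intron" if region[i] else "exon"
        base = seq[i]
        if sub_mask[i]:
            base = _substituted_base(base, rng, spec.ti_tv_kappa)
            truth[i] = label
        out.append(base)
        ref_map.append(i)
        if indel_mask[i]:
            length = int(rng.geometric(spec.indel_len_dist))
            if rng.random() < 0.5:  # deletion of the following intron bases
                j = i + 1
                deleted = 0
                while j < L and deleted < length and region[j] == 1:
                    truth[j] = "intron"
                    j += 1
                    deleted += 1
                i = j
                continue
            # insertion attached after site i
            ins = rng.choice(_BASES, size=length)
            out.extend(ins)
            ref_map.extend([-1] * length)
            truth[i] = "intron"
        i += 1

    truth_t = tuple(sorted(truth.items()))
    return MutatedVariant("".join(out), truth_t, np.asarray(ref_map, dtype=np.int64))


def splice(
    model: GeneModel,
    variant_sequence: str,
    coordinate_map: np.ndarray | None = None,
) -> str:
    """Concatenate the exonic bases of a variant, in gene order.

    ``coordinate_map`` relates variant positions to reference coordinates
    (-1 for insertions); it defaults to the identity, which requires the
    variant to have the reference length.  Every exonic reference coordinate
    must be represented exactly once, otherwise the map is inconsistent with
    the exon intervals.
    """
    if coordinate_map is None:
        if len(variant_sequence) != model.length:
            raise ValueError("identity coordinate map requires reference-length variant")
        coordinate_map = np.arange(model.length, dtype=np.int64)
    coordinate_map = np.asarray(coordinate_map)
    if len(coordinate_map) != len(variant_sequence):
        raise ValueError("coordinate map length must equal the variant length")
    mapped = coordinate_map[coordinate_map >= 0]
    if np.any(np.diff(mapped) <= 0):
        raise ValueError("mapped reference coordinates must be strictly increasing")
    exonic_mask = model._region == 0
    exon_coords = np.flatnonzero(exonic_mask)
    mapped_exonic = mapped[exonic_mask[mapped]]
    if mapped_exonic.size != exon_coords.size or np.any(mapped_exonic != exon_coords):
        raise ValueError("coordinate map is inconsistent with the exon intervals")
    keep = (coordinate_map >= 0) & exonic_mask[np.clip(coordinate_map, 0, model.length - 1)]
    return "".join(ch for ch, k in zip(variant_sequence, keep) if k)


# ---------------------------------------------------------------------------
# contig tilings
# ---------------------------------------------------------------------------


def fragment_into_contigs(
    sequence: str,
    n_contigs: int,
    overlap_fraction: float = 0.0,
    seed: int = 0,
) -> list[ContigPlacement]:
    """Tile a sequence into contigs with coverage 1 everywhere except
    pairwise junction overlaps (coverage 2).

    ``overlap_fraction`` is the total fraction of the sequence at coverage 2,
    split evenly across the n_contigs − 1 junctions.  Junction positions are
    jittered (seeded) within bounds that preserve the 1–2× coverage
    invariant; geometry that cannot satisfy it raises.
    """
    L = len(sequence)
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if L < n_contigs:
        raise ValueError("sequence shorter than the number of contigs")
    if n_contigs == 1:
        return [ContigPlacement("contig_1", 0, L, sequence)]

    v = int(round(overlap_fraction * L / (n_contigs - 1)))
    seg = L // n_contigs
    if v >= seg:
        raise ValueError(
            "impossible tiling geometry: junction overlap "
            f"({v} bp) reaches the contig spacing ({seg} bp)"
        )
    points = [round(i * L / n_contigs) for i in range(n_contigs + 1)]
    rng = np.random.default_rng(seed)
    amp = max(0, (seg - max(v, 1) - 2) // 3)
    if amp:
        for i in range(1, n_contigs):
            points[i] += int(rng.integers(-amp, amp + 1))

    placements = []
    for i in range(n_contigs):
        start = points[i] - (v if i > 0 else 0)
        end = points[i + 1]
        placements.append(ContigPlacement(f"contig_{i + 1}", start, end, sequence[start:end]))
    coverage = np.zeros(L, dtype=int)
    for p in placements:
        coverage[p.ref_start : p.ref_end] += 1
    assert set(np.unique(coverage)) <= {1, 2}, "internal error: coverage outside 1-2"
    return placements


# ---------------------------------------------------------------------------
# Ct datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CtTruth:
    """Generating parameters recorded alongside a synthetic Ct dataset."""

    log2_effects: dict[str, float]
    br_offsets: dict[tuple[str, int], float]
    outliers: tuple[tuple[str, int, int, str, float], ...]  # (group, br, tech_rep, role, shift)


def generate_ct_dataset(
    groups: tuple[str, ...] = ("control", "A", "B"),
    n_br: int = 3,
    n_tech: int = 3,
    base_ct_target: float = 24.0,
    base_ct_reference: float = 18.0,
    log2_effects: dict[str, float] | None = None,
    sd_tech: float = 0.3,
    sd_br: float = 0.3,
    n_outliers: int = 0,
    outlier_magnitude: float = 8.0,
    seed: int = 0,
) -> tuple[CtDataset, CtTruth]:
    """Simulate a grouped qPCR Ct table (default 3 groups × 3 BR × 3 tech reps).

    The target gene's Ct in group *g* is
    ``base_ct_target − log2_effects[g] + BR offset + tech noise`` (a +1 log2
    effect lowers Ct by one cycle, i.e. doubles expression).  The reference
    (housekeeping) gene has no group effect and no BR offset — the BR offset
    therefore models biological replicate-level variation of the *target*
    transcript and does not cancel in ΔCt.  ``n_outliers`` Ct values at
    random positions are shifted by ``outlier_magnitude`` cycles and their
    locations recorded in the returned truth.
    """
    if sd_tech < 0 or sd_br < 0:
        raise ValueError("noise standard deviations must be >= 0")
    if n_outliers < 0:
        raise ValueError("n_outliers must be >= 0")
    effects = {g: float((log2_effects or {}).get(g, 0.0)) for g in groups}
    rng = np.random.default_rng(seed)

    rows: list[tuple] = []
    br_offsets: dict[tuple[str, int], float] = {}
    for g in groups:
        for br in range(1, n_br + 1):
            off = float(rng.normal(0.0, sd_br))
            br_offsets[(g, br)] = off
            for role, base in (("target", base_ct_target), ("reference", base_ct_reference)):
                for tr in range(1, n_tech + 1):
                    noise = float(rng.normal(0.0, sd_tech))
                    ct = base + noise
                    if role == "target":
                        ct += off - effects[g]
                    rows.append((g, br, tr, role, ct))

    outliers: list[tuple[str, int, int, str, float]] = []
    if n_outliers:
        idx = rng.choice(len(rows), size=n_outliers, replace=False)
        for k in sorted(int(j) for j in idx):
            g, br, tr, role, ct = rows[k]
            rows[k] = (g, br, tr, role, ct + outlier_magnitude)
            outliers.append((g, br, tr, role, float(outlier_magnitude)))

    return CtDataset.from_records(rows), CtTruth(effects, br_offsets, tuple(outliers))
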