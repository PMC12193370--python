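"""Column classification and conflictual-coordinate marking on multiple alignments.

The alignments this module consumes mix *gene* rows (genomic sequences from
several populations) with *transcript* rows (spliced sequences).  Because a
transcript aligns only to the exons, its gap structure delimits the introns:
a column is exonic when at least one transcript row carries a residue there,
intronic when all transcript rows are gapped but a gene row is not.

Conflict marking follows two coverage rules:

* columns whose non-gap coverage is 1 or 2 are conflictual by construction
  (too few sequences to corroborate the region);
* columns with coverage 3-5 are conflictual when at least two non-gap
  residues differ, or when a gene row is gapped while another gene row
  carries a residue (an indel among the genomes).  Gap-vs-gap is not a
  difference, and transcript gaps never count (they encode intron
  boundaries, not variation).

Conflictual columns are projected onto the coordinate frame of a designated
anchor gene row; columns where the anchor is gapped attach to the nearest
preceding anchor coordinate (left attachment), and duplicate projected
coordinates collapse to a single entry, counted once.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .models import DNA, GeneModel, Interval
from .synthetic import MutatedVariant, splice

GAP = "-"


@dataclass(frozen=True)
class AlignedRow:
    row_id: str
    population: str
    role: str  # "gene" | "transcript"
    seq: str

    def __post_init__(self) -> None:
        if self.role not in ("gene", "transcript"):
            raise ValueError(f"row role must be gene or transcript, got {self.role!r}")
        residues = set(self.seq.upper()) - {GAP}
        if residues - DNA:
            raise ValueError(f"row {self.row_id}: non-ACGT residues {sorted(residues - DNA)}")


class AlignmentBundle:
    """A multiple alignment of gene rows plus transcript rows."""

    def __init__(self, rows: list[AlignedRow]) -> None:
        if not rows:
            raise ValueError("empty alignment bundle")
        lengths = {len(r.seq) for r in rows}
        if len(lengths) != 1:
            raise ValueError("all aligned rows must have equal length")
        self.width = lengths.pop()
        if self.width == 0:
            raise ValueError("zero-length alignment")
        self.rows = [AlignedRow(r.row_id, r.population, r.role, r.seq.upper()) for r in rows]
        if not self.gene_rows:
            raise ValueError("an alignment bundle needs at least one gene row")

    @property
    def gene_rows(self) -> list[AlignedRow]:
        return [r for r in self.rows if r.role == "gene"]

    @property
    def transcript_rows(self) -> list[AlignedRow]:
        return [r for r in self.rows if r.role == "transcript"]

    def row(self, row_id: str) -> AlignedRow:
        for r in self.rows:
            if r.row_id == row_id:
                return r
        raise KeyError(f"no row {row_id!r} in bundle")


@dataclass(frozen=True)
class ColumnClass:
    column_index: int
    coverage: int
    region: str  # "exonic" | "intronic" | "ambiguous"
    conflictual: bool


@dataclass(frozen=True)
class ConflictEntry:
    coordinate: int  # 0-based position on the anchor gene row
    region: str  # "exon" | "intron"
    n_variant_rows: int


@dataclass(frozen=True)
class ConflictTable:
    gene_id: str
    entries: tuple[ConflictEntry, ...]

    @property
    def coordinates(self) -> frozenset[int]:
        return frozenset(e.coordinate for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class RegionCounts:
    n_total: int
    n_exon: int
    n_intron: int
    pct_exon: float
    pct_intron: float


# ---------------------------------------------------------------------------
# column classification and conflict marking
# ---------------------------------------------------------------------------


def classify_columns(bundle: AlignmentBundle) -> list[ColumnClass]:
    """Per-column coverage, exon/intron class and conflict flag."""
    gene_seqs = [r.seq for r in bundle.gene_rows]
    tx_seqs = [r.seq for r in bundle.transcript_rows]
    out: list[ColumnClass] = []
    for j in range(bundle.width):
        gene_chars = [s[j] for s in gene_seqs]
        tx_chars = [s[j] for s in tx_seqs]
        residues = [c for c in gene_chars + tx_chars if c != GAP]
        coverage = len(residues)
        if any(c != GAP for c in tx_chars):
            region = "exonic"
        elif any(c != GAP for c in gene_chars):
            region = "intronic"
        else:
            region = "ambiguous"
        if coverage == 0:
            conflict = False
        elif coverage <= 2:
            conflict = True
        else:
            gene_gap_vs_residue = any(c == GAP for c in gene_chars) and any(
                c != GAP for c in gene_chars
            )
            conflict = len(set(residues)) >= 2 or gene_gap_vs_residue
        out.append(ColumnClass(j, coverage, region, conflict))
    return out


def _n_variant_rows(bundle: AlignmentBundle, j: int) -> int:
    residues = [r.seq[j] for r in bundle.rows if r.seq[j] != GAP]
    if not residues:
        return 0
    counts = Counter(residues)
    return len(residues) - counts.most_common(1)[0][1]


def mark_conflicts(
    bundle: AlignmentBundle,
    anchor_id: str | None = None,
    gene_id: str = "gene",
) -> ConflictTable:
    """Project conflictual columns onto the anchor gene row's coordinates.

    The anchor defaults to the first gene row.  Columns where the anchor is
    gapped attach to the nearest preceding anchor coordinate (clamped to 0
    before the first anchor residue); coordinates are counted once even when
    several columns collapse onto them, keeping the left-most contributing
    column's region.
    """
    anchor = bundle.gene_rows[0] if anchor_id is None else bundle.row(anchor_id)
    if anchor.role != "gene":
        raise ValueError("the anchor row must be a gene row")
    classes = classify_columns(bundle)

    entries: dict[int, ConflictEntry] = {}
    anchor_pos = -1
    for cls in classes:
        if anchor.seq[cls.column_index] != GAP:
            anchor_pos += 1
        if not cls.conflictual:
            continue
        coord = max(anchor_pos, 0)
        region = "exon" if cls.region == "exonic" else "intron"
        nvar = _n_variant_rows(bundle, cls.column_index)
        if coord in entries:
            prev = entries[coord]
            entries[coord] = ConflictEntry(coord, prev.region, max(prev.n_variant_rows, nvar))
        else:
            entries[coord] = ConflictEntry(coord, region, nvar)
    return ConflictTable(gene_id, tuple(entries[c] for c in sorted(entries)))


def count_by_region(
    table: ConflictTable,
    model: GeneModel,
    exclude: Interval | None = None,
) -> RegionCounts:
    """Tally conflict entries into exon/intron counts and percentages.

    Regions are re-checked against the gene model's intervals (the model is
    authoritative for entries whose alignment-derived label disagrees, e.g.
    at exon/intron boundaries).  ``exclude`` drops entries inside an interval
    — the dual-accounting mode for genes dominated by one intron.
    Percentages are rounded to 2 decimals.
    """
    n_exon = n_intron = 0
    for e in table.entries:
        if e.coordinate >= model.length:
            raise ValueError(f"conflict coordinate {e.coordinate} outside gene of length {model.length}")
        if exclude is not None and exclude.contains(e.coordinate):
            continue
        if model.region_of(e.coordinate) == "exon":
            n_exon += 1
        else:
            n_intron += 1
    n_total = n_exon + n_intron
    if n_total == 0:
        return RegionCounts(0, 0, 0, 0.0, 0.0)
    return RegionCounts(
        n_total,
        n_exon,
        n_intron,
        round(100.0 * n_exon / n_total, 2),
        round(100.0 * n_intron / n_total, 2),
    )


# ---------------------------------------------------------------------------
# bundle construction from synthetic variants
# ---------------------------------------------------------------------------


def bundle_from_variants(
    model: GeneModel,
    gene_variants: list[tuple[str, MutatedVariant | None]],
    transcript_of: tuple[str, ...] = (),
) -> AlignmentBundle:
    """Build the true multiple alignment of population variants of one gene.

    ``gene_variants`` maps row ids to mutated variants (``None`` for an
    unmutated copy of the reference model).  Because indels are restricted to
    introns, the true alignment is reconstructed exactly from the variants'
    coordinate maps: one column per reference position, plus insertion
    columns attached after their anchor position.  ``transcript_of`` names
    gene rows whose spliced transcript is added as a transcript row
    (mirroring alignments that mix genes with the reference transcripts).
    """
    L = model.length
    base_at_ref: dict[str, list[str]] = {}
    ins_after: dict[str, dict[int, str]] = {}
    variant_by_id: dict[str, MutatedVariant | None] = {}

    for row_id, variant in gene_variants:
        variant_by_id[row_id] = variant
        if variant is None:
            if model.sequence is None:
                raise ValueError("reference rows require a gene model with a sequence")
            base_at_ref[row_id] = list(model.sequence)
            ins_after[row_id] = {}
            continue
        bases = [GAP] * L
        ins: dict[int, str] = {}
        last_ref = 0
        for v, r in enumerate(variant.ref_map):
            if r >= 0:
                bases[r] = variant.sequence[v]
                last_ref = int(r)
            else:
                ins[last_ref] = ins.get(last_ref, "") + variant.sequence[v]
        base_at_ref[row_id] = bases
        ins_after[row_id] = ins

    ins_width = [0] * L
    for ins in ins_after.values():
        for j, s in ins.items():
            ins_width[j] = max(ins_width[j], len(s))

    def gene_row_string(row_id: str) -> str:
        parts: list[str] = []
        bases = base_at_ref[row_id]
        ins = ins_after[row_id]
        for j in range(L):
            parts.append(bases[j])
            if ins_width[j]:
                s = ins.get(j, "")
                parts.append(s + GAP * (ins_width[j] - len(s)))
        return "".join(parts)

    def transcript_row_string(row_id: str) -> str:
        bases = base_at_ref[row_id]
        parts: list[str] = []
        for j in range(L):
            if model._region[j] == 0 and bases[j] != GAP:
                parts.append(bases[j])
            else:
                parts.append(GAP)
            if ins_width[j]:
                parts.append(GAP * ins_width[j])
        return "".join(parts)

    rows = [
        AlignedRow(row_id, row_id, "gene", gene_row_string(row_id))
        for row_id, _ in gene_variants
    ]
    for row_id in transcript_of:
        if row_id not in base_at_ref:
            raise KeyError(f"transcript source {row_id!r} is not a gene row")
        rows.append(AlignedRow(f"{row_id}_tx", row_id, "transcript", transcript_row_string(row_id)))
    return AlignmentBundle(rows)


def infer_coordinate_map(reference: str, query: str) -> np.ndarray:
    """Variant-to-reference coordinate map via global pairwise alignment.

    Uses match +1 / mismatch -1 / gap -2 scoring; returns, per query
    position, the aligned reference coordinate (-1 where the query base is an
    insertion relative to the reference).  Intended for externally supplied
    variants that lack a generator coordinate map.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(reference.upper(), query.upper())[0]
    ref_map = np.full(len(query), -1, dtype=np.int64)
    for (rs, re_), (qs, qe) in zip(*aln.aligned):
        ref_map[qs:qe] = np.arange(rs, re_)
    return ref_map
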