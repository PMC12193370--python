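"""File formats: FASTA, BED-like annotations, placement TSV, Ct/conflict/stats CSV.

Internal coordinates are 0-based half-open.  BED output keeps that
convention; the conflict and stats CSV exports use 1-based inclusive
coordinates, matching the spreadsheet exports this pipeline mirrors.
"""
from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

from .annotate import AlignedRow, AlignmentBundle, ConflictEntry, ConflictTable
from .models import ContigPlacement, GeneModel, Interval
from .phylo import DistanceMatrix
from .variant_stats import MatResult

FASTA_WIDTH = 70


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(path, records: list[tuple[str, str, str]]) -> None:
    """Write (id, description, sequence) triples, wrapped at 70 columns."""
    seqrecords = [
        SeqRecord(Seq(seq), id=rid, description=desc) for rid, desc, seq in records
    ]
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=FASTA_WIDTH)
        writer.write_file(seqrecords)


def read_fasta(path) -> dict[str, str]:
    """id → uppercase sequence (gaps preserved for aligned FASTA)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _description_fields(description: str) -> dict[str, str]:
    fields = {}
    for token in description.split()[1:]:  # token 0 is the id
        if "=" in token:
            key, value = token.split("=", 1)
            fields[key] = value
    return fields


def write_alignment_bundle(path, bundle: AlignmentBundle) -> None:
    write_fasta(
        path,
        [
            (r.row_id, f"population={r.population} role={r.role}", r.seq)
            for r in bundle.rows
        ],
    )


def read_alignment_bundle(path) -> AlignmentBundle:
    """Aligned FASTA whose descriptions carry ``population=... role=gene|transcript``."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = _description_fields(rec.description)
        rows.append(
            AlignedRow(
                rec.id,
                fields.get("population", rec.id),
                fields.get("role", "gene"),
                str(rec.seq).upper(),
            )
        )
    return AlignmentBundle(rows)


# ---------------------------------------------------------------------------
# gene annotation (BED-like: 0-based half-open)
# ---------------------------------------------------------------------------


def write_annotation(path, model: GeneModel) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        tagged = [(iv, "exon", utr) for iv, utr in zip(model.exons, model.exon_utr)]
        tagged += [(iv, "intron", utr) for iv, utr in zip(model.introns, model.intron_utr)]
        for iv, kind, utr in sorted(tagged, key=lambda t: t[0].start):
            w.writerow([model.gene_id, iv.start, iv.end, kind, int(utr)])


def read_annotation(path, sequence: str | None = None) -> GeneModel:
    exons, introns, exon_utr, intron_utr = [], [], [], []
    gene_id = None
    length = 0
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row:
                continue
            gene_id = row[0]
            iv = Interval(int(row[1]), int(row[2]))
            utr = bool(int(row[4])) if len(row) > 4 else False
            if row[3] == "exon":
                exons.append(iv)
                exon_utr.append(utr)
            elif row[3] == "intron":
                introns.append(iv)
                intron_utr.append(utr)
            else:
                raise ValueError(f"unknown region kind {row[3]!r}")
            length = max(length, iv.end)
    if gene_id is None:
        raise ValueError(f"empty annotation file {path}")
    return GeneModel(
        gene_id, sequence, exons, introns, exon_utr, intron_utr,
        length=None if sequence is not None else length,
    )


# ---------------------------------------------------------------------------
# contig placements
# ---------------------------------------------------------------------------


def write_placements(path, placements: list[ContigPlacement]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["contig_id", "ref_start", "ref_end", "sequence"])
        for p in placements:
            w.writerow([p.contig_id, p.ref_start, p.ref_end, p.sequence])


def read_placements(path) -> list[ContigPlacement]:
    df = pd.read_csv(path, sep="\t")
    return [
        ContigPlacement(str(r.contig_id), int(r.ref_start), int(r.ref_end), str(r.sequence))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# conflicts and stats (1-based inclusive CSV exports)
# ---------------------------------------------------------------------------


def write_conflicts_csv(path, table: ConflictTable) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gene_id", "coordinate_1based", "region", "n_variant_rows"])
        for e in table.entries:
            w.writerow([table.gene_id, e.coordinate + 1, e.region, e.n_variant_rows])


def read_conflicts_csv(path) -> ConflictTable:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty conflict table {path}")
    gene_id = str(df["gene_id"].iloc[0])
    entries = tuple(
        ConflictEntry(int(r.coordinate_1based) - 1, str(r.region), int(r.n_variant_rows))
        for r in df.itertuples()
    )
    return ConflictTable(gene_id, entries)


def write_stats_csv(path, results: list[MatResult]) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "n_total": r.n_total,
            "n_exon": r.n_exon,
            "pct_exon": r.pct_exon,
            "n_intron": r.n_intron,
            "pct_intron": r.pct_intron,
            "intron_fraction": r.intron_fraction,
            "fisher_p": r.fisher_p,
            "mat": r.mat,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# phylogenetics
# ---------------------------------------------------------------------------


def write_phylip(path, dm: DistanceMatrix) -> None:
    """Lower-triangle PHYLIP distance matrix (NaN rendered as 'NA')."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for i, label in enumerate(dm.labels):
            cells = []
            for j in range(i):
                v = dm.values[i, j]
                cells.append("NA" if v != v else f"{v:.6f}")
            fh.write("\t".join([label, *cells]).rstrip() + "\n")


def write_newick(path, tree) -> None:
    tree.write(str(path), format="newick")
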