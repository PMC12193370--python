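"""Shared domain containers for the mutational-landscape / expression pipeline.

All genomic coordinates are 0-based, half-open internally.  Exported CSV files
use 1-based inclusive coordinates (the convention of the annotation-viewer
exports this pipeline mirrors); BED output stays 0-based half-open as BED
requires.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DNA = frozenset("ACGT")

GENE_ROLES = ("target", "reference")


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based, half-open interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap(self, other: "Interval") -> int:
        """Length of the intersection with *other* (0 if disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class GeneModel:
    """A gene sequence partitioned into ordered exon and intron intervals.

    The exons and introns must be disjoint, sorted, and jointly tile
    ``[0, length)``; the gene begins and ends with an exon.  UTR membership is
    tracked per interval (``exon_utr`` / ``intron_utr``) but UTR exons count as
    exonic and UTR introns as intronic in every statistic.

    ``sequence`` may be ``None`` for annotation-only models (e.g. built from a
    BED file); ``length`` is then mandatory.
    """

    def __init__(
        self,
        gene_id: str,
        sequence: str | None,
        exons: list[Interval],
        introns: list[Interval],
        exon_utr: list[bool] | None = None,
        intron_utr: list[bool] | None = None,
        length: int | None = None,
    ) -> None:
        self.gene_id = gene_id
        if sequence is not None:
            sequence = sequence.upper()
            extra = set(sequence) - DNA
            if extra:
                raise ValueError(f"non-ACGT characters in gene sequence: {sorted(extra)}")
            if length is None:
                length = len(sequence)
            elif length != len(sequence):
                raise ValueError("explicit length disagrees with sequence length")
        if length is None:
            raise ValueError("either a sequence or an explicit length is required")
        self.sequence = sequence
        self.length = length
        self.exons = sorted(exons)
        self.introns = sorted(introns)
        self.exon_utr = list(exon_utr) if exon_utr is not None else [False] * len(self.exons)
        self.intron_utr = list(intron_utr) if intron_utr is not None else [False] * len(self.introns)
        if len(self.exon_utr) != len(self.exons) or len(self.intron_utr) != len(self.introns):
            raise ValueError("UTR flag lists must match the interval lists in length")
        self._validate_tiling()
        region = np.zeros(self.length, dtype=np.uint8)
        for iv in self.introns:
            region[iv.start : iv.end] = 1
        self._region = region

    def _validate_tiling(self) -> None:
        if not self.exons:
            raise ValueError("a gene model needs at least one exon")
        tagged = sorted(
            [(iv, "exon") for iv in self.exons] + [(iv, "intron") for iv in self.introns],
            key=lambda t: t[0].start,
        )
        pos = 0
        for iv, _ in tagged:
            if iv.start != pos:
                raise ValueError("exons and introns must tile the gene without gaps or overlaps")
            pos = iv.end
        if pos != self.length:
            raise ValueError("exon/intron intervals do not cover the full gene length")
        if tagged[0][1] != "exon" or tagged[-1][1] != "exon":
            raise ValueError("a gene must begin and end with an exon")

    # -- region arithmetic ------------------------------------------------

    def region_of(self, pos: int) -> str:
        """``'exon'`` or ``'intron'`` for a 0-based gene coordinate."""
        if not (0 <= pos < self.length):
            raise ValueError(f"coordinate {pos} outside gene [0, {self.length})")
        return "intron" if self._region[pos] else "exon"

    def region_lengths(self, exclude: Interval | None = None) -> tuple[int, int]:
        """(exon_len, intron_len) in bp, optionally excluding an interval.

        The exclusion supports dual accounting of genes with one dominant
        intron (full gene vs. gene minus that intron).
        """
        exon_len = sum(len(iv) for iv in self.exons)
        intron_len = sum(len(iv) for iv in self.introns)
        if exclude is not None:
            exon_len -= sum(iv.overlap(exclude) for iv in self.exons)
            intron_len -= sum(iv.overlap(exclude) for iv in self.introns)
        return exon_len, intron_len

    def intron_fraction(self, exclude: Interval | None = None) -> float:
        exon_len, intron_len = self.region_lengths(exclude)
        total = exon_len + intron_len
        if total <= 0:
            raise ValueError("exclusion removes the entire gene")
        return intron_len / total

    def spliced_sequence(self) -> str:
        """Concatenation of the exon subsequences (the reference transcript)."""
        if self.sequence is None:
            raise ValueError("gene model has no sequence to splice")
        return "".join(self.sequence[iv.start : iv.end] for iv in self.exons)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"GeneModel({self.gene_id!r}, length={self.length}, "
            f"{len(self.exons)} exons, {len(self.introns)} introns)"
        )


@dataclass(frozen=True)
class MutationSpec:
    """Ground-truth knobs of the population mutation generator.

    sub_rate_exon / sub_rate_intron
        Per-site substitution probabilities (one draw per site, so these are
        the expected observable mismatch densities, no multiple hits).
    indel_rate_intron
        Per-intron-site probability of initiating an indel; indels are
        restricted to introns so the variant-to-reference coordinate map
        stays monotonic over exons.
    indel_len_dist
        Success parameter of the geometric indel-length distribution.
    ti_tv_kappa
        Transition/transversion rate ratio; a substituted site becomes a
        transition with probability kappa / (kappa + 2).
    """

    sub_rate_exon: float = 0.01
    sub_rate_intron: float = 0.03
    indel_rate_intron: float = 0.0
    indel_len_dist: float = 0.5
    ti_tv_kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate_exon", "sub_rate_intron", "indel_rate_intron"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.indel_len_dist <= 1.0:
            raise ValueError("indel_len_dist must be in (0, 1]")
        if self.ti_tv_kappa <= 0:
            raise ValueError("ti_tv_kappa must be > 0")


@dataclass(frozen=True)
class ContigPlacement:
    """A contig placed on the reference coordinate frame (substitutions only)."""

    contig_id: str
    ref_start: int
    ref_end: int
    sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.ref_start < self.ref_end):
            raise ValueError("require 0 <= ref_start < ref_end")
        if len(self.sequence) != self.ref_end - self.ref_start:
            raise ValueError("contig sequence length must equal its reference span")
        extra = set(self.sequence.upper()) - DNA
        if extra:
            raise ValueError(f"non-ACGT characters in contig: {sorted(extra)}")


class CtDataset:
    """Ct values indexed by (group, biological replicate, technical replicate, gene role).

    Stored as a pandas DataFrame with columns
    ``group, br, tech_rep, gene_role, ct``.  Every (group, br) cell must carry
    at least one technical replicate for both the target and the reference
    gene, and all Ct values must be finite and positive.
    """

    COLUMNS = ("group", "br", "tech_rep", "gene_role", "ct")

    def __init__(self, records: pd.DataFrame) -> None:
        missing = set(self.COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        df = records.loc[:, list(self.COLUMNS)].copy()
        df["group"] = df["group"].astype(str)
        df["br"] = df["br"].astype(int)
        df["tech_rep"] = df["tech_rep"].astype(int)
        df["gene_role"] = df["gene_role"].astype(str)
        df["ct"] = df["ct"].astype(float)
        bad_roles = set(df["gene_role"]) - set(GENE_ROLES)
        if bad_roles:
            raise ValueError(f"unknown gene roles: {sorted(bad_roles)}")
        if not np.all(np.isfinite(df["ct"])) or (df["ct"] <= 0).any():
            raise ValueError("Ct values must be finite and positive")
        for (group, br), cell in df.groupby(["group", "br"]):
            roles = set(cell["gene_role"])
            if roles != set(GENE_ROLES):
                raise ValueError(
                    f"cell (group={group!r}, br={br}) lacks {set(GENE_ROLES) - roles} measurements"
                )
        self.records = df.reset_index(drop=True)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_records(cls, rows: list[tuple]) -> "CtDataset":
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @classmethod
    def from_csv(cls, path) -> "CtDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    # -- accessors --------------------------------------------------------

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.records["group"]))

    def brs(self, group: str) -> list[int]:
        sub = self.records[self.records["group"] == group]
        return sorted(sub["br"].unique())

    def ct_values(self, group: str, br: int, gene_role: str) -> np.ndarray:
        df = self.records
        mask = (df["group"] == group) & (df["br"] == br) & (df["gene_role"] == gene_role)
        return df.loc[mask, "ct"].to_numpy()

    def copy(self) -> "CtDataset":
        return CtDataset(self.records.copy())

    def __len__(self) -> int:
        return len(self.records)
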