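"""MAT statistic and Fisher's exact contingency analysis of conflict counts.

The mutation accumulation tendency (MAT) of a gene is the ratio between the
fraction of conflictual coordinates that fall in introns and the fraction of
the gene's length occupied by introns; MAT > 1 indicates an excess intronic
mutation load relative to a uniform per-base-pair placement.

The contingency test compares the observed exon/intron split of conflictual
positions with the split expected under per-base-pair uniformity within each
region:  [[n_exon, exon_len − n_exon], [n_intron, intron_len − n_intron]],
evaluated with a two-sided Fisher's exact test (point-probability method).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .annotate import ConflictTable, count_by_region
from .models import GeneModel, Interval


@dataclass(frozen=True)
class MatResult:
    gene_id: str
    n_total: int
    n_exon: int
    n_intron: int
    pct_exon: float
    pct_intron: float
    intron_fraction: float
    mat: float
    fisher_p: float


def compute_mat(n_total: int, n_intron: int, intron_fraction: float) -> float:
    """(n_intron / n_total) / intron_fraction, unrounded."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_intron <= n_total:
        raise ValueError("require 0 <= n_intron <= n_total")
    if not 0.0 < intron_fraction < 1.0:
        raise ValueError("intron_fraction must be strictly between 0 and 1")
    return (n_intron / n_total) / intron_fraction


def region_percentages(n_total: int, n_exon: int, n_intron: int) -> tuple[float, float]:
    """(pct_exon, pct_intron) rounded to 2 decimals."""
    if n_total <= 0 or n_exon + n_intron != n_total:
        raise ValueError("counts must be positive and sum to n_total")
    return round(100.0 * n_exon / n_total, 2), round(100.0 * n_intron / n_total, 2)


def build_contingency(n_exon: int, n_intron: int, exon_len: int, intron_len: int) -> np.ndarray:
    """2x2 table of conflictual vs non-conflictual positions by region."""
    for name, v in (("n_exon", n_exon), ("n_intron", n_intron)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if n_exon > exon_len:
        raise ValueError(f"n_exon={n_exon} exceeds exon_len={exon_len}")
    if n_intron > intron_len:
        raise ValueError(f"n_intron={n_intron} exceeds intron_len={intron_len}")
    return np.array(
        [[n_exon, exon_len - n_exon], [n_intron, intron_len - n_intron]], dtype=np.int64
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one (within
    relative tolerance 1e-7).  Degenerate tables with an empty margin carry
    no information and return 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    m1, m2 = a + b, c + d
    n1 = a + c
    n = m1 + m2
    if m1 == 0 or m2 == 0 or n1 == 0 or n1 == n:
        return 1.0
    k = np.arange(max(0, n1 - m2), min(n1, m1) + 1)
    logpmf = (
        gammaln(m1 + 1)
        - gammaln(k + 1)
        - gammaln(m1 - k + 1)
        + gammaln(m2 + 1)
        - gammaln(n1 - k + 1)
        - gammaln(m2 - n1 + k + 1)
        + gammaln(n1 + 1)
        + gammaln(n - n1 + 1)
        - gammaln(n + 1)
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[a - k[0]]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def gene_stats(
    table: ConflictTable,
    model: GeneModel,
    exclude: Interval | None = None,
) -> MatResult:
    """Full per-gene summary: counts, percentages, intron fraction, MAT, Fisher p.

    ``exclude`` removes an interval from both the conflict entries and the
    region lengths — the dual-accounting mode used when a single dominant
    intron would otherwise swamp the statistic.
    """
    counts = count_by_region(table, model, exclude=exclude)
    exon_len, intron_len = model.region_lengths(exclude)
    total_len = exon_len + intron_len
    if total_len <= 0:
        raise ValueError("exclusion removes the entire gene")
    intron_fraction = intron_len / total_len
    if counts.n_total == 0:
        return MatResult(table.gene_id, 0, 0, 0, 0.0, 0.0, intron_fraction, float("nan"), 1.0)
    mat = compute_mat(counts.n_total, counts.n_intron, intron_fraction)
    p = fisher_exact_2x2(build_contingency(counts.n_exon, counts.n_intron, exon_len, intron_len))
    return MatResult(
        table.gene_id,
        counts.n_total,
        counts.n_exon,
        counts.n_intron,
        counts.pct_exon,
        counts.pct_intron,
        intron_fraction,
        mat,
        p,
    )
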