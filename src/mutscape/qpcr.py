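"""All-pairs ΔCt expression analysis with replicate repair and rank testing.

The Livak variant implemented here forms, within each biological replicate
(BR), every possible ΔCt = target Ct − reference Ct across the technical
replicates (3 × 3 → 9 values per BR), converts them to relative expression
2^−ΔCt, pools the expression values of a group's BRs, and compares groups by

* log2 fold change = log2(mean pooled expression of the experimental group /
  mean pooled expression of the baseline group), and
* a two-sided Mann–Whitney U test on the two pooled 2^−ΔCt samples.

Perfect amplification efficiency (doubling per cycle) is assumed throughout.

Repair of spoiled measurements happens in two passes, single-value outliers
first: a Ct is omitted when it deviates from its BR's median by more than
z × the scaled median absolute deviation, and a whole BR is "eccentric" —
all its technical replicates replaced by the BR's own mean — when its mean
Ct deviates from the mean of its companion BRs' means by more than z × their
standard deviation.  Outliers are removed first because a single wild Ct
would otherwise drag its BR's mean and masquerade as an eccentric BR.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import CtDataset

MAD_SCALE = 1.4826  # consistency factor for normal data


@dataclass(frozen=True)
class DeltaCtSet:
    """All-pairs ΔCt values of one biological replicate."""

    group: str
    br: int
    delta_cts: np.ndarray

    @property
    def expression_values(self) -> np.ndarray:
        return np.exp2(-self.delta_cts)


@dataclass(frozen=True)
class RepairAction:
    kind: str  # "omit_outlier" | "replace_eccentric_br"
    group: str
    br: int
    gene_role: str
    tech_rep: int | None
    deviation: float


@dataclass(frozen=True)
class RepairReport:
    actions: tuple[RepairAction, ...]

    def __len__(self) -> int:
        return len(self.actions)

    def of_kind(self, kind: str) -> list[RepairAction]:
        return [a for a in self.actions if a.kind == kind]


@dataclass(frozen=True)
class ExpressionResult:
    experiment: str
    comparison: tuple[str, str]  # (experimental group, baseline group)
    log2_fc: float
    u_stat: float
    p_value: float
    n1: int
    n2: int


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def all_pairs_delta_ct(
    target_cts,
    reference_cts,
    group: str = "",
    br: int = 0,
) -> DeltaCtSet:
    """Cartesian-product ΔCt within one BR, target-major order."""
    t = np.asarray(target_cts, dtype=float)
    r = np.asarray(reference_cts, dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("target and reference Ct lists must be non-empty")
    deltas = (t[:, None] - r[None, :]).ravel()
    return DeltaCtSet(group, br, deltas)


def repair_eccentric_br(
    dataset: CtDataset, z_threshold: float = 3.0
) -> tuple[CtDataset, RepairReport]:
    """Omit single-Ct outliers, then replace eccentric BRs by their mean.

    Returns the repaired dataset and a report listing every action.  Groups
    with a single BR cannot be assessed for eccentricity and are skipped with
    a warning.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be > 0")
    df = dataset.records.copy()
    actions: list[RepairAction] = []

    # pass 1: single-value outliers (median/MAD within each BR cell)
    drop: list[int] = []
    for (group, br, role), cell in df.groupby(["group", "br", "gene_role"]):
        ct = cell["ct"].to_numpy()
        if ct.size < 3:
            continue
        med = np.median(ct)
        mad = MAD_SCALE * np.median(np.abs(ct - med))
        dev = np.abs(ct - med)
        for idx, d in zip(cell.index, dev):
            if d > z_threshold * mad and d > 0:
                drop.append(idx)
                actions.append(RepairAction("omit_outlier", group, br, role, int(df.loc[idx, "tech_rep"]), float(d)))
    df = df.drop(index=drop)

    # pass 2: eccentric BRs (mean vs companion-BR means within group & role)
    for (group, role), sub in df.groupby(["group", "gene_role"]):
        means = sub.groupby("br")["ct"].mean()
        if len(means) < 2:
            warnings.warn(
                f"group {group!r} has a single BR for role {role!r}; eccentricity check skipped",
                stacklevel=2,
            )
            continue
        for br, m in means.items():
            others = means.drop(index=br)
            center = others.mean()
            spread = others.std(ddof=1) if len(others) > 1 else 0.0
            dev = abs(m - center)
            if dev > z_threshold * spread and dev > 0:
                mask = (df["group"] == group) & (df["br"] == br) & (df["gene_role"] == role)
                df.loc[mask, "ct"] = m
                actions.append(RepairAction("replace_eccentric_br", group, int(br), role, None, float(dev)))

    return CtDataset(df.reset_index(drop=True)), RepairReport(tuple(actions))


def delta_ct_sets(dataset: CtDataset, group: str) -> list[DeltaCtSet]:
    """One all-pairs DeltaCtSet per biological replicate of a group."""
    if group not in dataset.groups:
        raise ValueError(f"unknown group {group!r}")
    return [
        all_pairs_delta_ct(
            dataset.ct_values(group, br, "target"),
            dataset.ct_values(group, br, "reference"),
            group=group,
            br=br,
        )
        for br in dataset.brs(group)
    ]


def pooled_expression(sets: list[DeltaCtSet]) -> np.ndarray:
    """Concatenated 2^-ΔCt values across a group's BRs."""
    if not sets:
        raise ValueError("no ΔCt sets to pool")
    return np.concatenate([s.expression_values for s in sets])


def log2_fold_change(experimental: list[DeltaCtSet], baseline: list[DeltaCtSet]) -> float:
    """log2 of the ratio of pooled mean relative expressions."""
    e = pooled_expression(experimental)
    b = pooled_expression(baseline)
    mb = float(b.mean())
    if mb <= 0:
        raise ValueError("baseline mean expression must be positive")
    return float(np.log2(e.mean() / mb))


def mann_whitney_u(x, y, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (midranks for ties).

    Exact p by enumeration when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= exact_max_n and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def run_expression_analysis(
    datasets,
    comparisons: list[tuple[str, str]],
    combine: str = "per-experiment",
    repair: bool = False,
    z_threshold: float = 3.0,
) -> list[ExpressionResult]:
    """End-to-end group comparisons on one or several experiments.

    ``datasets`` is a single CtDataset or a mapping experiment-label →
    CtDataset.  ΔCt values are always formed within a BR of its own
    experiment; ``combine='cumulative'`` pools the resulting expression
    values across experiments before testing, ``'per-experiment'`` reports
    one result per experiment and comparison.
    """
    if combine not in ("per-experiment", "cumulative"):
        raise ValueError("combine must be 'per-experiment' or 'cumulative'")
    if isinstance(datasets, CtDataset):
        datasets = {"experiment": datasets}
    if repair:
        datasets = {label: repair_eccentric_br(ds, z_threshold)[0] for label, ds in datasets.items()}

    results: list[ExpressionResult] = []

    def compare(label: str, sets_by_group: dict[str, list[DeltaCtSet]]) -> None:
        for g_exp, g_base in comparisons:
            for g in (g_exp, g_base):
                if g not in sets_by_group:
                    raise ValueError(f"unknown group {g!r} in comparison {(g_exp, g_base)}")
            fc = log2_fold_change(sets_by_group[g_exp], sets_by_group[g_base])
            e = pooled_expression(sets_by_group[g_exp])
            b = pooled_expression(sets_by_group[g_base])
            u, p = mann_whitney_u(e, b)
            results.append(ExpressionResult(label, (g_exp, g_base), fc, u, p, e.size, b.size))

    if combine == "per-experiment":
        for label, ds in datasets.items():
            compare(label, {g: delta_ct_sets(ds, g) for g in ds.groups})
    else:
        merged: dict[str, list[DeltaCtSet]] = {}
        for ds in datasets.values():
            for g in ds.groups:
                merged.setdefault(g, []).extend(delta_ct_sets(ds, g))
        compare("cumulative", merged)
    return results
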