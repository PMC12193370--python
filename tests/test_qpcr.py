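from itertools import combinations

import numpy as np
import pytest

from mutscape import (
    CtDataset,
    all_pairs_delta_ct,
    generate_ct_dataset,
    log2_fold_change,
    mann_whitney_u,
    repair_eccentric_br,
    run_expression_analysis,
)
from mutscape.qpcr import delta_ct_sets, pooled_expression


def permutation_mann_whitney(x, y) -> float:
    """Exact two-sided p by enumerating all group-label assignments.

    For each split of the pooled sample into groups of the observed sizes,
    the U statistic is recomputed; the two-sided p is 2*min(P(U<=u), P(U>=u))
    capped at 1 (the convention of the implementation under test).
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_stat(x, y)
    us = []
    idx = range(len(pooled))
    for chosen in combinations(idx, n1):
        chosen = set(chosen)
        xs = [pooled[i] for i in idx if i in chosen]
        ys = [pooled[i] for i in idx if i not in chosen]
        us.append(u_stat(xs, ys))
    us = np.asarray(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


class TestAllPairsDeltaCt:
    def test_cartesian_product_order_and_expression(self):
        s = all_pairs_delta_ct([20, 21], [15])
        np.testing.assert_allclose(s.delta_cts, [5, 6])
        np.testing.assert_allclose(s.expression_values, [2.0**-5, 2.0**-6])

    def test_equal_cts_give_unit_expression(self):
        s = all_pairs_delta_ct([20, 20, 20], [20, 20, 20])
        assert len(s.delta_cts) == 9
        np.testing.assert_allclose(s.expression_values, 1.0)

    def test_three_by_three_yields_nine(self):
        s = all_pairs_delta_ct([20.1, 20.2, 20.3], [18.1, 18.3, 18.2])
        assert len(s.delta_cts) == 9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            all_pairs_delta_ct([], [15])


class TestRepair:
    def test_clean_noise_free_dataset_is_untouched(self):
        ds, _ = generate_ct_dataset(sd_tech=0.0, sd_br=0.0, log2_effects={"A": 2}, seed=1)
        repaired, report = repair_eccentric_br(ds, z_threshold=3.0)
        assert len(report) == 0
        assert repaired.records["ct"].tolist() == ds.records["ct"].tolist()

    def test_single_shifted_ct_is_omitted_not_replaced(self):
        ds, truth = generate_ct_dataset(
            sd_tech=0.0, sd_br=0.0, n_outliers=1, outlier_magnitude=8.0, seed=2
        )
        repaired, report = repair_eccentric_br(ds, z_threshold=3.0)
        assert len(report.of_kind("omit_outlier")) == 1
        assert len(report.of_kind("replace_eccentric_br")) == 0
        (action,) = report.of_kind("omit_outlier")
        group, br, tech_rep, role, _ = truth.outliers[0]
        assert (action.group, action.br, action.gene_role, action.tech_rep) == (
            group,
            br,
            role,
            tech_rep,
        )
        assert len(repaired) == len(ds) - 1

    def test_wholesale_shifted_br_is_replaced_by_its_mean(self):
        ds, _ = generate_ct_dataset(sd_tech=0.0, sd_br=0.0, seed=3)
        df = ds.records.copy()
        mask = (df["group"] == "A") & (df["br"] == 2) & (df["gene_role"] == "target")
        df.loc[mask, "ct"] += 5.0
        shifted_mean = df.loc[mask, "ct"].mean()
        repaired, report = repair_eccentric_br(CtDataset(df), z_threshold=3.0)
        eccentric = report.of_kind("replace_eccentric_br")
        assert [(a.group, a.br, a.gene_role) for a in eccentric] == [("A", 2, "target")]
        assert len(report.of_kind("omit_outlier")) == 0
        np.testing.assert_allclose(repaired.ct_values("A", 2, "target"), shifted_mean)
        # companion BRs untouched
        np.testing.assert_allclose(
            repaired.ct_values("A", 1, "target"), ds.ct_values("A", 1, "target")
        )

    def test_single_br_group_warns_and_skips(self):
        rows = []
        for role in ("target", "reference"):
            for tr in (1, 2, 3):
                rows.append(("solo", 1, tr, role, 20.0 + tr * 0.1))
        with pytest.warns(UserWarning, match="single BR"):
            repaired, report = repair_eccentric_br(CtDataset.from_records(rows))
        assert len(report) == 0


class TestLog2FoldChange:
    def test_identical_groups_give_zero(self):
        ds, _ = generate_ct_dataset(groups=("control", "A"), sd_tech=0.0, sd_br=0.0, seed=4)
        fc = log2_fold_change(delta_ct_sets(ds, "A"), delta_ct_sets(ds, "control"))
        assert fc == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_effect_recovered_exactly(self):
        ds, _ = generate_ct_dataset(
            groups=("control", "A"), log2_effects={"A": 3.3}, sd_tech=0.0, sd_br=0.0, seed=5
        )
        fc = log2_fold_change(delta_ct_sets(ds, "A"), delta_ct_sets(ds, "control"))
        assert fc == pytest.approx(3.3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_antisymmetry(self, seed):
        ds, _ = generate_ct_dataset(
            groups=("control", "A"), log2_effects={"A": 1.0}, sd_tech=0.4, sd_br=0.4, seed=seed
        )
        a = delta_ct_sets(ds, "A")
        c = delta_ct_sets(ds, "control")
        assert log2_fold_change(a, c) == pytest.approx(-log2_fold_change(c, a))

    def test_expression_values_are_positive(self):
        ds, _ = generate_ct_dataset(sd_tech=1.0, sd_br=1.0, seed=6)
        for g in ds.groups:
            assert (pooled_expression(delta_ct_sets(ds, g)) > 0).all()


class TestMannWhitney:
    def test_fully_separated_triples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_samples_are_uninformative(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_large_shift_is_detected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, size=50)
        y = rng.normal(2, 1, size=50)
        _, p = mann_whitney_u(x, y)
        assert p < 1e-3

    def test_exact_matches_permutation_oracle_on_small_samples(self):
        rng = np.random.default_rng(11)
        for n in range(2, 9):
            for n1 in range(1, n):
                values = rng.permutation(np.arange(1, n + 1) + rng.random(n) * 0.1)
                x, y = values[:n1], values[n1:]
                _, p = mann_whitney_u(x, y)
                assert p == pytest.approx(permutation_mann_whitney(x, y), rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestRunExpressionAnalysis:
    def test_noise_free_two_experiments_per_experiment_equals_cumulative(self):
        datasets = {
            f"exp{k}": generate_ct_dataset(
                log2_effects={"A": 3.0, "B": 1.0}, sd_tech=0.0, sd_br=0.0, seed=k
            )[0]
            for k in (1, 2)
        }
        per = run_expression_analysis(datasets, [("A", "control")], combine="per-experiment")
        cum = run_expression_analysis(datasets, [("A", "control")], combine="cumulative")
        assert per[0].log2_fc == pytest.approx(per[1].log2_fc) == pytest.approx(3.0)
        assert cum[0].log2_fc == pytest.approx(3.0)
        assert cum[0].n1 == per[0].n1 + per[1].n1

    def test_sign_pattern_of_graded_effects(self):
        ds, _ = generate_ct_dataset(
            log2_effects={"A": 3.0, "B": 1.0}, sd_tech=0.1, sd_br=0.1, seed=8
        )
        results = run_expression_analysis(ds, [("A", "control"), ("B", "control"), ("B", "A")])
        by_cmp = {r.comparison: r for r in results}
        assert by_cmp[("A", "control")].log2_fc > 0
        assert by_cmp[("B", "control")].log2_fc > 0
        assert by_cmp[("B", "A")].log2_fc < 0

    def test_noise_free_b_vs_a_difference(self):
        ds, _ = generate_ct_dataset(
            log2_effects={"A": 3.0, "B": 1.0}, sd_tech=0.0, sd_br=0.0, seed=9
        )
        (result,) = run_expression_analysis(ds, [("B", "A")])
        assert result.log2_fc == pytest.approx(-2.0, abs=1e-12)

    def test_unknown_group_rejected(self):
        ds, _ = generate_ct_dataset(seed=10)
        with pytest.raises(ValueError, match="unknown group"):
            run_expression_analysis(ds, [("missing", "control")])

    def test_repair_flag_runs_end_to_end(self):
        ds, _ = generate_ct_dataset(
            log2_effects={"A": 2.0}, sd_tech=0.2, sd_br=0.2, n_outliers=1, seed=11
        )
        raw = run_expression_analysis(ds, [("A", "control")])
        fixed = run_expression_analysis(ds, [("A", "control")], repair=True)
        assert np.isfinite(fixed[0].log2_fc)
        assert fixed[0].n1 <= raw[0].n1  # an omitted Ct can only shrink the pool
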