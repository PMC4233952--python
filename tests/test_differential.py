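"""Sample categorization, statistical tests, FDR, and stability calling."""

import numpy as np
import pandas as pd
import pytest

from mrnadecay import (
    DifferentialStabilityTest,
    ExpressionMatrix,
    HalfLifeTable,
    SampleSheet,
    benjamini_hochberg,
    categorize_sample,
    delta_delta_ct,
    half_life_ratio_test,
    one_way_anova,
    total_expression_differential,
    two_sample_t,
)

from conftest import anova_oracle, bh_oracle, pooled_t_oracle

LN2 = np.log(2.0)


class TestCategorizeSample:
    @pytest.mark.parametrize(
        "status, score, expected",
        [
            ("non-OA", 3, "normal"),
            ("non-OA", 0, "normal"),
            ("non-OA", 9, "normal"),
            ("OA", 6, "intact_OA"),
            ("OA", 9, "intact_OA"),
            ("OA", 10, "fibrillated_OA"),
            ("OA", 15, "fibrillated_OA"),
        ],
    )
    def test_grading_rule(self, status, score, expected):
        assert categorize_sample(status, score) == expected

    def test_unclassifiable_combination_is_an_explicit_error(self):
        with pytest.raises(ValueError, match="unclassifiable"):
            categorize_sample("non-OA", 12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="joint_status"):
            categorize_sample("maybe", 3)
        with pytest.raises(ValueError, match="non-negative"):
            categorize_sample("OA", -1)


class TestOneWayAnova:
    def test_identical_groups_give_f_zero(self):
        f, p = one_way_anova([(1, 2, 3), (1, 2, 3), (1, 2, 3)])
        assert f == 0.0
        assert p == 1.0

    def test_separation_limit(self):
        _, p_loose = one_way_anova([(0, 0.1), (10, 10.1)])
        _, p_tight = one_way_anova([(0, 0.001), (10, 10.001)])
        assert p_tight < p_loose < 0.01

    def test_all_constant_resolves_to_null(self):
        f, p = one_way_anova([(5.0, 5.0), (5.0, 5.0)])
        assert (f, p) == (0.0, 1.0)

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            groups = [rng.normal(rng.uniform(-1, 1), 1.0, 5) for _ in range(3)]
            f, p = one_way_anova(groups)
            f_o, p_o = anova_oracle(groups)
            assert f == pytest.approx(f_o, rel=1e-9)
            assert p == pytest.approx(p_o, rel=1e-9)

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError, match=">=2"):
            one_way_anova([(1.0,), (2.0, 3.0)])


class TestTwoSampleT:
    def test_identical_groups(self):
        assert two_sample_t((1, 2, 3), (1, 2, 3)) == (0.0, 1.0)

    def test_gross_separation(self):
        _, p = two_sample_t((1, 2, 3), (11, 12, 13))
        assert p < 0.01

    def test_matches_pooled_variance_oracle(self):
        a, b = (2.1, 2.9, 3.4), (4.0, 5.2, 4.4)
        t, p = two_sample_t(a, b)
        t_o, p_o = pooled_t_oracle(a, b)
        assert t == pytest.approx(t_o, rel=1e-9)
        assert p == pytest.approx(p_o, rel=1e-9)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(2, 8))
            b = rng.normal(0.5, 2, rng.integers(2, 8))
            t, p = two_sample_t(a, b)
            t_o, p_o = pooled_t_oracle(a, b)
            assert t == pytest.approx(t_o, rel=1e-9)
            assert p == pytest.approx(p_o, rel=1e-9)

    def test_welch_differs_under_unequal_variance(self):
        a = (1.0, 1.1, 0.9, 1.2)
        b = (3.0, 8.0, -2.0)
        t_student, p_student = two_sample_t(a, b, equal_variance=True)
        t_welch, p_welch = two_sample_t(a, b, equal_variance=False)
        assert t_student != t_welch
        assert p_student != p_welch


class TestBenjaminiHochberg:
    def test_uniformly_spaced_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(benjamini_hochberg([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        p = rng.random(100)
        np.testing.assert_allclose(benjamini_hochberg(p), bh_oracle(p), rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            benjamini_hochberg([0.1, 1.2])

    def test_controls_fdr_under_global_null(self):
        rng = np.random.default_rng(7)
        rejections = 0
        trials = 200
        for _ in range(trials):
            p = rng.random(50)
            rejections += int((benjamini_hochberg(p) < 0.05).sum() > 0)
        # under the global null P(any BH rejection) <= alpha
        assert rejections / trials < 0.05 + 3 * np.sqrt(0.05 * 0.95 / trials)


class TestDeltaDeltaCt:
    def test_no_change_gives_fold_one(self):
        assert delta_delta_ct(20, 20, 20, 20) == 1.0

    def test_one_cycle_shift_halves_expression(self):
        assert delta_delta_ct(25, 20, 24, 20) == 0.5

    def test_hand_computed_example(self):
        # ddCt = (26.3-19.1) - (24.8-19.4) = 1.8
        assert delta_delta_ct(26.3, 19.1, 24.8, 19.4) == pytest.approx(
            2.0**-1.8, rel=1e-12
        )


def _t0_cohort(log2_means_by_group, n_donors=3, jitter=0.0, seed=0):
    """Build a normalized time-0 matrix with specified per-group log2 means."""
    rng = np.random.default_rng(seed)
    rows, cols, data = [], [], {}
    genes = [f"g{i}" for i in range(len(next(iter(log2_means_by_group.values()))))]
    for group, means in log2_means_by_group.items():
        for d in range(n_donors):
            sid = f"{group}_d{d}_t0"
            cols.append(sid)
            rows.append(
                {"sample_id": sid, "donor_id": f"{group}_d{d}", "group": group, "time_h": 0.0}
            )
            data[sid] = 2.0 ** (np.asarray(means) + jitter * rng.normal(size=len(genes)))
    matrix = ExpressionMatrix(
        pd.DataFrame(data, index=genes), normalized=True
    )
    return matrix, SampleSheet(pd.DataFrame(rows))


class TestTotalExpressionDifferential:
    def test_identical_group_means_not_significant(self):
        means = np.full(20, 10.0)
        matrix, sheet = _t0_cohort(
            {"normal": means, "intact_OA": means, "fibrillated_OA": means},
            jitter=0.05,
        )
        res = total_expression_differential(matrix, sheet)
        assert not res["significant"].any()

    def test_true_four_fold_shift_called_exactly(self):
        base = np.linspace(8.0, 12.0, 50)
        shifted = base.copy()
        shifted[:10] += 2.0  # 4-fold on log2 scale
        matrix, sheet = _t0_cohort(
            {"normal": base, "intact_OA": shifted, "fibrillated_OA": shifted},
            jitter=0.02,
        )
        res = total_expression_differential(matrix, sheet)
        assert set(res.index[res["significant"]]) == {f"g{i}" for i in range(10)}

    def test_fold_change_gate_blocks_sub_threshold_shift(self):
        base = np.full(5, 10.0)
        shifted = base + np.log2(1.9)  # strong but < 2-fold
        matrix, sheet = _t0_cohort(
            {"normal": base, "intact_OA": shifted, "fibrillated_OA": base},
            jitter=0.01,
        )
        res = total_expression_differential(matrix, sheet)
        assert (res["p"] < 0.05).all()
        assert not res["significant"].any()

    def test_global_intensity_shift_changes_no_calls(self):
        base = np.linspace(8.0, 12.0, 30)
        shifted = base.copy()
        shifted[:5] += 2.0
        groups = {"normal": base, "intact_OA": shifted, "fibrillated_OA": shifted}
        m1, sheet = _t0_cohort(groups, jitter=0.02)
        m2 = ExpressionMatrix(m1.intensities * 2.0**1.7, normalized=True)
        r1 = total_expression_differential(m1, sheet)
        r2 = total_expression_differential(m2, sheet)
        pd.testing.assert_series_equal(r1["significant"], r2["significant"])

    def test_requires_normalized_matrix(self):
        matrix, sheet = _t0_cohort({"normal": [1.0], "intact_OA": [1.0]})
        raw = ExpressionMatrix(matrix.intensities, normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            total_expression_differential(raw, sheet)


def _hl_table(hl_by_donor: dict, groups: dict):
    hl = pd.DataFrame(hl_by_donor)
    return HalfLifeTable(
        half_life=hl,
        slope=-LN2 / hl,
        r_squared=pd.DataFrame(1.0, index=hl.index, columns=hl.columns),
        retained=hl.notna().all(axis=1),
        donor_groups=pd.Series(groups),
        cap_h=24.0,
    )


class TestHalfLifeRatioTest:
    def test_identical_group_half_lives_not_tested(self):
        table = _hl_table(
            {"n1": [4.0], "n2": [4.2], "o1": [4.1], "o2": [3.9]},
            {"n1": "normal", "n2": "normal", "o1": "intact_OA", "o2": "intact_OA"},
        )
        res = half_life_ratio_test(table, "normal_vs_intact_OA")
        assert not res["tested"].any()
        assert not res["significant"].any()

    def test_wide_scatter_gene_tested_but_not_significant(self):
        # ratio of means 2.5 but within-group scatter spans both means
        table = _hl_table(
            {
                "n1": [2.0],
                "n2": [12.0],
                "n3": [4.0],
                "n4": [10.0],
                "o1": [1.0],
                "o2": [6.0],
                "o3": [2.0],
                "o4": [2.2],
            },
            {
                "n1": "normal",
                "n2": "normal",
                "n3": "normal",
                "n4": "normal",
                "o1": "intact_OA",
                "o2": "intact_OA",
                "o3": "intact_OA",
                "o4": "intact_OA",
            },
        )
        res = half_life_ratio_test(table, "normal_vs_intact_OA")
        row = res.iloc[0]
        assert row["tested"]
        assert row["ratio"] == pytest.approx(2.8 / 7.0)
        assert row["fdr"] >= 0.05
        assert not row["significant"]

    def test_label_swap_inverts_ratios_and_flips_direction(self):
        rng = np.random.default_rng(5)
        X = np.exp(rng.normal(1.5, 0.6, size=(6, 40)))
        X[:3, :8] *= 3.0  # first 8 genes more stable in group A
        y = np.array(["a"] * 3 + ["b"] * 3)
        fwd = DifferentialStabilityTest(reference="a").fit(X, y)
        rev = DifferentialStabilityTest(reference="b").fit(X, y)
        np.testing.assert_allclose(
            fwd.results_["ratio"], 1.0 / rev.results_["ratio"], rtol=1e-12
        )
        np.testing.assert_array_equal(fwd.significant_, rev.significant_)
        tested = fwd.results_["tested"].to_numpy()
        flipped = fwd.results_.loc[tested, "direction"].map(
            {"stabilized": "destabilized", "destabilized": "stabilized"}
        )
        np.testing.assert_array_equal(
            flipped.to_numpy(), rev.results_.loc[tested, "direction"].to_numpy()
        )

    def test_pooled_scheme_uses_all_oa_donors(self):
        table = _hl_table(
            {
                "n1": [9.0],
                "n2": [9.0],
                "i1": [3.0],
                "i2": [3.0],
                "f1": [1.0],
                "f2": [1.0],
            },
            {
                "n1": "normal",
                "n2": "normal",
                "i1": "intact_OA",
                "i2": "intact_OA",
                "f1": "fibrillated_OA",
                "f2": "fibrillated_OA",
            },
        )
        res = half_life_ratio_test(table, "normal_vs_pooled_OA")
        # pooled mean is (3+3+1+1)/4 = 2, not the mean of subgroup means (2.5)
        assert res.iloc[0]["mean_pooled_OA"] == pytest.approx(2.0)

    def test_noiseless_truth_calls_are_destabilized_only(self, noiseless_cohort):
        from mrnadecay import build_decay_sets, detection_filter, half_life_table

        _, matrix, sheet, truth = noiseless_cohort
        detected = detection_filter(matrix, sheet)
        sets = build_decay_sets(matrix, sheet, detected)
        table = half_life_table(sets)
        res = half_life_ratio_test(table, "normal_vs_pooled_OA")
        called = res.index[res["significant"]]
        assert len(called) > 0
        assert truth.loc[called, "destabilized"].all()
        assert (res.loc[called, "direction"] == "destabilized").all()
        # every resolvable truly destabilized gene is recovered
        resolvable = truth.index[truth["destabilized"] & truth["short_lived"]]
        resolvable = resolvable.intersection(res.index)
        assert res.loc[resolvable, "significant"].all()

    def test_empty_tested_set_is_not_an_error(self):
        table = _hl_table(
            {"n1": [4.0, 5.0], "n2": [4.0, 5.0], "o1": [4.0, 5.0], "o2": [4.0, 5.0]},
            {"n1": "normal", "n2": "normal", "o1": "intact_OA", "o2": "intact_OA"},
        )
        res = half_life_ratio_test(table, "normal_vs_intact_OA")
        assert len(res) == 2
        assert res["fdr"].isna().all()

    def test_fdr_universe_all_is_more_conservative(self):
        rng = np.random.default_rng(9)
        X = np.exp(rng.normal(1.5, 0.5, size=(8, 60)))
        X[:4, :6] *= 3.5
        y = np.array(["a"] * 4 + ["b"] * 4)
        gated = DifferentialStabilityTest(fdr_universe="tested").fit(X, y)
        full = DifferentialStabilityTest(fdr_universe="all").fit(X, y)
        t = gated.results_["tested"]
        assert (
            full.results_.loc[t, "fdr"].to_numpy()
            >= gated.results_.loc[t, "fdr"].to_numpy() - 1e-12
        ).all()

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        est = DifferentialStabilityTest(ratio_threshold=3.0, log_scale=True)
        assert clone(est).get_params()["ratio_threshold"] == 3.0
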