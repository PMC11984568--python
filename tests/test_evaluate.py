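import itertools

import numpy as np
import pytest

from cbctplan import (
    ImageGrid,
    NTCPModel,
    compute_mae_me,
    ntcp,
    paired_signed_rank,
    population_percentile,
    v_metric,
    voxmin,
)


class TestVoxMin:
    def test_identical_inputs_and_zero_grid(self):
        g = np.arange(9.0).reshape(3, 3)
        assert np.array_equal(voxmin([g, g, g]), g)
        assert np.array_equal(voxmin([g, np.zeros((3, 3))]), np.zeros((3, 3)))

    def test_against_brute_force(self):
        rng = np.random.default_rng(1)
        grids = [rng.uniform(0, 70, (3, 3)) for _ in range(5)]
        expected = np.array(
            [[min(g[i, j] for g in grids) for j in range(3)] for i in range(3)]
        )
        assert np.allclose(voxmin(grids), expected)
        assert all(np.all(voxmin(grids) <= g) for g in grids)

    def test_shape_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            voxmin([np.zeros((2, 2)), np.zeros((3, 3))])
        with pytest.raises(ValueError):
            voxmin([])


class TestVMetric:
    def test_uniform_and_zero_dose(self):
        mask = np.ones((2, 2), dtype=bool)
        assert v_metric(np.full((2, 2), 54.25), mask, 54.25) == 100.0
        assert v_metric(np.zeros((2, 2)), mask, 54.25) == 0.0

    def test_hand_counted_case(self):
        dose = np.array([2.0, 1.9, 1.8, 1.0])
        mask = np.ones(4, dtype=bool)
        # cutoff 1.88 Gy: exactly two of four voxels pass
        assert v_metric(dose, mask, 2.0, 0.94) == 50.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            v_metric(np.zeros((2, 2)), np.zeros((2, 2), bool), 1.0)


class TestMaeMe:
    def grid(self, vals):
        return ImageGrid(np.asarray(vals, dtype=float), 1.0)

    def test_identity_and_constant_shift(self):
        ref = self.grid([[0.0, 10.0], [20.0, 30.0]])
        ext = np.ones((2, 2), bool)
        assert compute_mae_me(ref, ref, ext) == (0.0, 0.0)
        shifted = self.grid(ref.values + 50.0)
        assert compute_mae_me(shifted, ref, ext) == (50.0, 50.0)

    def test_hand_arithmetic(self):
        ref = self.grid([[0.0, 0.0, 0.0]])
        test = self.grid([[10.0, -20.0, 30.0]])
        ext = np.ones((1, 3), bool)
        mae, me = compute_mae_me(test, ref, ext)
        assert mae == pytest.approx(20.0)
        assert me == pytest.approx(10.0 / 1.5)  # 6.67

    def test_air_voxels_excluded_by_reference_value(self):
        ref = self.grid([[-1000.0, 0.0]])
        test = self.grid([[0.0, 50.0]])  # huge error in the air voxel
        mae, me = compute_mae_me(test, ref, np.ones((1, 2), bool))
        assert mae == me == 50.0

    def test_all_excluded_rejected(self):
        ref = self.grid([[-1000.0]])
        with pytest.raises(ValueError):
            compute_mae_me(ref, ref, np.ones((1, 1), bool))


class TestNtcp:
    def test_logistic_midpoint_and_hand_value(self):
        m = NTCPModel("x", 0.0, {"mean_d": 0.0001})
        assert ntcp({"mean_d": 0.0}, m) == pytest.approx(0.5)
        m2 = NTCPModel("x", -4.0, {"mean_d": 0.1})
        # linear predictor 2 -> logistic(2) = 0.8808
        assert ntcp({"mean_d": 60.0}, m2) == pytest.approx(0.8808, abs=1e-4)

    def test_monotone_in_positive_coefficient_metric(self):
        m = NTCPModel("x", -2.0, {"mean_d": 0.05})
        vals = [ntcp({"mean_d": d}, m) for d in np.linspace(0, 80, 9)]
        assert np.all(np.diff(vals) > 0)

    def test_missing_metric_rejected(self):
        m = NTCPModel("x", -2.0, {"mean_d": 0.05})
        with pytest.raises(KeyError):
            ntcp({"other": 1.0}, m)


class TestPopulationPercentile:
    def test_constant_values(self):
        assert population_percentile([3.0] * 10) == 3.0

    def test_coverage_type_lower_is_worse(self):
        # best-to-worst is 23..1; rank 20.7 interpolates 0.3*4 + 0.7*3
        vals = list(range(1, 24))
        assert population_percentile(vals, 0.90, worse="lower") == pytest.approx(3.3)

    def test_ntcp_type_higher_is_worse(self):
        vals = list(range(1, 24))
        assert population_percentile(vals, 0.90, worse="higher") == pytest.approx(20.7)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, 23)
        shuffled = rng.permutation(vals)
        assert population_percentile(vals) == population_percentile(shuffled)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            population_percentile([1.0])
        with pytest.raises(ValueError):
            population_percentile([1.0, 2.0], fraction=1.0)


def exact_signed_rank_p(diffs):
    """Exhaustive two-sided p over all sign assignments (no ties/zeros)."""
    diffs = np.asarray(diffs, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    w_obs = min(ranks[diffs > 0].sum(), ranks[diffs < 0].sum())
    count = 0
    total = 0
    for signs in itertools.product([1, -1], repeat=len(diffs)):
        w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
        w = min(w_plus, ranks.sum() - w_plus)
        total += 1
        if w <= w_obs:
            count += 1
    return count / total


class TestPairedSignedRank:
    def test_identical_lists_degenerate(self):
        with pytest.warns(UserWarning):
            res = paired_signed_rank([1.0] * 6, [1.0] * 6)
        assert res.pvalue == 1.0 and not res.significant and res.degenerate

    def test_all_positive_differences_match_enumeration(self):
        b = np.zeros(6)
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = paired_signed_rank(a, b)
        assert res.pvalue == pytest.approx(exact_signed_rank_p(a - b))
        assert res.pvalue == pytest.approx(2.0 / 64.0)

    @pytest.mark.parametrize("n", [6, 8, 10, 12])
    def test_random_pairs_match_enumeration(self, n):
        rng = np.random.default_rng(n)
        a = rng.normal(size=n)
        b = a + rng.normal(0.4, 1.0, size=n)
        res = paired_signed_rank(a, b)
        assert res.pvalue == pytest.approx(exact_signed_rank_p(a - b))

    def test_swap_flips_statistic_sign_keeps_p(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=9)
        b = rng.normal(size=9)
        r1 = paired_signed_rank(a, b)
        r2 = paired_signed_rank(b, a)
        assert r1.statistic == -r2.statistic
        assert r1.pvalue == r2.pvalue

    def test_short_or_unequal_samples_rejected(self):
        with pytest.raises(ValueError):
            paired_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestEvaluatePlan:
    def test_zero_weight_plan_reports_baseline_risk(self, compact_setup):
        from cbctplan import Plan, evaluate_plan, default_ntcp_models

        s = compact_setup
        n = sum(b.n_spots for b in s["beams"])
        plan = Plan(np.zeros(n), s["beams"], s["scenarios"])
        report = evaluate_plan(plan, s["image"], s["structs"])
        assert report.v94 == {"ctv_high": 0.0, "ctv_low": 0.0}
        assert all(v == 0.0 for v in report.oar_mean.values())
        for model in default_ntcp_models():
            expected = 100.0 / (1.0 + np.exp(-model.intercept))
            assert report.ntcp[model.name] == pytest.approx(expected)

    def test_error_free_cbct_evaluates_identically(self, compact_setup):
        from cbctplan import ErrorFieldParams, Plan, evaluate_plan, generate_cbct

        s = compact_setup
        n = sum(b.n_spots for b in s["beams"])
        rng = np.random.default_rng(0)
        plan = Plan(rng.uniform(0, 5, n), s["beams"], s["scenarios"])
        cbct = generate_cbct(s["image"], s["structs"], ErrorFieldParams.zero(), seed=1)
        r_truth = evaluate_plan(plan, s["image"], s["structs"])
        r_cbct = evaluate_plan(plan, cbct, s["structs"])
        assert r_truth.v94 == r_cbct.v94
        assert r_truth.oar_mean == r_cbct.oar_mean

    def test_mae_me_passthrough(self, compact_setup):
        from cbctplan import Plan, evaluate_plan

        s = compact_setup
        n = sum(b.n_spots for b in s["beams"])
        plan = Plan(np.zeros(n), s["beams"], s["scenarios"])
        shifted = s["image"].with_values(s["image"].values + 30.0)
        report = evaluate_plan(
            plan, s["image"], s["structs"], planning_image=shifted
        )
        assert report.mae == pytest.approx(30.0)
        assert report.me == pytest.approx(30.0)
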