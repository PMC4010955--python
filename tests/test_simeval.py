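"""Synthetic scenarios, error laws, Wilson intervals and the studies."""

import numpy as np
import pytest

from permglm.simeval import (
    GROUP_SCENARIOS,
    ScenarioSpec,
    draw_errors,
    group_scenario,
    induce_correlation,
    ks_two_sample,
    make_scenario_design,
    run_distribution_comparison,
    run_error_power_study,
    simulate_group_dataset,
    simulate_regression_dataset,
    wilson_ci,
)


class TestScenarioDesign:
    @pytest.mark.parametrize("N", [8, 12, 40])
    def test_continuous_regressors_are_orthogonal(self, N):
        x1, z1, ones = make_scenario_design("continuous", "continuous", N)
        assert x1[0] == -1.0 and x1[-1] == 1.0
        assert np.allclose(np.diff(x1), np.diff(x1)[0])
        assert abs(x1 @ z1) < 1e-12 and abs(z1.sum()) < 1e-12

    def test_discrete_construction_n8(self):
        x1, z1, _ = make_scenario_design("discrete", "discrete", 8)
        np.testing.assert_array_equal(x1, [1, 1, 1, 1, -1, -1, -1, -1])
        np.testing.assert_array_equal(z1, [-1, -1, 1, 1, 1, 1, -1, -1])
        assert x1 @ z1 == 0

    def test_discrete_requires_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            make_scenario_design("discrete", "discrete", 10)


class TestInduceCorrelation:
    def test_zero_rho_is_identity(self, rng):
        x, z = rng.standard_normal((2, 20))
        xr, zr = induce_correlation(x, z, 0.0)
        np.testing.assert_array_equal(xr, x)
        np.testing.assert_array_equal(zr, z)

    def test_target_correlation_on_orthonormal_columns(self, rng):
        A = np.linalg.qr(rng.standard_normal((50, 2)))[0]
        xr, zr = induce_correlation(A[:, 0], A[:, 1], 0.8)
        assert xr @ zr / np.sqrt((xr @ xr) * (zr @ zr)) == pytest.approx(
            0.8, abs=1e-10
        )

    def test_transform_is_invertible(self, rng):
        x, z = rng.standard_normal((2, 15))
        xr, zr = induce_correlation(x, z, 0.8)
        K = np.array([[1.0, 0.8], [0.8, 1.0]])
        L = np.linalg.cholesky(K).T
        back = np.column_stack([xr, zr]) @ np.linalg.inv(L)
        np.testing.assert_allclose(back, np.column_stack([x, z]), atol=1e-10)

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            induce_correlation(np.ones(4), np.ones(4), 1.0)


class TestErrorLaws:
    @pytest.mark.parametrize("law", ["normal", "uniform", "exponential"])
    def test_standardised_moments(self, law):
        x = draw_errors(law, 1_000_000, seed=0)
        assert x.mean() == pytest.approx(0.0, abs=0.01)
        assert x.var() == pytest.approx(1.0, abs=0.02)

    def test_weibull_moments(self):
        # shape 1/3 is very heavy-tailed; the variance converges slowly
        x = draw_errors("weibull", 2_000_000, seed=1)
        assert x.mean() == pytest.approx(0.0, abs=0.02)
        assert x.var() == pytest.approx(1.0, rel=0.15)

    def test_uniform_support_is_sqrt3(self):
        x = draw_errors("uniform", 100_000, seed=2)
        assert np.sqrt(3.0) * 0.99 < x.max() <= np.sqrt(3.0)

    def test_seed_reproducibility(self):
        a = draw_errors("exponential", 100, seed=5)
        b = draw_errors("exponential", 100, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_unknown_law(self):
        with pytest.raises(ValueError):
            draw_errors("cauchy", 10, seed=0)


class TestGroupDatasets:
    def test_all_table_scenarios_constructible(self):
        for scenario, (sizes, variants) in GROUP_SCENARIOS.items():
            for letter in variants:
                spec = group_scenario(scenario, letter)
                Y, M, C, vg = simulate_group_dataset(spec, 3, seed=0)
                assert Y.shape == (sum(sizes), 3)
                assert M.shape == (sum(sizes), len(sizes))
                assert C.shape == (len(sizes), len(sizes) - 1)
                assert vg.n_groups == len(sizes)

    def test_scenario1_structure_and_variances(self):
        spec = group_scenario(1, "a")
        Y, M, C, vg = simulate_group_dataset(spec, 40_000, seed=3)
        assert Y.shape[0] == 12
        assert Y[:8].var() == pytest.approx(5.0, rel=0.05)
        assert Y[8:].var() == pytest.approx(1.0, rel=0.05)
        assert abs(Y.mean()) < 0.05

    def test_four_group_signal_spacing(self):
        spec = group_scenario(4, "c", signal=True)
        Y, M, C, vg = simulate_group_dataset(spec, 30_000, seed=4)
        means = [Y[lab == g].mean() for g, lab in
                 [(g, np.repeat(np.arange(4), (40, 30, 20, 10))) for g in range(4)]]
        np.testing.assert_allclose(means, [0.0, -0.33, -0.67, -1.0], atol=0.02)

    def test_regression_dataset_truth(self):
        spec = ScenarioSpec(N=12, beta1=0.5, error_law="normal")
        Y, M, C = simulate_regression_dataset(spec, 50_000, seed=5)
        truth = M @ np.array([0.5, 0.5, 1.0])
        np.testing.assert_allclose(Y.mean(axis=1), truth, atol=0.03)
        np.testing.assert_array_equal(C.ravel(), [1, 0, 0])


class TestWilsonAndKs:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [(49, 1000, 3.7, 6.4), (729, 1000, 70.1, 75.6), (0, 10, 0.0, 27.8)],
    )
    def test_wilson_interval_reproduces_printed_values(self, k, n, lo, hi):
        got_lo, got_hi = wilson_ci(k, n)
        assert round(100 * got_lo, 1) == lo
        assert round(100 * got_hi, 1) == hi

    def test_wilson_rejects_bad_input(self):
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(5, 3)

    def test_ks_degenerate_cases(self, rng):
        a = rng.standard_normal(100)
        D, p = ks_two_sample(a, a)
        assert D == 0.0
        D, _ = ks_two_sample(np.zeros(50), np.ones(50) + 1)
        assert D == 1.0
        with pytest.raises(ValueError):
            ks_two_sample(a, [])

    def test_ks_calibration_under_null(self, rng):
        rejections = sum(
            ks_two_sample(rng.standard_normal(500), rng.standard_normal(500))[1]
            <= 0.05
            for _ in range(200)
        )
        assert rejections / 200 == pytest.approx(0.05, abs=0.045)


class TestStudies:
    def test_null_scenario_controls_error_rate(self):
        spec = group_scenario(5, "a")  # exhaustive 70 relabelings
        res = run_error_power_study(spec, n_reps=400, J=1000, seed=9)
        r = res[("freedman_lane", "G")]
        # exact test: rejection rate 3/70 = 4.29%, well inside Wilson CI
        assert r.ci_lo <= 4.29 <= r.ci_hi or abs(r.proportion - 4.29) < 2.5

    def test_huge_effect_gives_full_power(self):
        spec = ScenarioSpec(
            group_sizes=(6, 6), group_variances=(0.01, 0.01), signal=True
        )
        res = run_error_power_study(spec, n_reps=100, J=500, seed=10)
        assert res[("freedman_lane", "G")].proportion == 100.0

    def test_f_and_g_streams_identical_for_balanced_single_variance(self):
        spec = group_scenario(6, "a")  # equal sizes, equal variances
        res = run_error_power_study(
            spec, n_reps=150, J=200, seed=11, statistics=("F", "G")
        )
        assert (
            res[("freedman_lane", "F")].proportion
            == res[("freedman_lane", "G")].proportion
        )

    def test_distribution_comparison_flags_f_not_g(self):
        """Scenario 4 heteroscedasticity: the pooled F statistic's null
        distribution shifts across variance configurations (KS rejects far
        above alpha) while G's stays put."""
        ks = run_distribution_comparison(
            4, n_voxels=300, n_reps=40, seed=12, configs=("a", "c", "e")
        )
        f_rates = [v for (st, _), v in ks.rejection_fraction.items() if st == "F"]
        g_rates = [v for (st, _), v in ks.rejection_fraction.items() if st == "G"]
        assert min(f_rates) > 0.5
        assert max(g_rates) < 0.2

    def test_distribution_comparison_self_null(self):
        """Comparing same-variance configurations rejects at roughly the
        Bonferroni-corrected alpha."""
        ks = run_distribution_comparison(
            6, n_voxels=300, n_reps=40, seed=13, configs=("a", "b")
        )
        g = ks.rejection_fraction[("G", ("a", "b"))]
        assert g <= 0.2
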