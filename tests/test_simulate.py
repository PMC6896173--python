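"""Synthetic data generator: covariance scenarios, effects, censoring, drivers."""

import numpy as np
import pandas as pd
import pytest

from hiscompage.simulate import (
    SimulationConfig,
    build_covariance,
    draw_effects,
    generate_expression,
    generate_survival,
    run_power_experiment,
    run_type1_experiment,
    simulate_dataset,
    solve_censoring_rate,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"I": 0},
            {"m_p": 1.5},
            {"c_p": 1.0},
            {"m_s": 300},
            {"scenario": 5},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)

    def test_causal_count_rounds(self):
        assert SimulationConfig(m_p=0.1, m_s=50).n_causal == 5
        assert SimulationConfig(m_p=0.3, m_s=50).n_causal == 15


class TestCovarianceScenarios:
    def test_scenario1_exactly_diagonal(self):
        sigma = build_covariance(1, 200, 50)
        np.testing.assert_array_equal(sigma, 0.2 * np.eye(200))

    def test_scenario2_constant_correlation_block(self):
        sigma = build_covariance(2, 10, 4)
        assert sigma[0, 0] == pytest.approx(0.2)
        assert sigma[0, 1] == pytest.approx(0.2 * 0.02)
        assert sigma[0, 5] == 0.0  # causal/noise blocks uncorrelated

    def test_scenario3_autoregressive_hand_values(self):
        sigma = build_covariance(3, 5, 2)
        np.testing.assert_allclose(sigma[:2, :2], [[0.2, 0.02], [0.02, 0.2]])

    def test_scenario4_symmetric_psd(self):
        for seed in range(5):
            sigma = build_covariance(4, 30, 20, seed=seed)
            np.testing.assert_allclose(sigma, sigma.T)
            assert np.linalg.eigvalsh(sigma).min() >= -1e-10

    def test_l_larger_than_k_rejected(self):
        with pytest.raises(ValueError):
            build_covariance(1, 5, 6)


class TestExpression:
    def test_large_sample_moments_match_target(self):
        cfg = SimulationConfig(I=50_000, K=4, m_s=4, m_p=0.5, scenario=1)
        X = generate_expression(cfg, rng=np.random.default_rng(0))
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=0.01)
        np.testing.assert_allclose(np.cov(X.T), build_covariance(1, 4, 2), atol=0.01)

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(I=10, K=6, m_s=3, seed=99)
        np.testing.assert_array_equal(generate_expression(cfg), generate_expression(cfg))


class TestEffects:
    def test_null_flag_gives_zero_vector(self):
        cfg = SimulationConfig(null=True, m_p=0.5)
        assert not draw_effects(cfg, rng=np.random.default_rng(0)).any()

    def test_zero_causal_genes_gives_zero_vector(self):
        cfg = SimulationConfig(m_p=0.0)
        assert not draw_effects(cfg, rng=np.random.default_rng(0)).any()

    def test_uniform_support_and_mean(self):
        cfg = SimulationConfig(K=10_000, m_s=10_000, m_p=1.0)
        eff = draw_effects(cfg, rng=np.random.default_rng(1))
        assert eff.min() >= 0.2 and eff.max() <= 0.6
        assert eff.mean() == pytest.approx(0.4, abs=0.01)

    def test_nonzero_effects_confined_to_causal_prefix(self):
        cfg = SimulationConfig(m_p=0.1, m_s=50, K=200)
        eff = draw_effects(cfg, rng=np.random.default_rng(2))
        assert np.all(eff[:5] > 0) and not eff[5:].any()


class TestCensoringRate:
    def test_homogeneous_rates_half_censoring_matches_symmetry(self):
        # two independent exponentials with equal rates: P(censor first) = 1/2
        lam = solve_censoring_rate(0.5, np.full(100, 0.005))
        assert lam == pytest.approx(0.005, rel=1e-8)

    def test_zero_target_gives_zero_rate(self):
        assert solve_censoring_rate(0.0, [0.005, 0.01]) == 0.0

    def test_heterogeneous_rates_monte_carlo_cross_check(self):
        rates = np.tile([0.005, 0.01], 1)
        lam = solve_censoring_rate(0.25, rates)
        rng = np.random.default_rng(0)
        n = 200_000
        t = rng.exponential(1 / np.repeat(rates, n // 2))
        c = rng.exponential(1 / lam, size=n)
        assert np.mean(c < t) == pytest.approx(0.25, abs=0.01)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            solve_censoring_rate(1.0, [0.005])


class TestSurvivalGeneration:
    def test_no_censoring_gives_all_events(self):
        rng = np.random.default_rng(0)
        cfg = SimulationConfig(I=200, K=1, m_s=1, c_p=0.0)
        t, e, lam = generate_survival(np.zeros((200, 1)), np.zeros(1), cfg, rng=rng)
        assert e.all() and lam == 0.0

    def test_null_mean_survival_is_reciprocal_baseline_hazard(self):
        rng = np.random.default_rng(1)
        cfg = SimulationConfig(I=100_000, K=1, m_s=1, c_p=0.0)
        t, e, _ = generate_survival(np.zeros((100_000, 1)), np.zeros(1), cfg, rng=rng)
        assert t.mean() == pytest.approx(1 / 0.005, rel=0.01)

    @pytest.mark.parametrize("c_p", [0.1, 0.3, 0.5])
    def test_empirical_censoring_matches_target(self, c_p):
        rng = np.random.default_rng(10)
        n = 10_000
        x = rng.normal(0, 1, (n, 3))
        eff = np.array([0.4, 0.3, 0.2])
        cfg = SimulationConfig(I=n, K=3, m_s=3, m_p=1.0, c_p=c_p)
        t, e, _ = generate_survival(x, eff, cfg, rng=rng)
        assert 1.0 - e.mean() == pytest.approx(c_p, abs=0.02)


class TestSimulateDataset:
    def test_block_pathways_and_causal_placement(self):
        cfg = SimulationConfig(K=200, m_s=50, m_p=0.3)
        ds = simulate_dataset(cfg, rng=np.random.default_rng(0))
        assert ds.pathways.names == ["P1", "P2", "P3", "P4"]
        assert all(len(p.genes) == 50 for p in ds.pathways)
        # nonzero effects only among pathway 1's genes
        assert np.all(ds.true_effects[:15] > 0) and not ds.true_effects[15:].any()
        assert ds.X.n_samples == 80 and ds.X.n_genes == 200

    def test_deterministic_given_rng_seed(self):
        cfg = SimulationConfig(I=20, K=20, m_s=10, m_p=0.2, c_p=0.3)
        a = simulate_dataset(cfg, rng=np.random.default_rng(4))
        b = simulate_dataset(cfg, rng=np.random.default_rng(4))
        np.testing.assert_array_equal(a.X.values, b.X.values)
        np.testing.assert_array_equal(a.survival.time, b.survival.time)


class TestExperimentDrivers:
    _base = dict(I=30, K=12, m_s=4, m_p=0.5, scenario=1)

    def test_type1_table_deterministic_and_well_formed(self):
        kw = dict(
            methods=["gsea1", "wald"], c_p_values=[0.0], n_replicates=3, n_perm=6,
            seed=11, base_config=SimulationConfig(**self._base),
            lambda_gene=2.0, lambda_pathway=2.0,
        )
        a = run_type1_experiment(**kw)
        b = run_type1_experiment(**kw)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["method"]) == {"gsea1", "wald"}
        assert np.all((a["ci_low"] <= a["rate"]) & (a["rate"] <= a["ci_high"]))

    def test_alpha_one_rejects_everything(self):
        tab = run_type1_experiment(
            methods=["globaltest"], c_p_values=[0.0], n_replicates=3, n_perm=6,
            alpha=1.0, seed=0, base_config=SimulationConfig(**self._base),
            lambda_gene=2.0, lambda_pathway=2.0,
        )
        assert (tab["rate"] == 1.0).all()

    def test_power_table_deterministic(self):
        kw = dict(
            methods=["hiscom"], m_p_values=[0.25, 0.5], c_p_values=[0.0],
            n_replicates=2, n_perm=5, seed=3,
            base_config=SimulationConfig(**self._base),
            lambda_gene=2.0, lambda_pathway=2.0,
        )
        a = run_power_experiment(**kw)
        b = run_power_experiment(**kw)
        pd.testing.assert_frame_equal(a, b)
        assert list(a["m_p"]) == [0.25, 0.5]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            run_type1_experiment(
                methods=["nope"], c_p_values=[0.0], n_replicates=1, n_perm=2,
                base_config=SimulationConfig(**self._base),
                lambda_gene=1.0, lambda_pathway=1.0,
            )
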