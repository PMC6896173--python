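"""Latent scores, penalized objective, ALS estimator and CV selection."""

import numpy as np
import pandas as pd
import pytest

import lifelines

from hiscompage import (
    HierarchyDesign,
    als_fit,
    compute_latent_scores,
    cv_select_lambdas,
    penalized_objective,
)
from hiscompage.simulate import SimulationConfig, generate_survival, simulate_dataset
from tests.conftest import random_survival


def _single_gene_design():
    return HierarchyDesign(["P1"], [np.array([0])], 1)


def _lifelines_coef(x, time, event, columns=None):
    df = pd.DataFrame(x, columns=columns or [f"x{j}" for j in range(x.shape[1])])
    df["time"], df["event"] = time, event
    cph = lifelines.CoxPHFitter()
    cph.fit(df, "time", "event", fit_options={"precision": 1e-9})
    return cph.params_.to_numpy()


class TestLatentScores:
    def test_single_gene_identity(self):
        x = np.arange(5.0).reshape(5, 1)
        F = compute_latent_scores(x, _single_gene_design(), [np.array([1.0])])
        np.testing.assert_array_equal(F[:, 0], x[:, 0])

    def test_weighted_sum_arithmetic(self):
        x = np.array([[2.0, 4.0]])
        d = HierarchyDesign(["P1"], [np.array([0, 1])], 2)
        F = compute_latent_scores(x, d, [np.array([0.5, 0.5])])
        assert F[0, 0] == 3.0

    def test_overlapping_gene_contributes_to_each_pathway(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 3))
        d = HierarchyDesign(["P1", "P2"], [np.array([0, 1]), np.array([1, 2])], 3)
        W = [np.array([0.3, -1.2]), np.array([0.7, 0.4])]
        F = compute_latent_scores(x, d, W)
        # brute-force double loop over (pathway, member) pairs
        expected = np.zeros((6, 2))
        for j, (cols, w) in enumerate(zip(d.pathway_index, W)):
            for c, wk in zip(cols, w):
                expected[:, j] += x[:, c] * wk
        np.testing.assert_allclose(F, expected, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            compute_latent_scores(np.zeros((3, 2)), _single_gene_design(), [np.array([1.0])])


class TestPenalizedObjective:
    def test_zero_penalty_equals_partial_loglik(self):
        rng = np.random.default_rng(1)
        t, e = random_survival(rng, 10)
        F = rng.normal(size=(10, 2))
        B = np.array([0.5, -0.2])
        from hiscompage.cox import CoxTimes

        phi = penalized_objective(t, e, F, B, [np.ones(3), np.ones(2)], 0.0, 0.0)
        assert phi == pytest.approx(CoxTimes(t, e).loglik(F @ B))

    def test_pure_penalty_hand_value(self):
        # no events -> loglik 0; lambda_gene=2, single weight 3: -0.5*2*9 = -9
        phi = penalized_objective(
            [1.0, 2.0], [0, 0], np.zeros((2, 1)), [0.0], [np.array([3.0])], 2.0, 0.0
        )
        assert phi == -9.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            penalized_objective([1.0], [1], np.zeros((1, 1)), [0.0], [np.array([0.0])], -1.0, 0.0)


class TestAlsFit:
    def test_single_gene_zero_penalty_matches_univariate_cox(self):
        """With one single-gene pathway and no penalty, w*beta is the Cox MLE."""
        rng = np.random.default_rng(10)
        for trial in range(5):
            x = rng.standard_normal((50, 1))
            cfg = SimulationConfig(I=50, K=1, m_s=1, m_p=1.0, c_p=0.2)
            t, e, _ = generate_survival(x, np.array([0.7]), cfg, rng=rng)
            fit = als_fit(x, _single_gene_design(), t, e, 0.0, 0.0, standardize=False)
            oracle = _lifelines_coef(x, t, e)[0]
            assert fit.W[0][0] * fit.B[0] == pytest.approx(oracle, abs=1e-4)

    def test_singleton_pathways_zero_penalty_match_multivariate_cox_eta(self):
        """J single-gene pathways, lambda=0: eta-hat equals joint Cox fit."""
        rng = np.random.default_rng(11)
        x = rng.standard_normal((50, 3))
        cfg = SimulationConfig(I=50, K=3, m_s=3, m_p=1.0, c_p=0.2)
        t, e, _ = generate_survival(x, np.array([0.5, -0.4, 0.3]), cfg, rng=rng)
        d = HierarchyDesign(["P1", "P2", "P3"], [np.array([j]) for j in range(3)], 3)
        fit = als_fit(x, d, t, e, 0.0, 0.0, standardize=False, threshold=1e-7)
        eta_oracle = x @ _lifelines_coef(x, t, e)
        np.testing.assert_allclose(fit.eta, eta_oracle, atol=1e-3)

    def test_huge_penalty_shrinks_coefficients_to_zero(self, small_dataset):
        ds = small_dataset
        fit = als_fit(
            ds.X.values, ds.design(), ds.survival.time, ds.survival.event, 1e8, 1e8
        )
        assert np.all(np.abs(fit.B) < 1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_trace_monotone_and_converged(self, seed):
        rng = np.random.default_rng(seed)
        cfg = SimulationConfig(I=30, K=10, m_s=5, m_p=0.4, c_p=0.2)
        ds = simulate_dataset(cfg, rng=rng)
        fit = als_fit(ds.X.values, ds.design(), ds.survival.time, ds.survival.event, 2.0, 2.0)
        diffs = np.diff(fit.objective_trace)
        assert np.all(diffs >= -1e-8)
        assert fit.converged and abs(diffs[-1]) < 1e-4

    def test_reported_scale_unit_variance_sign_and_consistency(self, small_dataset):
        ds = small_dataset
        fit = als_fit(ds.X.values, ds.design(), ds.survival.time, ds.survival.event, 4.0, 4.0)
        # unit sample variance of each latent column
        np.testing.assert_allclose(fit.F.std(axis=0, ddof=1), 1.0, atol=1e-8)
        # F is exactly the latent score of the reported weights
        values = (ds.X.values - fit.gene_mean) / fit.gene_scale
        np.testing.assert_allclose(
            fit.F, compute_latent_scores(values, fit.design, fit.W), atol=1e-10
        )
        # sign convention
        assert all(w.sum() >= 0 for w in fit.W)

    def test_score_identity_holds_at_every_irls_step(self, small_dataset):
        ds = small_dataset
        fit = als_fit(ds.X.values, ds.design(), ds.survival.time, ds.survival.event, 2.0, 2.0)
        assert fit.score_sum_max < 1e-10

    def test_max_iter_exhaustion_returns_unconverged_fit(self, small_dataset):
        ds = small_dataset
        fit = als_fit(
            ds.X.values, ds.design(), ds.survival.time, ds.survival.event,
            0.5, 0.5, max_iter=1,
        )
        assert fit.converged is False and fit.n_iter == 1

    def test_requires_an_event(self):
        x = np.random.default_rng(0).normal(size=(5, 1))
        with pytest.raises(ValueError):
            als_fit(x, _single_gene_design(), [1, 2, 3, 4, 5], [0] * 5, 1.0, 1.0)

    def test_negative_penalty_rejected(self, small_dataset):
        ds = small_dataset
        with pytest.raises(ValueError):
            als_fit(ds.X.values, ds.design(), ds.survival.time, ds.survival.event, -1.0, 1.0)


class TestCvSelectLambdas:
    def test_singleton_grid_returns_that_pair(self, small_dataset):
        ds = small_dataset
        lg, lp, table = cv_select_lambdas(
            ds.X.values, ds.design(), ds.survival.time, ds.survival.event,
            lambda_grid_gene=[4.0], lambda_grid_pathway=[2.0], seed=0,
        )
        assert (lg, lp) == (4.0, 2.0) and len(table) == 1

    def test_duplicate_grid_entries_give_identical_scores(self, small_dataset):
        ds = small_dataset
        _, _, table = cv_select_lambdas(
            ds.X.values, ds.design(), ds.survival.time, ds.survival.event,
            lambda_grid_gene=[8.0, 8.0], lambda_grid_pathway=[8.0], seed=1,
        )
        assert table["cv_loglik"].iloc[0] == table["cv_loglik"].iloc[1]

    def test_deterministic_given_seed(self, small_dataset):
        ds = small_dataset
        args = (ds.X.values, ds.design(), ds.survival.time, ds.survival.event)
        kw = dict(lambda_grid_gene=[1.0, 16.0], lambda_grid_pathway=[4.0], seed=3)
        out1 = cv_select_lambdas(*args, **kw)
        out2 = cv_select_lambdas(*args, **kw)
        assert out1[:2] == out2[:2]
        pd.testing.assert_frame_equal(out1[2], out2[2])

    def test_too_few_events_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 2))
        d = HierarchyDesign(["P"], [np.array([0, 1])], 2)
        with pytest.raises(ValueError):
            cv_select_lambdas(x, d, np.arange(1.0, 13.0), [1] + [0] * 11, n_folds=5)
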