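"""Synthetic expression + censored survival generator and benchmark drivers.

One replicate draws an I x K expression matrix from N(0, Sigma) where Sigma
is block-diagonal: an l x l block A over the causal genes (l = round(m_p *
m_s), placed first inside pathway 1) and 0.2 * I over the remaining genes.
Four covariance scenarios for A are supported:

1. A = 0.2 * I_l                       (independent causal genes)
2. A = 0.2 * [x_ij], x_ii = 1, x_ij = 0.02 for i != j (constant correlation)
3. A = 0.2 * [0.1^|i-j|]               (autoregressive decay)
4. A = 0.2 * [x_ij], x_ii = 1, x_ij ~ N(0, 0.1^2) symmetrized, then
   projected to the nearest PSD matrix by eigenvalue clipping.

Survival times follow a Cox model with constant baseline hazard h0 = 0.005
(exponential given eta); effects on the l causal genes are U(0.2, 0.6) draws
(zero under the null). Censoring times are exponential with rate lambda
solved so the expected censoring fraction matches the target c_p; the
observed time is the minimum of the two.

The experiment drivers reproduce the type-I-error and power comparisons
across the hierarchical model and the competitor tests, with per-replicate
seed substreams and one shared permutation stream per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.stats.proportion import proportion_confint

from .competitors import global_test
from .core import als_fit, cv_select_lambdas
from .datatypes import (
    ExpressionMatrix,
    HierarchyDesign,
    Pathway,
    PathwayCollection,
    SurvivalPhenotype,
)
from .inference import permutation_tests

METHODS = ("hiscom", "gsea1", "gsea2", "globaltest", "wald")

# coarse grid for the per-setting CV used by the experiment drivers
EXPERIMENT_LAMBDA_GRID = (1.0, 4.0, 16.0, 64.0)


@dataclass
class SimulationConfig:
    """Parameters of one simulation replicate.

    I — sample size; K — total genes; m_s — pathway size (genes are split
    into consecutive pathways of this size, pathway 1 causal); m_p — causal
    gene proportion within pathway 1; c_p — target censoring proportion;
    scenario — covariance scenario 1-4; h0 — constant baseline hazard;
    effect_low/high — bounds of the uniform effect distribution; null —
    force all effects to zero (type-I runs); seed — replicate seed.
    """

    I: int = 80
    K: int = 200
    m_s: int = 50
    m_p: float = 0.1
    c_p: float = 0.0
    scenario: int = 1
    h0: float = 0.005
    effect_low: float = 0.2
    effect_high: float = 0.6
    null: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.I, self.K, self.m_s) < 1:
            raise ValueError("I, K and m_s must be positive")
        if not (0.0 <= self.m_p <= 1.0):
            raise ValueError("m_p must lie in [0, 1]")
        if not (0.0 <= self.c_p < 1.0):
            raise ValueError("c_p must lie in [0, 1)")
        if self.m_s > self.K:
            raise ValueError("pathway size m_s cannot exceed K")
        if self.scenario not in (1, 2, 3, 4):
            raise ValueError("scenario must be 1, 2, 3 or 4")

    @property
    def n_causal(self) -> int:
        return int(round(self.m_p * self.m_s))


@dataclass
class SimulatedDataset:
    X: ExpressionMatrix
    pathways: PathwayCollection
    survival: SurvivalPhenotype
    true_effects: np.ndarray
    censoring_rate: float
    config: SimulationConfig = field(repr=False)

    def design(self) -> HierarchyDesign:
        return HierarchyDesign.from_collection(self.pathways, self.X)


def build_covariance(scenario: int, K: int, l: int, seed=None) -> np.ndarray:
    """K x K covariance Sigma = blockdiag(A_l, 0.2 * I_{K-l}) per scenario."""
    if l > K:
        raise ValueError("l cannot exceed K")
    if scenario == 1:
        A = 0.2 * np.eye(l)
    elif scenario == 2:
        # off-diagonal entries 0.02 cannot apply to the diagonal (variances
        # would be 0.004, inconsistent with scenarios 3-4); diagonal is 1.
        A = 0.2 * (np.full((l, l), 0.02) + (1.0 - 0.02) * np.eye(l))
    elif scenario == 3:
        idx = np.arange(l)
        A = 0.2 * (0.1 ** np.abs(np.subtract.outer(idx, idx)))
    elif scenario == 4:
        rng = np.random.default_rng(seed)
        rho = rng.normal(0.0, 0.1, size=(l, l))
        rho = np.triu(rho, k=1)
        A = 0.2 * (rho + rho.T + np.eye(l))
        evals, evecs = np.linalg.eigh(A)
        A = (evecs * np.clip(evals, 1e-8, None)) @ evecs.T
        A = (A + A.T) / 2.0
    else:
        raise ValueError("scenario must be 1, 2, 3 or 4")
    sigma = 0.2 * np.eye(K)
    sigma[:l, :l] = A
    if l > 0 and np.linalg.eigvalsh(sigma).min() < -1e-10:
        raise ValueError("covariance is not positive semidefinite")
    return sigma


def generate_expression(config: SimulationConfig, rng=None) -> np.ndarray:
    """Draw I samples from N(0, Sigma) for the config's scenario."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    sigma = build_covariance(config.scenario, config.K, config.n_causal, seed=rng)
    evals, evecs = np.linalg.eigh(sigma)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    z = rng.standard_normal((config.I, config.K))
    return z @ root.T


def draw_effects(config: SimulationConfig, rng=None) -> np.ndarray:
    """Per-gene true log-hazard coefficients: U(low, high) on the first l genes."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    effects = np.zeros(config.K)
    l = config.n_causal
    if not config.null and l > 0:
        effects[:l] = rng.uniform(config.effect_low, config.effect_high, size=l)
    return effects


def solve_censoring_rate(target_cp: float, subject_rates) -> float:
    """Exponential censoring rate lambda matching an expected censoring fraction.

    With independent exponential event times (per-subject rates r_i) and
    censoring times (rate lambda), P(censored_i) = lambda / (lambda + r_i);
    lambda solves mean_i P(censored_i) = target_cp by monotone root finding.
    """
    rates = np.asarray(subject_rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("subject event rates must be positive")
    if not (0.0 <= target_cp < 1.0):
        raise ValueError("target censoring proportion must lie in [0, 1)")
    if target_cp == 0.0:
        return 0.0

    def frac(lam):
        return np.mean(lam / (lam + rates)) - target_cp

    hi = rates.max()
    while frac(hi) < 0:
        hi *= 2.0
    return float(optimize.brentq(frac, 0.0, hi, xtol=1e-14, rtol=1e-12))


def generate_survival(
    X: np.ndarray, effects: np.ndarray, config: SimulationConfig, rng=None
):
    """Observed (time, event) pairs under the Cox model with exponential censoring.

    Returns (time, event, censoring_rate). Survival and censoring times come
    from independent substreams of ``rng``.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    rng_t, rng_c = [np.random.default_rng(s) for s in rng.spawn(2)]
    eta = np.asarray(X, dtype=float) @ np.asarray(effects, dtype=float)
    rates = config.h0 * np.exp(eta)
    t_surv = rng_t.exponential(1.0 / rates)
    lam = solve_censoring_rate(config.c_p, rates)
    if lam > 0:
        t_cens = rng_c.exponential(1.0 / lam, size=rates.size)
    else:
        t_cens = np.full(rates.size, np.inf)
    time = np.minimum(t_surv, t_cens)
    event = (t_surv <= t_cens).astype(int)
    return time, event, lam


def _block_pathways(K: int, m_s: int) -> PathwayCollection:
    """Disjoint consecutive pathways of size m_s (last may be smaller)."""
    pathways = []
    j = 0
    for start in range(0, K, m_s):
        j += 1
        genes = [f"g{k+1:04d}" for k in range(start, min(start + m_s, K))]
        pathways.append(Pathway(f"P{j}", f"simulated block {j}", genes))
    return PathwayCollection(pathways)


def simulate_dataset(config: SimulationConfig, rng=None) -> SimulatedDataset:
    """One full replicate: expression, block pathways, survival, truth."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    rng_x, rng_w, rng_s = [np.random.default_rng(s) for s in rng.spawn(3)]
    values = generate_expression(config, rng=rng_x)
    effects = draw_effects(config, rng=rng_w)
    time, event, lam = generate_survival(values, effects, config, rng=rng_s)
    sample_ids = [f"s{i+1:04d}" for i in range(config.I)]
    gene_ids = [f"g{k+1:04d}" for k in range(config.K)]
    X = ExpressionMatrix(sample_ids, gene_ids, values)
    surv = SurvivalPhenotype(sample_ids, time, event)
    return SimulatedDataset(
        X=X,
        pathways=_block_pathways(config.K, config.m_s),
        survival=surv,
        true_effects=effects,
        censoring_rate=lam,
        config=config,
    )


# ---------------------------------------------------------------------------
# experiment drivers


def _method_pvalues(
    ds: SimulatedDataset,
    methods,
    n_perm: int,
    rng,
    lambda_gene: float,
    lambda_pathway: float,
    fit_max_iter: int,
) -> dict[str, float]:
    """p-value of the causal pathway (pathway 1) for each requested method.

    All methods share one permutation stream drawn from ``rng``.
    """
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; valid: {list(METHODS)}")
    time, event = ds.survival.time, ds.survival.event
    perms = np.array([rng.permutation(ds.config.I) for _ in range(n_perm)])
    causal = ds.pathways[0]
    m_causal = len(causal.genes)
    causal_cols = ds.X.values[:, :m_causal]
    out: dict[str, float] = {}

    # gsea1/gsea2/wald all derive from the same univariate Cox scans;
    # compute observed + permuted scans once and reuse
    scan_methods = [m for m in methods if m in ("gsea1", "gsea2", "wald")]
    if scan_methods:
        from .competitors import gsea_enrichment_score, univariate_cox_scan

        rank_obs = univariate_cox_scan(ds.X, time, event)
        obs_stat = {}
        if "gsea1" in scan_methods:
            obs_stat["gsea1"] = abs(gsea_enrichment_score(rank_obs, causal.genes, 0))
        if "gsea2" in scan_methods:
            obs_stat["gsea2"] = abs(gsea_enrichment_score(rank_obs, causal.genes, 1))
        if "wald" in scan_methods:
            obs_stat["wald"] = float(np.sum(rank_obs.statistic[:m_causal] ** 2))
        exceed = {m: 0 for m in scan_methods}
        for perm in perms:
            rk = univariate_cox_scan(ds.X, time[perm], event[perm])
            if "gsea1" in scan_methods:
                exceed["gsea1"] += (
                    abs(gsea_enrichment_score(rk, causal.genes, 0)) >= obs_stat["gsea1"]
                )
            if "gsea2" in scan_methods:
                exceed["gsea2"] += (
                    abs(gsea_enrichment_score(rk, causal.genes, 1)) >= obs_stat["gsea2"]
                )
            if "wald" in scan_methods:
                exceed["wald"] += (
                    float(np.sum(rk.statistic[:m_causal] ** 2)) >= obs_stat["wald"]
                )
        for m in scan_methods:
            out[m] = (exceed[m] + 1.0) / (n_perm + 1.0)

    for method in methods:
        if method == "hiscom":
            design = ds.design()
            fit = als_fit(
                ds.X.values,
                design,
                time,
                event,
                lambda_gene=lambda_gene,
                lambda_pathway=lambda_pathway,
                max_iter=fit_max_iter,
            )
            ptab, _ = permutation_tests(
                ds.X.values,
                design,
                time,
                event,
                fit,
                n_perm=n_perm,
                permutations=perms,
                max_iter=fit_max_iter,
            )
            out[method] = float(ptab.loc[ptab["pathway"] == causal.name, "p"].iloc[0])
        elif method == "globaltest":
            res = global_test(causal_cols, time, event, n_perm=n_perm, permutations=perms)
            out[method] = res.p_value
    return {m: out[m] for m in methods}


def _rejection_table(records, alpha) -> pd.DataFrame:
    frame = pd.DataFrame(records)
    rows = []
    group_cols = [c for c in ("scenario", "m_p", "c_p", "method") if c in frame.columns]
    for key, grp in frame.groupby(group_cols, sort=False):
        # reject when p <= alpha: with add-one p-values this attains level
        # alpha exactly whenever (n_perm + 1) * alpha is an integer
        k = int((grp["p"] <= alpha).sum())
        n = len(grp)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row.update(
            {"n_replicates": n, "rejections": k, "rate": k / n, "ci_low": lo, "ci_high": hi}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _replicate_rngs(seed: int, c_p: float, r: int):
    """Deterministic (data, permutation) substreams keyed by (setting, replicate)."""
    ss = np.random.SeedSequence(seed, spawn_key=(int(round(c_p * 1000)), r))
    return [np.random.default_rng(s) for s in ss.spawn(2)]


def _setting_lambdas(
    base, c_p, m_p, null, seed, lambda_gene, lambda_pathway, fit_max_iter
):
    """Penalties for one experiment setting.

    Explicit values are passed through; otherwise both are selected by
    5-fold CV on the setting's first replicate (coarse grid) and held fixed
    for every replicate and permutation refit of that setting.
    """
    if lambda_gene is not None and lambda_pathway is not None:
        return float(lambda_gene), float(lambda_pathway)
    rng_data, _ = _replicate_rngs(seed, c_p, 0)
    config = replace(base, c_p=c_p, m_p=m_p, null=null, seed=None)
    ds = simulate_dataset(config, rng=rng_data)
    lg, lp, _ = cv_select_lambdas(
        ds.X.values,
        ds.design(),
        ds.survival.time,
        ds.survival.event,
        lambda_grid_gene=EXPERIMENT_LAMBDA_GRID,
        lambda_grid_pathway=EXPERIMENT_LAMBDA_GRID,
        seed=0,
        max_iter=fit_max_iter,
    )
    return lg, lp


def run_type1_experiment(
    methods=METHODS,
    c_p_values=(0.0, 0.3),
    n_replicates: int = 200,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
    lambda_gene: float | None = None,
    lambda_pathway: float | None = None,
    fit_max_iter: int = 500,
) -> pd.DataFrame:
    """Empirical type-I error per method and censoring proportion.

    Data are simulated under the global null (all effects zero); for each
    replicate every method tests the causal-position pathway and the
    rejection fraction at ``alpha`` is tabulated with an exact binomial 95%
    confidence interval. Penalties default to per-setting CV (see
    :func:`_setting_lambdas`). Deterministic given ``seed``.
    """
    if alpha <= 0 or alpha > 1:
        raise ValueError("alpha must lie in (0, 1]")
    base = base_config or SimulationConfig()
    records = []
    for c_p in c_p_values:
        lg = lp = None
        if "hiscom" in methods:
            lg, lp = _setting_lambdas(
                base, c_p, base.m_p, True, seed, lambda_gene, lambda_pathway,
                fit_max_iter,
            )
        for r in range(n_replicates):
            rng_data, rng_perm = _replicate_rngs(seed, c_p, r)
            config = replace(base, c_p=c_p, null=True, seed=None)
            ds = simulate_dataset(config, rng=rng_data)
            pvals = _method_pvalues(ds, methods, n_perm, rng_perm, lg, lp, fit_max_iter)
            for method, p in pvals.items():
                records.append(
                    {"scenario": config.scenario, "c_p": c_p, "replicate": r,
                     "method": method, "p": p}
                )
    return _rejection_table(records, alpha)


def run_power_experiment(
    methods=METHODS,
    m_p_values=(0.1, 0.3, 0.5),
    c_p_values=(0.0,),
    n_replicates: int = 100,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
    lambda_gene: float | None = None,
    lambda_pathway: float | None = None,
    fit_max_iter: int = 500,
) -> pd.DataFrame:
    """Empirical power per method across causal-gene proportions m_p.

    Effects are drawn per replicate from the uniform effect distribution.
    Replicate r shares its random substream across m_p values (common random
    numbers), which pairs the power curves in m_p; penalties are selected
    once per censoring setting (first replicate, first m_p) so the analysis
    is identical across the m_p grid.
    """
    base = base_config or SimulationConfig()
    records = []
    for c_p in c_p_values:
        lg = lp = None
        if "hiscom" in methods:
            lg, lp = _setting_lambdas(
                base, c_p, m_p_values[0], False, seed, lambda_gene, lambda_pathway,
                fit_max_iter,
            )
        for m_p in m_p_values:
            for r in range(n_replicates):
                rng_data, rng_perm = _replicate_rngs(seed, c_p, r)
                config = replace(base, c_p=c_p, m_p=m_p, null=False, seed=None)
                ds = simulate_dataset(config, rng=rng_data)
                pvals = _method_pvalues(ds, methods, n_perm, rng_perm, lg, lp, fit_max_iter)
                for method, p in pvals.items():
                    records.append(
                        {"scenario": config.scenario, "m_p": m_p, "c_p": c_p,
                         "replicate": r, "method": method, "p": p}
                    )
    return _rejection_table(records, alpha)
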