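"""Competitor pathway association tests for survival phenotypes.

Implements the three single-pathway reference methods used for head-to-head
comparison with the hierarchical component model:

* GSEA for survival (weight exponent 0 = rank-only "GSEA1", exponent 1 =
  statistic-weighted "GSEA2"): genes are ranked by the absolute univariate
  Cox Wald statistic and a running-sum Kolmogorov–Smirnov enrichment score
  is computed for each gene set;
* the Global Test: per-gene quadratic score statistics against the null
  survival model, averaged over the set, with a permutation null built by
  permuting the null-model martingale residuals;
* the Wald-type test: sum of squared per-gene univariate Cox Wald
  statistics.

All permutation p-values use the add-one rule (count + 1)/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import CoxTimes
from .datatypes import ExpressionMatrix, PathwayCollection


def _values(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    v = np.asarray(X, dtype=float)
    return v[:, None] if v.ndim == 1 else v


@dataclass
class GeneRanking:
    """Per-gene univariate Cox Wald statistics with the induced ranking.

    ``statistic`` and ``converged`` are in original gene order; ``order``
    sorts by descending |statistic| with ties broken by original order.
    """

    gene_ids: list[str]
    statistic: np.ndarray
    coef: np.ndarray
    se: np.ndarray
    converged: np.ndarray
    order: np.ndarray

    @property
    def ranked_ids(self) -> list[str]:
        return [self.gene_ids[j] for j in self.order]

    @property
    def ranked_statistics(self) -> np.ndarray:
        return self.statistic[self.order]


@dataclass
class PathwayTestResult:
    """Outcome of one single-pathway test."""

    method: str
    statistic: float
    p_value: float
    n_perm: int
    n_flagged: int = 0


def _scan_arrays(values: np.ndarray, ct: CoxTimes, max_iter: int = 40, tol: float = 1e-9):
    """Newton fits of K univariate Cox models, vectorized across genes.

    Returns (coef, se, wald, converged). Genes with no information (constant
    columns) or whose Newton iteration does not converge are flagged and get
    statistic 0.
    """
    I, K = values.shape
    if ct.n_events == 0:
        raise ValueError("at least one event is required")
    xs = values[ct.order]
    ev_x_sum = values[ct._event_mask].sum(axis=0)
    d_mult = ct.d_mult[:, None]
    start = ct._risk_start

    def suff_stats(beta):
        eta = values * beta  # (I, K), per-gene linear predictor
        shift = eta.max(axis=0)
        w = np.exp(eta[ct.order] - shift)
        wx = w * xs
        wxx = wx * xs
        s0 = np.cumsum(w[::-1], axis=0)[::-1][start]
        s1 = np.cumsum(wx[::-1], axis=0)[::-1][start]
        s2 = np.cumsum(wxx[::-1], axis=0)[::-1][start]
        score = ev_x_sum - (d_mult * s1 / s0).sum(axis=0)
        info = (d_mult * (s2 / s0 - (s1 / s0) ** 2)).sum(axis=0)
        return score, info

    beta = np.zeros(K)
    _, info0 = suff_stats(beta)
    informative = info0 > 1e-12
    active = informative.copy()
    newton_done = np.zeros(K, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        score, info = suff_stats(beta)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(info > 1e-12, score / np.maximum(info, 1e-12), 0.0)
        delta = np.clip(delta, -2.0, 2.0)
        beta = np.where(active, beta + delta, beta)
        done = active & (np.abs(delta) < tol)
        newton_done |= done
        active &= ~done
    _, info_hat = suff_stats(beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(info_hat > 1e-12, 1.0 / np.sqrt(np.maximum(info_hat, 1e-12)), np.inf)
    ok = informative & newton_done
    wald = np.where(ok, beta / se, 0.0)
    coef = np.where(ok, beta, 0.0)
    return coef, se, wald, ok


def univariate_cox_scan(X, time, event) -> GeneRanking:
    """Univariate Cox Wald statistic per gene, ranked by |statistic| descending.

    Each gene is fit in its own univariate Cox model (Breslow ties, Newton
    iterations); the Wald statistic is coef/SE with the SE from the observed
    information. Non-converged or constant genes are flagged with statistic 0.
    """
    values = _values(X)
    gene_ids = (
        list(X.gene_ids)
        if isinstance(X, ExpressionMatrix)
        else [f"g{j+1}" for j in range(values.shape[1])]
    )
    ct = CoxTimes(np.asarray(time, float), np.asarray(event, int))
    coef, se, wald, ok = _scan_arrays(values, ct)
    # stable sort on -|stat| keeps original order among ties
    order = np.argsort(-np.abs(wald), kind="stable")
    return GeneRanking(
        gene_ids=gene_ids, statistic=wald, coef=coef, se=se, converged=ok, order=order
    )


def gsea_enrichment_score(ranking: GeneRanking, gene_set, weight_exponent: int) -> float:
    """Running-sum enrichment score of a gene set against a ranking.

    Walking the ranked list, hits increment the running sum by
    |stat|^p / sum_hits |stat|^p and misses decrement by 1/(K - m); the score
    is the signed maximum deviation. ``weight_exponent`` p = 0 gives the
    classic rank-only Kolmogorov–Smirnov form; p = 1 weights by statistic.
    """
    if weight_exponent not in (0, 1):
        raise ValueError("weight_exponent must be 0 or 1")
    members = set(gene_set)
    ranked_ids = ranking.ranked_ids
    hit = np.array([g in members for g in ranked_ids])
    m = int(hit.sum())
    K = len(ranked_ids)
    if m == 0:
        raise ValueError("gene set shares no genes with the ranking")
    if m == K:
        raise ValueError("gene set covers every ranked gene; score undefined")
    weights = np.abs(ranking.ranked_statistics) ** weight_exponent
    hit_w = np.where(hit, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit statistics zero: fall back to equal hit weights
        hit_w = hit.astype(float)
        total = float(m)
    steps = np.where(hit, hit_w / total, -1.0 / (K - m))
    run = np.cumsum(steps)
    return float(run[np.argmax(np.abs(run))])


def _permutation_rows(n, n_perm, seed, permutations):
    if permutations is not None:
        return np.asarray(permutations)[:n_perm]
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def gsea_test(
    X,
    time,
    event,
    pathways: PathwayCollection,
    weight_exponent: int,
    n_perm: int = 1000,
    seed: int = 0,
    permutations=None,
) -> pd.DataFrame:
    """Permutation GSEA for survival over all pathways in a collection.

    Each permutation shuffles the (time, event) pairs, recomputes the full
    Cox ranking and every pathway's enrichment score; significance is
    two-sided on |ES|.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ranking = univariate_cox_scan(X, time, event)
    obs = np.array(
        [gsea_enrichment_score(ranking, p.genes, weight_exponent) for p in pathways]
    )
    perms = _permutation_rows(time.size, n_perm, seed, permutations)
    exceed = np.zeros(len(obs))
    for perm in perms:
        rk = univariate_cox_scan(X, time[perm], event[perm])
        es = np.array(
            [gsea_enrichment_score(rk, p.genes, weight_exponent) for p in pathways]
        )
        exceed += np.abs(es) >= np.abs(obs)
    p = (exceed + 1.0) / (len(perms) + 1.0)
    method = f"GSEA{1 if weight_exponent == 0 else 2}"
    return pd.DataFrame(
        {"method": method, "pathway": pathways.names, "statistic": obs, "p": p}
    )


def global_test(
    X_set, time, event, n_perm: int = 1000, seed: int = 0, permutations=None
) -> PathwayTestResult:
    """Global Test for one pathway's expression submatrix.

    Martingale residuals r_i from the covariate-free null Cox model (eta = 0)
    are scored against each gene, Q_k = (x_k' r)^2 / Var_perm(x_k' r), and
    averaged: Q = mean_k Q_k. The null distribution permutes the residual-to-
    sample assignment (residuals are exchangeable under the null), with the
    variance estimated from the permutation stream. Zero-variance genes
    contribute 0 and are flagged.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = _values(X_set)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ct = CoxTimes(time, event)
    if ct.n_events == 0:
        raise ValueError("at least one event is required")
    # Breslow cumulative hazard at eta = 0: Lambda(t) = sum_{t_d <= t} d_d / |R_d|
    risk_size = ct.n - ct._risk_start
    cum = np.concatenate(([0.0], np.cumsum(ct.d_mult / risk_size)))
    r = event - cum[ct._n_le]  # martingale residuals; sum to 0

    perms = _permutation_rows(time.size, n_perm, seed, permutations)
    s_obs = values.T @ r  # (m,)
    s_perm = values.T @ r[perms.T]  # (m, B)
    # variance pooled over permuted AND observed scores: the statistic is
    # then a symmetric function of the pooled set, keeping the permutation
    # test exactly exchangeable under the null
    pooled = np.concatenate([s_obs[:, None], s_perm], axis=1)
    var = pooled.var(axis=1, ddof=1)
    usable = var > 1e-12
    n_flagged = int((~usable).sum())
    if not usable.any():
        return PathwayTestResult("GlobalTest", 0.0, 1.0, len(perms), n_flagged)
    q_obs = float(np.mean(np.where(usable, s_obs**2 / np.where(usable, var, 1.0), 0.0)))
    q_perm = np.mean(
        np.where(usable[:, None], s_perm**2 / np.where(usable, var, 1.0)[:, None], 0.0),
        axis=0,
    )
    p = (np.sum(q_perm >= q_obs) + 1.0) / (len(perms) + 1.0)
    return PathwayTestResult("GlobalTest", q_obs, float(p), len(perms), n_flagged)


def wald_type_test(
    X_set, time, event, n_perm: int = 1000, seed: int = 0, permutations=None
) -> PathwayTestResult:
    """Wald-type pathway test: sum of squared univariate Cox Wald statistics.

    Significance by joint permutation of the (time, event) pairs, add-one
    rule. Non-converged genes contribute 0 and are flagged; all genes failing
    is an error.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = _values(X_set)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ranking = univariate_cox_scan(values, time, event)
    if not ranking.converged.any():
        raise ValueError("no gene in the set yielded a usable Wald statistic")
    n_flagged = int((~ranking.converged).sum())
    stat = float(np.sum(ranking.statistic**2))
    perms = _permutation_rows(time.size, n_perm, seed, permutations)
    exceed = 0
    for perm in perms:
        rk = univariate_cox_scan(values, time[perm], event[perm])
        exceed += float(np.sum(rk.statistic**2)) >= stat
    p = (exceed + 1.0) / (len(perms) + 1.0)
    return PathwayTestResult("WaldType", stat, float(p), len(perms), n_flagged)
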