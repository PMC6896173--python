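"""Permutation significance for pathway and gene effects, with FDR control.

Ridge estimation does not yield usable asymptotic standard errors, so
significance comes from a permutation null: (time, event) pairs are permuted
jointly across samples (keeping the censoring pattern and the expression
correlation structure intact), the model is refit with the penalties held
fixed, and the observed |beta_j| (pathways) or |w_jk * beta_j| (genes within
pathways) is compared against the permuted statistics with the add-one rule
p = (#exceedances + 1) / (n_perm + 1). Benjamini–Hochberg q-values adjust
for multiplicity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import HiscomFit, als_fit
from .datatypes import HierarchyDesign


def permute_survival(time, event, rng):
    """Jointly permute (time, event) pairs across samples.

    ``rng`` is a numpy Generator or an integer seed. The multiset of pairs is
    preserved: a sample's time never recombines with another sample's event
    flag.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    time = np.asarray(time)
    event = np.asarray(event)
    perm = rng.permutation(time.size)
    return time[perm], event[perm]


def fdr_bh(p_values, method: str = "bh") -> np.ndarray:
    """Benjamini–Hochberg (or Benjamini–Yekutieli) adjusted q-values.

    All p-values must lie in (0, 1]. q-values are clipped to <= 1 and are
    monotone nondecreasing in p-rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    key = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if key is None:
        raise ValueError(f"unknown FDR method {method!r}")
    return multipletests(p, method=key)[1]


def _refit_statistics(X, design, time, event, fit: HiscomFit, **fit_kwargs):
    refit = als_fit(
        X,
        design,
        time,
        event,
        lambda_gene=fit.lambda_gene,
        lambda_pathway=fit.lambda_pathway,
        standardize=fit.standardize,
        **fit_kwargs,
    )
    beta_abs = np.abs(refit.B)
    wb_abs = np.concatenate(
        [np.abs(w * b) for w, b in zip(refit.W, refit.B)]
    )
    return beta_abs, wb_abs, refit.converged


def permutation_tests(
    X,
    design: HierarchyDesign,
    time,
    event,
    fit: HiscomFit,
    n_perm: int = 1000,
    seed: int = 0,
    permutations=None,
    fdr_method: str = "bh",
    max_failure_fraction: float = 0.1,
    **fit_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Joint pathway- and gene-level permutation test (one refit serves both).

    For every permutation the survival pairs are shuffled and the model refit
    with the original fit's penalties. Returns (pathway_table, gene_table)
    with columns statistic / null_count / n_perm_effective / p / q. Permuted
    refits that fail to converge are excluded; more than
    ``max_failure_fraction`` failures is an error.

    ``permutations`` may supply precomputed permutation index rows (B, I) to
    share one permutation stream between several procedures.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    rng = np.random.default_rng(seed)
    if permutations is None:
        permutations = np.array([rng.permutation(time.size) for _ in range(n_perm)])
    else:
        permutations = np.asarray(permutations)[:n_perm]

    obs_beta = np.abs(fit.B)
    obs_wb = np.concatenate([np.abs(w * b) for w, b in zip(fit.W, fit.B)])

    null_beta = np.zeros_like(obs_beta)
    null_wb = np.zeros_like(obs_wb)
    n_ok = 0
    n_failed = 0
    for perm in permutations:
        beta_b, wb_b, ok = _refit_statistics(
            X, design, time[perm], event[perm], fit, **fit_kwargs
        )
        if not ok:
            n_failed += 1
            continue
        null_beta += beta_b >= obs_beta
        null_wb += wb_b >= obs_wb
        n_ok += 1
    if n_failed > max_failure_fraction * len(permutations):
        raise RuntimeError(
            f"{n_failed}/{len(permutations)} permuted refits failed to converge"
        )
    if n_ok == 0:
        raise RuntimeError("no successful permuted refits")

    p_path = (null_beta + 1.0) / (n_ok + 1.0)
    pathway_table = pd.DataFrame(
        {
            "pathway": fit.pathway_names,
            "statistic": obs_beta,
            "null_count": null_beta.astype(int),
            "n_perm_effective": n_ok,
            "p": p_path,
            "q": fdr_bh(p_path, method=fdr_method),
        }
    )
    gene_table = fit.gene_table()[["pathway", "gene"]].copy()
    p_gene = (null_wb + 1.0) / (n_ok + 1.0)
    gene_table["statistic"] = obs_wb
    gene_table["null_count"] = null_wb.astype(int)
    gene_table["n_perm_effective"] = n_ok
    gene_table["p"] = p_gene
    gene_table["q"] = fdr_bh(p_gene, method=fdr_method)
    return pathway_table, gene_table


def pathway_permutation_test(
    X, design, time, event, fit, n_perm: int = 1000, seed: int = 0, **kwargs
) -> pd.DataFrame:
    """Permutation p/q-values for the pathway coefficients |beta_j|."""
    pathway_table, _ = permutation_tests(
        X, design, time, event, fit, n_perm=n_perm, seed=seed, **kwargs
    )
    return pathway_table


def gene_effect_test(
    X, design, time, event, fit, n_perm: int = 1000, seed: int = 0, **kwargs
) -> pd.DataFrame:
    """Permutation p/q-values for the per-membership gene effects |w_jk * beta_j|.

    A gene in several pathways yields one row per membership.
    """
    _, gene_table = permutation_tests(
        X, design, time, event, fit, n_perm=n_perm, seed=seed, **kwargs
    )
    return gene_table
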