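"""The hierarchical structured-component Cox model and its ALS estimator.

The model summarizes each pathway j as a latent score
``f_ij = sum_k x_ijk w_jk`` (a weighted sum of its member genes) and links
the scores to the hazard through a Cox proportional-hazards model,

    h(y_i | f_i) = h0(y_i) * exp( sum_j f_ij * beta_j ).

Estimation maximizes the ridge-penalized Breslow partial log-likelihood

    phi = loglik(eta) - 1/2 lambda_gene ||W||^2 - 1/2 lambda_pathway ||B||^2

by alternating least squares: each outer iteration takes one penalized
weighted-least-squares (IRLS) step in the pathway coefficients B with the
weights W fixed, then one in W with B fixed, both on the working response
z = eta + A^+ u. Every step is safeguarded by step-halving against the
exact penalized objective, so the objective trace is nondecreasing by
construction; the outer loop stops when the objective changes by less than
the convergence threshold (1e-4 by default).

Because eta depends on W and B only through the products f_j * beta_j, the
pair (W_j, beta_j) is identified only up to scale. On exit each latent score
is normalized to unit sample variance with the scale absorbed into beta_j
and the sign fixed so that sum_k w_jk >= 0; this leaves eta (and the
maximized objective) unchanged and makes the reported coefficients unique.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cox import CoxTimes
from .datatypes import ExpressionMatrix, HierarchyDesign

_HALVING_TOL = 1e-9
_MAX_HALVINGS = 30


def compute_latent_scores(X, design: HierarchyDesign, W: list[np.ndarray]) -> np.ndarray:
    """Latent score matrix F with F[i, j] = sum_{k in pathway j} x_ik * w_jk.

    ``X`` may be an :class:`ExpressionMatrix` or a plain (I, K) array. No
    scaling is applied. A gene in several pathways contributes independently
    to each of its pathways' columns.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if values.shape[1] != design.n_genes:
        raise ValueError(
            f"matrix has {values.shape[1]} genes but design expects {design.n_genes}"
        )
    if len(W) != design.n_pathways:
        raise ValueError("one weight vector per pathway required")
    F = np.empty((values.shape[0], design.n_pathways))
    for j, (cols, w) in enumerate(zip(design.pathway_index, W)):
        w = np.asarray(w, dtype=float)
        if w.shape != (len(cols),):
            raise ValueError(f"weight vector {j} has wrong length")
        F[:, j] = values[:, cols] @ w
    return F


def penalized_objective(time, event, F, B, W, lambda_gene, lambda_pathway) -> float:
    """phi = Breslow partial loglik(F B) - ridge penalties on W and B."""
    if lambda_gene < 0 or lambda_pathway < 0:
        raise ValueError("penalty parameters must be nonnegative")
    ct = CoxTimes(time, event)
    B = np.asarray(B, dtype=float)
    ll = ct.loglik(np.asarray(F, dtype=float) @ B)
    pen_w = sum(float(np.sum(np.square(w))) for w in W)
    return ll - 0.5 * lambda_gene * pen_w - 0.5 * lambda_pathway * float(np.sum(B * B))


@dataclass
class HiscomFit:
    """Result of one alternating-least-squares fit.

    W holds one weight vector per pathway and B the pathway log-hazard
    coefficients, reported on the unit-variance latent scale (sign fixed so
    each weight vector sums to >= 0); F are the corresponding latent scores
    X_j W_j. ``objective_trace`` records the penalized objective once per
    outer iteration and ``score_sum_max`` the largest |sum_i u_i| seen over
    all IRLS steps (a score-identity diagnostic).
    """

    pathway_names: list[str]
    W: list[np.ndarray]
    B: np.ndarray
    F: np.ndarray
    lambda_gene: float
    lambda_pathway: float
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    standardize: bool
    gene_mean: np.ndarray
    gene_scale: np.ndarray
    design: HierarchyDesign = field(repr=False)
    score_sum_max: float = 0.0

    @property
    def eta(self) -> np.ndarray:
        return self.F @ self.B

    def predict_eta(self, values: np.ndarray) -> np.ndarray:
        """Linear predictor for new samples (applies the fit's gene scaling)."""
        values = np.asarray(values, dtype=float)
        Xs = (values - self.gene_mean) / self.gene_scale
        return compute_latent_scores(Xs, self.design, self.W) @ self.B

    def pathway_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway": self.pathway_names,
                "beta": self.B,
                "abs_beta": np.abs(self.B),
            }
        )

    def gene_table(self, gene_ids: list[str] | None = None) -> pd.DataFrame:
        rows = []
        for name, cols, w, b in zip(
            self.pathway_names, self.design.pathway_index, self.W, self.B
        ):
            for col, wk in zip(cols, w):
                gene = gene_ids[col] if gene_ids is not None else f"col{col}"
                rows.append((name, gene, wk, wk * b, abs(wk * b)))
        return pd.DataFrame(
            rows, columns=["pathway", "gene", "w", "w_beta", "abs_w_beta"]
        )

    def meta_json(self) -> str:
        return json.dumps(
            {
                "lambda_gene": self.lambda_gene,
                "lambda_pathway": self.lambda_pathway,
                "n_iter": self.n_iter,
                "converged": self.converged,
                "standardize": self.standardize,
                "objective_trace": [float(v) for v in self.objective_trace],
            },
            indent=2,
        )


def _standardize(values: np.ndarray, enabled: bool):
    if not enabled:
        K = values.shape[1]
        return values, np.zeros(K), np.ones(K)
    mean = values.mean(axis=0)
    scale = values.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    return (values - mean) / scale, mean, scale


def als_fit(
    X,
    design: HierarchyDesign,
    time,
    event,
    lambda_gene: float,
    lambda_pathway: float,
    threshold: float = 1e-4,
    max_iter: int = 500,
    init: str = "uniform",
    seed: int | None = None,
    standardize: bool = True,
) -> HiscomFit:
    """Fit the hierarchical pathway Cox model by alternating least squares.

    Each outer iteration takes one ridge-penalized IRLS step in B (penalty
    ``lambda_pathway``) and one in the flattened weight vector W (penalty
    ``lambda_gene``), both step-halved against the exact penalized
    objective. The loop stops when the objective change drops below
    ``threshold``; if ``max_iter`` is reached first the fit is returned with
    ``converged=False`` (not an exception).

    ``init`` is "uniform" (equal weights per pathway, scaled so each latent
    score starts at unit variance) or "random" (N(0,1) draws via ``seed``).
    Gene columns are standardized to mean 0, variance 1 by default
    (``standardize=False`` to disable).
    """
    if lambda_gene < 0 or lambda_pathway < 0:
        raise ValueError("penalty parameters must be nonnegative")
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    names = (
        list(design.pathway_names)
        if design.pathway_names
        else [f"P{j+1}" for j in range(design.n_pathways)]
    )
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ct = CoxTimes(time, event)
    if ct.n_events == 0:
        raise ValueError("at least one event is required to fit the model")

    values, gmean, gscale = _standardize(values, standardize)
    I = values.shape[0]
    J = design.n_pathways
    M = design.total_weight_count
    sizes = design.sizes
    # flattened layout: member columns gathered once; block j owns
    # weights [offsets[j], offsets[j+1])
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    flat_cols = np.concatenate(design.pathway_index)
    Xw = values[:, flat_cols]  # (I, M), duplicated columns for overlaps
    block_of = np.repeat(np.arange(J), sizes)

    def latent(Wf):
        F = np.empty((I, J))
        for j in range(J):
            F[:, j] = Xw[:, offsets[j] : offsets[j + 1]] @ Wf[offsets[j] : offsets[j + 1]]
        return F

    if init == "uniform":
        Wf = np.ones(M)
    elif init == "random":
        Wf = np.random.default_rng(seed).standard_normal(M)
    else:
        raise ValueError(f"unknown init {init!r}")
    # scale initial blocks so each latent score starts at unit variance
    F = latent(Wf)
    for j in range(J):
        sd = F[:, j].std(ddof=1)
        if sd > 0:
            Wf[offsets[j] : offsets[j + 1]] /= sd
    F = latent(Wf)
    B = np.zeros(J)

    def objective(F, B, Wf):
        return (
            ct.loglik(F @ B)
            - 0.5 * lambda_gene * float(Wf @ Wf)
            - 0.5 * lambda_pathway * float(B @ B)
        )

    phi = objective(F, B, Wf)
    trace = [phi]
    score_sum_max = 0.0

    def working(eta):
        nonlocal score_sum_max
        u, A = ct.score_info(eta)
        score_sum_max = max(score_sum_max, abs(float(u.sum())))
        return u, A

    def ridge_solve(M_mat, rhs):
        # non-finite systems arise only from overflowed eta; returning None
        # skips the update (the safeguarded step keeps the previous iterate)
        if not (np.isfinite(M_mat).all() and np.isfinite(rhs).all()):
            return None
        try:
            return np.linalg.solve(M_mat, rhs)
        except np.linalg.LinAlgError:
            return np.linalg.lstsq(M_mat, rhs, rcond=None)[0]

    converged = False
    n_outer = 0
    for n_outer in range(1, max_iter + 1):
        # one IRLS step in B with W fixed
        eta = F @ B
        u, A = working(eta)
        Mb = F.T @ A @ F + lambda_pathway * np.eye(J)
        B_prop = ridge_solve(Mb, F.T @ (A @ eta) + F.T @ u)
        if B_prop is not None and np.isfinite(B_prop).all():
            step = 1.0
            for _ in range(_MAX_HALVINGS):
                cand = B + step * (B_prop - B)
                phi_c = objective(F, cand, Wf)
                if np.isfinite(phi_c) and phi_c >= phi - _HALVING_TOL:
                    B, phi = cand, phi_c
                    break
                step *= 0.5
        # one IRLS step in W with B fixed; design column for weight (j, k)
        # is x_{.k} * beta_j
        eta = F @ B
        u, A = working(eta)
        G = Xw * B[block_of]
        Mw = G.T @ A @ G + lambda_gene * np.eye(M)
        W_prop = ridge_solve(Mw, G.T @ (A @ eta) + G.T @ u)
        if W_prop is not None and np.isfinite(W_prop).all():
            step = 1.0
            for _ in range(_MAX_HALVINGS):
                cand = Wf + step * (W_prop - Wf)
                F_c = latent(cand)
                phi_c = objective(F_c, B, cand)
                if np.isfinite(phi_c) and phi_c >= phi - _HALVING_TOL:
                    Wf, F, phi = cand, F_c, phi_c
                    break
                step *= 0.5
        if not np.isfinite(phi):
            raise FloatingPointError("objective became non-finite during ALS")
        trace.append(phi)
        if abs(trace[-1] - trace[-2]) < threshold:
            converged = True
            break

    # identifiability normalization (leaves eta unchanged): unit sample
    # variance per latent score, scale absorbed into beta, sign fixed so
    # each weight vector sums to >= 0
    W_out, B_out = [], B.copy()
    F_out = F.copy()
    for j in range(J):
        w = Wf[offsets[j] : offsets[j + 1]].copy()
        sd = F[:, j].std(ddof=1)
        if sd > 0:
            w /= sd
            B_out[j] *= sd
            F_out[:, j] = F[:, j] / sd
        else:
            B_out[j] = 0.0
        if w.sum() < 0:
            w = -w
            B_out[j] = -B_out[j]
            F_out[:, j] = -F_out[:, j]
        W_out.append(w)

    return HiscomFit(
        pathway_names=names,
        W=W_out,
        B=B_out,
        F=F_out,
        lambda_gene=float(lambda_gene),
        lambda_pathway=float(lambda_pathway),
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_outer,
        standardize=standardize,
        gene_mean=gmean,
        gene_scale=gscale,
        design=design,
        score_sum_max=score_sum_max,
    )


DEFAULT_LAMBDA_GRID = tuple(float(2.0**p) for p in range(-4, 9))


def cv_select_lambdas(
    X,
    design: HierarchyDesign,
    time,
    event,
    lambda_grid_gene=DEFAULT_LAMBDA_GRID,
    lambda_grid_pathway=DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    seed: int = 0,
    **fit_kwargs,
):
    """Select (lambda_gene, lambda_pathway) by k-fold cross-validated partial likelihood.

    Folds are stratified by event status. The fold score is the
    Verweij–van Houwelingen cross-validated partial likelihood: the full-data
    log-likelihood at the fold-trained parameters minus the training-fold
    log-likelihood. Returns the arg-max pair and the full grid table.
    """
    lambda_grid_gene = list(lambda_grid_gene)
    lambda_grid_pathway = list(lambda_grid_pathway)
    if not lambda_grid_gene or not lambda_grid_pathway:
        raise ValueError("lambda grids must be nonempty")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < n_folds:
        raise ValueError("need at least one event per fold")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(values, event))
    for train_ix, _ in folds:
        if event[train_ix].sum() == 0:
            raise ValueError("a training fold contains no events")
    ct_full = CoxTimes(time, event)
    rows = []
    for lg in lambda_grid_gene:
        for lp in lambda_grid_pathway:
            score = 0.0
            for train_ix, _ in folds:
                fit = als_fit(
                    values[train_ix],
                    design,
                    time[train_ix],
                    event[train_ix],
                    lambda_gene=lg,
                    lambda_pathway=lp,
                    **fit_kwargs,
                )
                eta_full = fit.predict_eta(values)
                ll_full = ct_full.loglik(eta_full)
                ll_train = CoxTimes(time[train_ix], event[train_ix]).loglik(
                    eta_full[train_ix]
                )
                score += ll_full - ll_train
            rows.append((lg, lp, score))
    table = pd.DataFrame(rows, columns=["lambda_gene", "lambda_pathway", "cv_loglik"])
    best = table["cv_loglik"].idxmax()
    return (
        float(table.loc[best, "lambda_gene"]),
        float(table.loc[best, "lambda_pathway"]),
        table,
    )
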