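# Methods

## Model

For subject *i* (*i = 1…I*) with observed follow-up time *y_i* and event
indicator *C_i*, and gene expression *x_ijk* (gene *k* inside pathway *j*,
*j = 1…J*, pathway size *m_j*), the model places a latent variable on each
pathway,

    f_ij = Σ_k x_ijk · w_jk ,

and links the latent scores to the hazard through a Cox proportional-hazards
model with linear predictor η_i = Σ_j f_ij β_j. A gene that belongs to
several pathways contributes one weight per membership; overlap is
deliberately not deduplicated, so shared genes couple their pathways'
scores. All pathways are estimated **jointly** in one model, which is what
distinguishes this approach from single-pathway tests: correlation between
pathway scores (from co-expression and from shared genes) is handled by the
joint likelihood and the ridge penalties rather than ignored.

The estimand maximizes the ridge-penalized Breslow partial log-likelihood

    φ(W, B) = Σ_{i:C_i=1} [ η_i − log Σ_{l∈R(y_i)} exp(η_l) ]
              − ½ λ_gene ‖W‖² − ½ λ_pathway ‖B‖²,

with risk set R(y) = {l : y_l ≥ y}. Tied event times share a common
denominator (Breslow convention — it matches the plain risk-set formula
above). Two penalized-regression conventions are worth stating explicitly:

* **Gene columns are standardized** to mean 0, variance 1 before fitting
  (`standardize=False` to disable). Ridge penalties are not
  scale-equivariant, so standardization makes the penalty treat genes
  symmetrically.
* **Identifiability.** η depends on (W_j, β_j) only through their product,
  so each pair is identified up to scale and sign. The optimizer works on
  the raw penalized objective exactly as written above; on exit each latent
  score is normalized to unit sample variance with the scale absorbed into
  β_j, and the sign fixed so Σ_k w_jk ≥ 0. This normalization leaves η and
  the maximized objective unchanged and makes the reported coefficients
  unique: β_j is the log-hazard effect per standard deviation of the
  pathway score. An earlier design rescaled the latent scores after *every*
  weight update (the GSCA convention); that turned out to cancel the
  gene-level ridge — the rescale restores exactly the magnitude the penalty
  removed — leaving the weights effectively unpenalized, which both overfit
  W and slowed the alternating scheme to a geometric crawl (observed
  contraction ratio ≈ 0.993). Normalizing once at exit keeps the penalty
  meaningful and the iteration fast.

## Estimation

Alternating least squares on the IRLS working response. With
u = ∂φ/∂η and A = −∂²ℓ/∂η∂ηᵀ (the full negative Hessian of the unpenalized
partial log-likelihood; symmetric PSD with the constant vector in its null
space, since ℓ is invariant to constant shifts of η), the working response
is z = η + A⁺u. Each outer iteration performs

1. one penalized weighted-least-squares step in B with W fixed:
   B ← (FᵀAF + λ_pathway I)⁻¹ Fᵀ(Aη + u);
2. one step in the flattened weight vector with B fixed, using the design
   matrix whose column for weight (j, k) is x_{·k} β_j:
   W ← (GᵀAG + λ_gene I)⁻¹ Gᵀ(Aη + u).

Both steps are safeguarded by **step-halving against the exact penalized
objective** (up to 30 halvings; a step that cannot improve is skipped), so
the objective trace is nondecreasing by construction — plain IRLS carries no
such guarantee. The loop stops when |Δφ| between consecutive outer
iterations falls below the threshold (default 1e-4); hitting `max_iter`
(default 500) returns a fit flagged `converged=False` rather than raising.
One sweep per block per outer iteration was chosen over iterating each
block to inner convergence: both schemes are block ascent on the same
objective with the same fixed points, and the single-sweep variant reached
the 1e-4 criterion roughly 2.3× faster in wall-clock benchmarks.

Initialization: equal weights per pathway scaled so each latent score
starts at unit variance, B = 0. (Starting W at exactly zero would make
every latent score identically zero and the first weight update degenerate,
since the weight-step design matrix is proportional to B.)

Degenerate inputs: a pathway whose latent score has zero variance reports
β_j = 0; data without any event are rejected (the partial likelihood is
constant); singular normal matrices at λ = 0 fall back to least-squares
solves; overflowed working quantities (possible during tiny-λ
cross-validation fits) invalidate the step, and the safeguard keeps the
previous iterate.

## Penalty selection

5-fold cross-validation stratified by event status, scoring each (λ_gene,
λ_pathway) pair by the Verweij–van Houwelingen cross-validated partial
likelihood: the full-data log-likelihood at fold-trained parameters minus
the training-fold log-likelihood, summed over folds. Default grid 2⁻⁴…2⁸
per penalty on log2 spacing.

## Inference

Ridge estimation does not provide usable asymptotic standard errors, so
significance is by permutation:

* the permutation unit is the **(time, event) pair**, shuffled jointly
  across samples — this preserves the censoring pattern and the expression
  correlation structure;
* the model is refit on each permuted dataset with the penalties **held
  fixed** at the original fit's values (re-running CV inside every
  permutation would be computationally prohibitive and is not part of the
  procedure being calibrated);
* statistics: |β_j| per pathway and |w_jk · β_j| per gene-in-pathway
  membership (a shared gene gets one result per pathway it belongs to); the
  pathway- and gene-level tests reuse the same permutation refits;
* p-values use the add-one rule p = (#{null ≥ observed} + 1)/(B + 1),
  which never returns 0; refits that fail to converge are dropped from the
  null (an error is raised if more than 10% fail);
* multiplicity: Benjamini–Hochberg q-values (Benjamini–Yekutieli available
  via a flag).

## Competitor tests

For head-to-head comparison the package ships three single-pathway methods,
all using the same permutation-of-survival-pairs null and add-one p-values:

* **GSEA for survival** — genes ranked by the absolute Wald statistic
  (coef/SE) from per-gene univariate Cox fits; running-sum enrichment score
  with hit increments |stat|^p / Σ_hits |stat|^p and miss decrements
  1/(K−m); p = 0 is the rank-only form ("GSEA1"), p = 1 the
  statistic-weighted form ("GSEA2"). Significance is two-sided on |ES|
  against the permutation null (the full ranking is recomputed per
  permutation). The "t statistic" in the source description is read as the
  Cox Wald statistic, its natural survival analogue.
* **Global Test** — martingale residuals r from the covariate-free null
  model are scored against each member gene, Q_k = (x_kᵀr)² normalized by
  the permutation variance of x_kᵀr, and averaged over the set. Because
  the null model has no covariates, residuals are exchangeable under the
  null, so the permutation shuffles the residual-to-sample assignment
  rather than refitting; the variance estimate comes from the same
  permutation stream.
* **Wald-type test** — Σ_k (coef_k/SE_k)² over the set's univariate Cox
  fits ("individual genes", so univariate rather than joint fits).
  Non-converged or constant genes contribute 0 and are flagged.

In the benchmark drivers all methods share one permutation stream per
replicate (variance reduction in the comparisons), and the three
scan-based tests reuse one set of univariate Cox scans per permutation.

## Synthetic data

One replicate draws I samples of K genes from N(0, Σ) with
Σ = blockdiag(A, 0.2·I_{K−l}), where l = round(m_p · m_s) causal genes sit
at the start of pathway 1 and genes are partitioned into disjoint
consecutive pathways of size m_s. Scenarios for the causal block A:
(1) 0.2·I_l; (2) 0.2·[x_ij] with x_ii = 1, x_ij = 0.02 — the off-diagonal
value cannot also be the diagonal, which would give variance 0.004,
inconsistent with the other scenarios, so the diagonal is 1; (3)
0.2·[0.1^|i−j|]; (4) 0.2·[x_ij] with x_ii = 1 and x_ij ~ N(0, 0.1²)
symmetrized, projected to the nearest PSD matrix by eigenvalue clipping at
1e-8.

Survival times are exponential given η (Cox model with constant baseline
hazard h0 = 0.005); causal effects are U(0.2, 0.6) draws (all zero under
the null flag); censoring times are exponential with rate λ solved by
monotone root finding so that the expected censoring fraction
mean_i λ/(λ + r_i) equals the target c_p (λ = 0 means no censoring). The
observed time is min(survival, censoring). Survival and censoring use
independent seed substreams.

What this generator does **not** emulate: count noise and library-size
effects of RNA-seq, heavy-tailed or skewed expression distributions,
batch effects, non-proportional hazards, and realistic pathway overlap
(simulated pathways are disjoint). Passing calibration and power checks on
these data therefore validates the statistical machinery under the stated
Gaussian/proportional-hazards design, not robustness to those real-data
features.

## Benchmark experiments

Defaults follow the simulation design: K = 200, I = 80, m_s = 50 (four
pathways, pathway 1 causal), α = 0.05, scenario 1, censoring 0/0.3 for
type-I error, m_p ∈ {0.1, 0.3, 0.5} for power. Rejection is p ≤ α, which
with add-one p-values attains the level exactly whenever (B+1)·α is an
integer. Each (method, setting) cell reports the rejection fraction with an
exact (Clopper–Pearson) binomial 95% CI. Per-replicate seed substreams are
keyed by (setting, replicate); power runs reuse the same substream across
m_p values (common random numbers), so power curves are paired in m_p.
Penalties for the hierarchical model default to 5-fold CV on each setting's
first replicate over the coarse grid {1, 4, 16, 64}², then stay fixed for
all replicates and permutation refits of that setting — mirroring how the
penalties would be chosen once on a real dataset. How non-causal genes are
grouped into pathways, and the fact that competitor tests evaluate only the
causal-position set, are generator conventions, configurable in principle
and documented here.

**Problem sizes.** The shipped test suite runs the calibration experiments
at desk scale — type-I: 100 replicates × 99 permutations per censoring
setting; power: 50 replicates × 99 permutations per m_p, paired seeds — and
checks rejection counts against the central 95% region of the exact
binomial at that scale. `scripts/acceptance.py` uses 60 and 40 replicates
respectively. Larger runs (e.g. 1000 × 1000) are a matter of passing larger
`n_replicates`/`n_perm` to the same drivers.

## Known limitations

* Breslow tie handling only (adequate for continuous simulated times and
  typical expression cohorts; Efron ties are not implemented).
* The permutation test assumes exchangeability of (time, event) pairs
  across samples under the null — no covariate adjustment of the null is
  offered.
* CV selects penalties on a coarse grid by default in the benchmark
  drivers; a finer grid costs proportionally more.
* Kernel extensions of the structured-component model, multi-omics
  integration and prognostic prediction-model construction are out of
  scope.
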