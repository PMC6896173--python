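"""hiscompage — hierarchical structured-component Cox models for pathway analysis.

Summarizes gene expression into pathway-level latent variables (weighted
sums of member genes) and links them to a right-censored survival outcome
through a ridge-penalized Cox model fit by alternating least squares; all
pathways are modelled jointly, so pathway-pathway correlation is accounted
for. Significance of pathway coefficients and per-gene contributions comes
from permutation testing with FDR adjustment. Companion modules provide the
standard single-pathway competitor tests (GSEA for survival, Global Test,
Wald-type test) and a simulation harness for type-I error and power studies.
"""

from .datatypes import (
    DataError,
    ExpressionMatrix,
    HierarchyDesign,
    Pathway,
    PathwayCollection,
    SurvivalPhenotype,
)
from .io_formats import (
    filter_top_dispersion,
    filter_zero_proportion,
    log2_transform,
    map_genes_to_pathways,
    read_expression,
    read_gmt,
    read_survival,
    write_expression,
    write_gmt,
    write_survival,
)
from .cox import CoxWorking, cox_partial_loglik, cox_working_response
from .core import (
    HiscomFit,
    als_fit,
    compute_latent_scores,
    cv_select_lambdas,
    penalized_objective,
)
from .inference import (
    fdr_bh,
    gene_effect_test,
    pathway_permutation_test,
    permutation_tests,
    permute_survival,
)
from .competitors import (
    GeneRanking,
    PathwayTestResult,
    global_test,
    gsea_enrichment_score,
    gsea_test,
    univariate_cox_scan,
    wald_type_test,
)
from .simulate import (
    SimulatedDataset,
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

__version__ = "0.1.0"


def fit_pathway_model(
    X: ExpressionMatrix,
    pathways: PathwayCollection,
    survival: SurvivalPhenotype,
    lambda_gene: float | None = None,
    lambda_pathway: float | None = None,
    min_genes: int = 3,
    seed: int = 0,
    **fit_kwargs,
):
    """Convenience pipeline: align inputs, map pathways, (optionally) CV, fit.

    If either penalty is None, both are chosen by 5-fold cross-validated
    partial likelihood over the default grid. Returns (fit, design, X_mapped,
    survival_aligned).
    """
    pruned, X_mapped = map_genes_to_pathways(X, pathways, min_genes=min_genes)
    surv = survival.align_to(X_mapped)
    design = HierarchyDesign.from_collection(pruned, X_mapped)
    if lambda_gene is None or lambda_pathway is None:
        lambda_gene, lambda_pathway, _ = cv_select_lambdas(
            X_mapped, design, surv.time, surv.event, seed=seed, **fit_kwargs
        )
    fit = als_fit(
        X_mapped,
        design,
        surv.time,
        surv.event,
        lambda_gene=lambda_gene,
        lambda_pathway=lambda_pathway,
        **fit_kwargs,
    )
    return fit, design, X_mapped, surv
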