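"""End-to-end differential-expression pipeline.

Stages: size factors -> dispersion model (gene-wise MLE, trend, prior,
MAP, outlier escape) -> unshrunken MLE fit -> Cook's-distance outlier
policy -> LFC prior width and MAP (ridge) fit on the expanded design ->
Wald or composite-threshold test -> independent filtering and BH
adjustment.  The pipeline is a pure function of (counts, metadata,
configuration): rerunning it reproduces results bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    CountDataset,
    estimate_size_factors,
    mean_normalized_counts,
)
from .design import DesignMatrix, DesignSpec, build_design, contrast_vector
from .dispersion import (
    DispersionModel,
    classify_dispersion_outliers,
    estimate_dispersions,
    genewise_dispersion_mle,
    map_dispersion,
)
from .glm import LN2, GLMFit, coefficient_covariance, contrast, fit_nb_glm_matrix
from .inference import (
    bh_adjust,
    composite_test_greater,
    composite_test_less,
    independent_filter,
    wald_test,
)
from .outliers import (
    apply_outlier_policy,
    cooks_cutoff,
    cooks_distances,
    robust_mom_dispersion,
)
from .shrinkage import LFCPrior, estimate_lfc_prior, fit_map_lfc

logger = logging.getLogger("nbshrink")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

RESULT_COLUMNS = [
    "baseMean",
    "log2FoldChange",
    "lfcSE",
    "stat",
    "pvalue",
    "padj",
    "maxCooks",
    "status",
]


@dataclass
class RunConfig:
    """Pipeline configuration.

    ``test`` is one of "standard" (null: LFC = 0), "greaterAbs" (null:
    |LFC| <= theta) or "lessAbs" (null: |LFC| >= theta; requires
    ``shrinkage=False``).  ``target_fdr`` drives both the independent
    filtering objective and the default call threshold.
    """

    test: str = "standard"
    lfc_threshold: float = 0.0
    target_fdr: float = 0.1
    shrinkage: bool = True
    outlier_policy: bool = True
    independent_filtering: bool = True
    matching_p: float = 0.05

    def __post_init__(self):
        if self.test not in {"standard", "greaterAbs", "lessAbs"}:
            raise ValueError(f"unknown test mode {self.test!r}")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be non-negative")
        if self.test == "lessAbs" and self.shrinkage:
            raise ValueError(
                "testing the null of large LFCs requires the LFC prior to be "
                "disabled (shrinkage=False)"
            )


@dataclass
class PipelineResult:
    results: pd.DataFrame
    dispersion_model: DispersionModel
    lfc_prior: LFCPrior | None
    filter_threshold: float | None
    size_factors: np.ndarray
    standard_design: DesignMatrix
    test_design: DesignMatrix
    mle_fit: GLMFit
    final_fit: GLMFit
    cooks: object | None = None
    config: RunConfig = field(default_factory=RunConfig)


def _refit_replaced(
    counts_sub: np.ndarray,
    X: np.ndarray,
    norm_sub: np.ndarray,
    disp_model: DispersionModel,
) -> tuple[np.ndarray, GLMFit]:
    """Re-estimate dispersions (fixed trend and prior) and the MLE fit
    for genes whose outlier counts were replaced."""
    bar_mu = (counts_sub / norm_sub).mean(axis=1)
    alpha_gw, _, mu0 = genewise_dispersion_mle(counts_sub, X, norm_sub)
    trend = disp_model.trend(bar_mu)
    alpha_map, _ = map_dispersion(counts_sub, mu0, X, trend, disp_model.prior_var)
    flags = classify_dispersion_outliers(alpha_gw, trend, disp_model.residual_sd)
    final = np.where(flags, alpha_gw, alpha_map)
    mle = fit_nb_glm_matrix(counts_sub, X, norm_sub, final)
    return final, mle


def run_pipeline(
    dataset: CountDataset,
    formula: str = "~ condition",
    contrast_spec: tuple[str, str, str] | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full analysis and return the per-gene result table."""
    config = config or RunConfig()
    spec = DesignSpec.from_formula(formula, dataset.sample_info)
    if contrast_spec is None:
        if len(spec.factors) != 1:
            raise ValueError("contrast_spec is required unless the design has one factor")
        fname, levels = next(iter(spec.factors.items()))
        if len(levels) != 2:
            raise ValueError("contrast_spec is required for factors with >2 levels")
        contrast_spec = (fname, levels[1], levels[0])

    if not dataset.has_normalization:
        estimate_size_factors(dataset)
    s = dataset.normalization
    s_mat = dataset.normalization_matrix()
    logger.info("size factors: %s", np.round(np.asarray(s).ravel()[:10], 4))

    counts = dataset.counts.astype(float)
    n, m = counts.shape
    std = build_design(spec, dataset.sample_info, expanded=False)
    X = std.matrix

    disp = estimate_dispersions(counts, X, s)
    logger.info(
        "dispersion trend a1=%.4g alpha0=%.4g sigma_d2=%.4g s_lr=%.4g outliers=%d",
        disp.trend_a1, disp.trend_alpha0, disp.prior_var, disp.residual_sd,
        int(disp.outlier_flags.sum()),
    )

    nonzero = counts.sum(axis=1) > 0
    final_disp = np.where(np.isfinite(disp.final) & (disp.final > 0), disp.final, 1e-8)

    # unshrunken MLE fit on the standard design
    mle_fit = fit_nb_glm_matrix(counts, X, s_mat, final_disp)

    # Cook's distances and the outlier policy
    status = np.array(["ok"] * n, dtype=object)
    status[~nonzero] = "all_zero"
    max_cooks = np.full(n, np.nan)
    cooks_diag = None
    work_counts = counts
    work_mle = mle_fit
    work_disp = final_disp
    if config.outlier_policy and m > std.n_parameters:
        alpha_rob = robust_mom_dispersion(counts, s_mat)
        alpha_rob_safe = np.where(np.isfinite(alpha_rob), alpha_rob, 0.0)
        D, _h = cooks_distances(counts, mle_fit, alpha_rob_safe)
        D = np.where(nonzero[:, None], D, np.nan)
        cutoff = cooks_cutoff(std.n_parameters, m)
        codes = spec.condition_cells(dataset.sample_info)
        cooks_diag = apply_outlier_policy(dataset.counts, D, cutoff, codes, s_mat)
        with np.errstate(invalid="ignore"):
            max_cooks = np.nanmax(np.where(np.isnan(D), -np.inf, D), axis=1)
        max_cooks[~np.isfinite(max_cooks)] = np.nan
        removed = cooks_diag.action == "gene_removed"
        replaced = cooks_diag.action == "count_replaced"
        status[removed] = "cooks_outlier_removed"
        status[replaced] = "counts_replaced"
        logger.info(
            "Cook's cutoff %.4g: %d genes removed, %d genes with replaced counts",
            cutoff, int(removed.sum()), int(replaced.sum()),
        )
        if np.any(replaced):
            work_counts = counts.copy()
            work_counts[replaced] = cooks_diag.replaced_counts[replaced]
            new_disp, new_mle = _refit_replaced(
                work_counts[replaced], X, s_mat[replaced], disp
            )
            work_disp = final_disp.copy()
            work_disp[replaced] = new_disp
            work_mle = fit_nb_glm_matrix(work_counts, X, s_mat, work_disp)

    # final (possibly shrunken) coefficient fit and contrast
    lfc_prior = None
    if config.shrinkage:
        expanded = build_design(spec, dataset.sample_info, expanded=True)
        lfc_prior = estimate_lfc_prior(work_mle, std, expanded, config.matching_p)
        logger.info(
            "LFC prior sd (log2): %s",
            np.round(np.sqrt(lfc_prior.sigma2) / LN2, 4),
        )
        final_fit, cov = fit_map_lfc(work_counts, expanded, s_mat, work_disp, lfc_prior)
        test_design = expanded
    else:
        final_fit = work_mle
        cov = coefficient_covariance(final_fit)
        test_design = std

    cvec = contrast_vector(test_design, *contrast_spec)
    lfc, lfc_se = contrast(final_fit, cov, cvec, log2_scale=True)

    # hypothesis test
    theta = config.lfc_threshold
    stat, p_standard = wald_test(lfc, lfc_se)
    if config.test == "standard":
        pvalue = p_standard
    elif config.test == "greaterAbs":
        pvalue = composite_test_greater(lfc, lfc_se, theta)
    else:
        pvalue = composite_test_less(lfc, lfc_se, theta, prior_used=config.shrinkage)

    # missingness: all-zero genes, removed genes, non-converged fits
    not_tested = ~nonzero | (status == "cooks_outlier_removed") | ~final_fit.converged
    pvalue = np.where(not_tested, np.nan, pvalue)
    stat = np.where(not_tested, np.nan, stat)
    base_mean = mean_normalized_counts(dataset)

    if config.independent_filtering:
        threshold, padj = independent_filter(base_mean, pvalue, config.target_fdr)
        logger.info("independent filtering threshold: %.4g", threshold)
    else:
        threshold, padj = None, bh_adjust(pvalue)

    results = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": np.where(nonzero, lfc, np.nan),
            "lfcSE": np.where(nonzero, lfc_se, np.nan),
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
            "maxCooks": max_cooks,
            "status": status,
        },
        index=pd.Index(dataset.gene_ids, name="gene"),
    )[RESULT_COLUMNS]

    return PipelineResult(
        results=results,
        dispersion_model=disp,
        lfc_prior=lfc_prior,
        filter_threshold=threshold,
        size_factors=np.asarray(s),
        standard_design=std,
        test_design=test_design,
        mle_fit=mle_fit,
        final_fit=final_fit,
        cooks=cooks_diag,
        config=config,
    )
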