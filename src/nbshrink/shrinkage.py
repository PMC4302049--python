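"""Empirical-Bayes shrinkage of log fold changes.

A zero-centered normal prior ``beta_r ~ N(0, sigma_r^2)`` is placed on
every non-intercept coefficient.  The prior width is estimated from the
spread of unpenalized MLE fold changes by quantile matching: sigma_r is
chosen so that the (1-p) empirical quantile of |beta_r^MLE| matches the
(1-p/2) quantile of N(0, sigma_r^2), with p = 0.05 by default.  MLEs
with |LFC| above 10 (base 2) are excluded as outliers, and for factors
the matched widths are averaged over all pairwise level contrasts so
the result does not depend on the choice of base level.

The MAP coefficients are obtained by iteratively reweighted ridge
regression on the *expanded* design matrix (one indicator per factor
level), which makes shrinkage symmetric across levels.  When
interaction terms are present, main-effect widths are not estimated but
set to a fixed wide value, (log 2)^2 * 1000 on the natural-log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .design import DesignMatrix
from .glm import LN2, GLMFit, coefficient_covariance, fit_nb_glm_matrix

__all__ = [
    "LFCPrior",
    "matched_prior_width",
    "estimate_lfc_prior",
    "fit_map_lfc",
    "WIDE_PRIOR_VAR",
]

# (log 2)^2 * 1000: natural-log-scale variance of the deliberately wide
# prior used for main effects under interaction designs and as fallback
WIDE_PRIOR_VAR = (LN2**2) * 1000.0
EXCLUDE_ABS_LFC = LN2 * 10.0  # |beta| > 10 on the log2 scale is excluded
MIN_MLES = 10
SIGMA_FLOOR = 1e-3 * LN2  # natural-log floor (1e-3 on the log2 scale)


@dataclass
class LFCPrior:
    """Per-coefficient prior variances on the natural-log scale.

    ``sigma2[r]`` is the variance for design column r; ``np.inf`` marks
    unpenalized columns (the intercept).  ``matching_p`` is the tail
    probability of the quantile match.
    """

    sigma2: np.ndarray
    matching_p: float = 0.05

    def penalties(self) -> np.ndarray:
        """Ridge penalties lambda_r = 1/sigma_r^2 (0 for unpenalized)."""
        lam = np.zeros_like(self.sigma2)
        finite = np.isfinite(self.sigma2)
        lam[finite] = 1.0 / self.sigma2[finite]
        return lam


def matched_prior_width(mle_betas: np.ndarray, matching_p: float = 0.05) -> float | None:
    """Quantile-matched prior sd for one coefficient:

        sigma_r = Q_{|beta|}(1 - p) / Q_N(1 - p/2),

    on whatever scale ``mle_betas`` is given.  Returns None when fewer
    than MIN_MLES usable values remain after excluding non-finite and
    extreme (|beta| > 10 log2 units) estimates.
    """
    b = np.asarray(mle_betas, dtype=float)
    b = b[np.isfinite(b)]
    b = b[np.abs(b) <= EXCLUDE_ABS_LFC]
    if b.size < MIN_MLES:
        return None
    q_emp = float(np.quantile(np.abs(b), 1.0 - matching_p))
    q_norm = float(stats.norm.ppf(1.0 - matching_p / 2.0))
    return max(q_emp / q_norm, SIGMA_FLOOR)


def estimate_lfc_prior(
    mle_fit: GLMFit,
    standard_design: DesignMatrix,
    expanded_design: DesignMatrix,
    matching_p: float = 0.05,
) -> LFCPrior:
    """Map quantile-matched widths from standard-design MLEs onto the
    columns of the (possibly expanded) design used for the MAP fit.

    For each factor the width is the average over all pairwise level
    contrasts of the matched widths (base-level independence);
    covariates use their own coefficient distribution.  With
    interaction terms, main effects get the fixed wide variance and
    only interaction coefficients are matched to data.
    """
    betas = mle_fit.beta  # natural-log scale, (n, p_std)
    has_interactions = bool(standard_design.spec.interactions)

    def col_index(name: str) -> int:
        return standard_design.columns.index(name)

    factor_sigma: dict[str, float | None] = {}
    for fname, levels in standard_design.spec.factors.items():
        widths = []
        base = levels[0]
        # coefficient for level lv (vs base); base itself is the zero vector
        def coef(lv):
            if lv == base:
                return np.zeros(betas.shape[0])
            return betas[:, col_index(f"{fname}_{lv}_vs_{base}")]

        for la, lb in combinations(levels, 2):
            w = matched_prior_width(coef(la) - coef(lb), matching_p)
            if w is not None:
                widths.append(w)
        factor_sigma[fname] = float(np.mean(widths)) if widths else None

    sigma2 = np.full(expanded_design.n_columns, WIDE_PRIOR_VAR)
    for idx, (name, fac) in enumerate(
        zip(expanded_design.columns, expanded_design.column_factor)
    ):
        if name == "Intercept":
            sigma2[idx] = np.inf
        elif fac is not None:  # factor level indicator (or std-coded level)
            if has_interactions:
                sigma2[idx] = WIDE_PRIOR_VAR
                continue
            w = factor_sigma.get(fac)
            if w is None:
                warnings.warn(
                    f"too few usable MLE fold changes for factor {fac!r}; "
                    "falling back to a wide prior"
                )
                sigma2[idx] = WIDE_PRIOR_VAR
            else:
                sigma2[idx] = w**2
        elif ":" in name:  # interaction column
            w = matched_prior_width(betas[:, col_index(name)], matching_p)
            sigma2[idx] = WIDE_PRIOR_VAR if w is None else w**2
        else:  # numeric covariate
            if has_interactions:
                sigma2[idx] = WIDE_PRIOR_VAR
                continue
            w = matched_prior_width(betas[:, col_index(name)], matching_p)
            if w is None:
                warnings.warn(
                    f"too few usable MLE estimates for covariate {name!r}; "
                    "falling back to a wide prior"
                )
                sigma2[idx] = WIDE_PRIOR_VAR
            else:
                sigma2[idx] = w**2
    return LFCPrior(sigma2=sigma2, matching_p=matching_p)


def fit_map_lfc(
    counts,
    expanded_design: DesignMatrix,
    normalization,
    dispersions,
    prior: LFCPrior,
) -> tuple[GLMFit, np.ndarray]:
    """Ridge (MAP) fit of all genes on the expanded design with the
    given prior; returns the fit and the sandwich covariance stack.

    ``dispersions`` must be the *final* per-gene values (MAP, or the
    gene-wise estimate for dispersion outliers).
    """
    lam = prior.penalties()
    fit = fit_nb_glm_matrix(
        np.atleast_2d(counts), expanded_design.matrix, normalization, dispersions,
        penalty=lam,
    )
    cov = coefficient_covariance(fit)
    return fit, cov
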