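"""Regularized-logarithm transformation.

For clustering and ordination, counts must be made approximately
homoskedastic: raw log2(normalized counts) exaggerates differences at
low counts, where Poisson noise dominates.  The rlog fits, per gene, an
intercept plus one shrunken per-sample coefficient,

    rlog(K_ij) = log2 q_ij = beta_i0 + beta_ij,

via the same ridge machinery used for fold-change shrinkage, with the
per-sample coefficients under a zero-centered normal prior and the
dispersions fixed at the fitted mean-dispersion trend.  For large
counts the transform approaches log2(K/s); for small counts the
per-sample values are pulled together.

In blind mode (the default) the experimental design is ignored and
dispersions are re-estimated treating all samples as replicates, so the
transformation is unsupervised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import CountDataset, estimate_size_factors, mean_normalized_counts, normalized_counts
from .dispersion import fit_dispersion_trend, genewise_dispersion_mle
from .glm import LN2, fit_nb_glm_matrix

__all__ = ["RlogOutput", "rlog_prior_width", "rlog_transform"]

PRIOR_VAR_FLOOR = 1e-6  # log2^2 units


@dataclass
class RlogOutput:
    transformed: np.ndarray  # (n, m), log2 scale
    intercept: np.ndarray  # (n,) log2 scale
    sample_lfcs: np.ndarray  # (n, m) shrunken per-sample log2 LFCs
    prior_var: float  # log2^2 scale
    blind: bool


def rlog_prior_width(dataset: CountDataset) -> float:
    """Prior variance (log2^2 scale) for the per-sample coefficients.

    A matrix of LFCs is formed as log2((K/s + 1/2) / (mean(K/s) + 1/2));
    the prior sd matches the 95% quantile of its absolute values to the
    97.5% quantile of a zero-centered normal.  Degenerate (all-equal)
    data hit a small positive floor.
    """
    q = normalized_counts(dataset)
    bar_mu = q.mean(axis=1)
    lfc = np.log2((q + 0.5) / (bar_mu[:, None] + 0.5))
    q95 = float(np.quantile(np.abs(lfc), 0.95))
    sigma = q95 / float(stats.norm.ppf(0.975))
    return max(sigma**2, PRIOR_VAR_FLOOR)


def _sample_indicator_design(m: int) -> np.ndarray:
    return np.column_stack([np.ones(m), np.eye(m)])


def rlog_transform(
    dataset: CountDataset,
    blind: bool = True,
    design_matrix: np.ndarray | None = None,
) -> RlogOutput:
    """Apply the regularized-logarithm transformation.

    ``blind=True`` (default) estimates the dispersion trend with an
    intercept-only model, ignoring any experimental design;
    ``blind=False`` uses ``design_matrix`` (intercept-only when absent)
    for the trend estimation only.  The per-gene fit always uses the
    intercept + per-sample-indicator design.
    """
    if dataset.n_samples < 2:
        raise ValueError("rlog requires at least two samples")
    if not dataset.has_normalization:
        estimate_size_factors(dataset)
    counts = dataset.counts.astype(float)
    n, m = counts.shape
    s = dataset.normalization_matrix()
    bar_mu = mean_normalized_counts(dataset)

    if blind or design_matrix is None:
        trend_design = np.ones((m, 1))
    else:
        trend_design = np.asarray(design_matrix, dtype=float)

    nonzero = bar_mu > 0
    if m - trend_design.shape[1] < 1 or m <= 2:
        warnings.warn(
            "too few samples for a stable dispersion trend; using a flat "
            "median-dispersion trend"
        )
        alpha_gw, _, _ = genewise_dispersion_mle(
            counts[nonzero], np.ones((m, 1)), s[nonzero]
        )
        alpha0 = float(np.median(alpha_gw))
        trend_values = np.full(n, alpha0)
    else:
        alpha_gw, at_bound, _ = genewise_dispersion_mle(
            counts[nonzero], trend_design, s[nonzero]
        )
        gw = np.where(at_bound, np.nan, alpha_gw)
        a1, alpha0, _ = fit_dispersion_trend(gw, bar_mu[nonzero])
        trend_values = a1 / np.maximum(bar_mu, 1e-8) + alpha0

    prior_var_log2 = rlog_prior_width(dataset)
    prior_var_nat = prior_var_log2 * LN2**2
    X = _sample_indicator_design(m)
    lam = np.concatenate([[0.0], np.full(m, 1.0 / prior_var_nat)])
    fit = fit_nb_glm_matrix(counts, X, s, np.maximum(trend_values, 1e-8), penalty=lam)

    beta0 = fit.beta[:, 0] / LN2
    blfc = fit.beta[:, 1:] / LN2
    transformed = beta0[:, None] + blfc
    # all-zero genes have undefined fits; report the floor of the scale
    zero = ~nonzero
    if np.any(zero):
        transformed[zero] = np.log2(0.5)
        beta0 = np.where(zero, np.log2(0.5), beta0)
        blfc[zero] = 0.0
    return RlogOutput(
        transformed=transformed,
        intercept=beta0,
        sample_lfcs=blfc,
        prior_var=prior_var_log2,
        blind=blind,
    )
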