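"""Wald and composite-threshold tests, BH adjustment, independent filtering.

The Wald statistic divides an estimated (possibly shrunken) LFC by its
standard error and refers it to a standard normal.  Composite tests
replace the point null with |LFC| <= theta (evidence of change larger
than theta) or |LFC| >= theta (evidence of change smaller than theta,
requiring that no LFC prior was used).  P values are adjusted with the
Benjamini-Hochberg step-up procedure; independent filtering first drops
genes with mean normalized count below a threshold chosen to maximize
the number of discoveries at the target FDR — valid because the mean
count is independent of the test statistic under the null.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "wald_test",
    "composite_test_greater",
    "composite_test_less",
    "bh_adjust",
    "independent_filter",
]


def wald_test(beta, se) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Wald test: z = beta/SE, p = 2*Phi(-|z|).

    Degenerate SE=0 cases give p=0 (beta != 0, with a warning) or p=1
    (beta == 0).  Missing inputs propagate as NaN.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    zero_se = se == 0
    if np.any(zero_se & (beta != 0)):
        warnings.warn("zero standard error with non-zero estimate; p set to 0")
        p = np.where(zero_se & (beta != 0), 0.0, p)
        with np.errstate(invalid="ignore"):
            z = np.where(zero_se & (beta != 0), np.inf * np.sign(beta), z)
    p = np.where(zero_se & (beta == 0), 1.0, p)
    return z, p


def composite_test_greater(beta, se, theta: float) -> np.ndarray:
    """Test of the composite null |LFC| <= theta:
    ``p = min(1, 2*(1 - Phi((|beta| - theta)/SE)))``.  Equals the Wald
    p value when theta = 0."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2.0 * stats.norm.sf((np.abs(beta) - theta) / se)
    return np.minimum(p, 1.0)


def composite_test_less(beta, se, theta: float, prior_used: bool = False) -> np.ndarray:
    """Test of the composite null |LFC| >= theta: the maximum of the two
    one-sided tests against beta = theta and beta = -theta,

        p = max( Phi((beta - theta)/SE), 1 - Phi((beta + theta)/SE) ).

    Must be applied to *unshrunken* estimates: a zero-centered prior
    would favor this alternative hypothesis.
    """
    if prior_used:
        raise ValueError(
            "the |LFC| >= theta test requires unshrunken estimates; disable "
            "the LFC prior"
        )
    if theta <= 0:
        raise ValueError("theta must be positive")
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_low = stats.norm.cdf((beta - theta) / se)
        p_high = stats.norm.sf((beta + theta) / se)
    return np.maximum(p_low, p_high)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Missing (NaN) entries are ignored and stay missing; the effective
    number of tests is the number of non-missing p values.
    """
    p = np.asarray(pvalues, dtype=float)
    adj = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    n = int(ok.sum())
    if n == 0:
        return adj
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    adj[ok] = out
    return adj


def independent_filter(
    base_mean, pvalues, target_fdr: float = 0.1
) -> tuple[float, np.ndarray]:
    """Choose the mean-normalized-count threshold maximizing the number
    of adjusted p values below ``target_fdr``.

    Candidate thresholds are 50 quantiles of the mean normalized count
    (from the fraction of zero-mean genes up to 95%).  The rejection
    count over thresholds is noisy, and taking its raw argmax
    systematically overshoots (selection bias toward lucky thresholds,
    which inflates the realized FDR); instead the curve is smoothed by
    lowess and the *smallest* threshold whose rejection count reaches
    the smoothed maximum minus one root-mean-square residual is chosen.
    With 10 or fewer rejections at every threshold, no filtering is
    done.  Returns (threshold, padj); genes below the threshold (or
    with missing p) get NaN.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    base_mean = np.asarray(base_mean, dtype=float)
    p = np.asarray(pvalues, dtype=float)
    if base_mean.size == 0:
        raise ValueError("empty result table")
    tested = np.isfinite(p)
    if not np.any(tested):
        return 0.0, np.full(p.shape, np.nan)

    lower_q = float(np.mean(base_mean[tested] == 0))
    upper_q = 0.95 if lower_q < 0.95 else 1.0
    theta_grid = np.linspace(lower_q, upper_q, 50)
    cutoffs = np.quantile(base_mean[tested], theta_grid)

    padj_all = []
    num_rej = np.empty(len(cutoffs), dtype=int)
    for k, theta in enumerate(cutoffs):
        mask = tested & (base_mean >= theta)
        padj = np.full(p.shape, np.nan)
        padj[mask] = bh_adjust(p[mask])
        padj_all.append(padj)
        num_rej[k] = int(np.nansum(padj < target_fdr))

    if num_rej.max() <= 10:
        j = 0
    else:
        fitted = lowess(num_rej, theta_grid, frac=1.0 / 5.0, return_sorted=False)
        pos = num_rej > 0
        rmse = float(np.sqrt(np.mean((num_rej[pos] - fitted[pos]) ** 2))) if pos.any() else 0.0
        max_fit = float(fitted.max())
        thresh = max_fit - rmse
        above = np.flatnonzero(num_rej > thresh)
        if above.size:
            j = int(above[0])
        else:
            for frac in (0.9, 0.8):
                above = np.flatnonzero(num_rej > frac * max_fit)
                if above.size:
                    j = int(above[0])
                    break
            else:
                j = 0
    return float(cutoffs[j]), padj_all[j]
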