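"""Count-outlier detection via Cook's distance and the replace/remove policy.

Cook's distance for a GLM measures how far the coefficient vector would
move if one sample were dropped:

    D_j = R_j^2 / (tau * p) * h_jj / (1 - h_jj)^2,

with Pearson residual R_j = (K_j - mu_j)/sqrt(V(mu_j)), V(mu) = mu +
alpha*mu^2, hat diagonal h_jj from H = W^1/2 X (X'WX)^-1 X' W^1/2, and
tau = 1 for the NB family.  The dispersion entering V is a robust
method-of-moments value so the outlier itself does not mask the
diagnostic.  Samples with D above the 0.99 quantile of F(p, m-p) are
flagged; conditions with two or fewer replicates are exempt.  A flagged
sample in a condition with at most six replicates removes the gene from
testing; with seven or more replicates the count is replaced by the
trimmed mean of normalized counts scaled by the size factor, and the
gene is refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .glm import GLMFit

__all__ = [
    "CooksDiagnostics",
    "robust_mom_dispersion",
    "hat_diagonal",
    "cooks_distances",
    "cooks_cutoff",
    "flag_outliers",
    "replacement_counts",
]

TRIM_FRACTION = 0.2
_MAD_SCALE = 1.0 / stats.norm.ppf(0.75)


@dataclass
class CooksDiagnostics:
    distances: np.ndarray  # (n, m)
    hat_diag: np.ndarray  # (n, m)
    robust_alpha: np.ndarray  # (n,)
    cutoff: float
    flags: np.ndarray  # (n, m) sample-level flags
    action: np.ndarray  # (n,) strings: none | gene_removed | count_replaced
    replaced_counts: np.ndarray | None = None


def robust_mom_dispersion(counts, normalization) -> np.ndarray:
    """Method-of-moments dispersion with a robust variance:

        alpha_rob = max((s_rob^2 - mu_bar)/mu_bar^2, 0),

    where s_rob^2 is the squared, normal-consistent MAD of the
    normalized counts.  Genes with mu_bar = 0 return NaN (diagnostics
    are skipped for them)."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    s = np.asarray(normalization, dtype=float)
    q = counts / (np.broadcast_to(s, counts.shape) if s.ndim == 1 else s)
    bar_mu = q.mean(axis=1)
    med = np.median(q, axis=1)
    s_rob = np.median(np.abs(q - med[:, None]), axis=1) * _MAD_SCALE
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.maximum((s_rob**2 - bar_mu) / bar_mu**2, 0.0)
    return np.where(bar_mu > 0, alpha, np.nan)


def hat_diagonal(design: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Diagonal of H = W^1/2 X (X'WX)^-1 X' W^1/2 per gene; weights is
    (n, m).  Rows of H sum (trace) to the number of parameters."""
    X = np.asarray(design, dtype=float)
    XtWX = np.einsum("jr,nj,js->nrs", X, weights, X, optimize=True)
    XtWX_inv = np.linalg.inv(XtWX)
    # h_jj = w_j * x_j' (X'WX)^-1 x_j
    quad = np.einsum("jr,nrs,js->nj", X, XtWX_inv, X, optimize=True)
    return weights * quad


def cooks_distances(
    counts, mle_fit: GLMFit, robust_alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample Cook's distances (and hat diagonals) from the MLE fit,
    using the robust dispersion in both the variance function and the
    weights.  Saturated samples (h_jj ~ 1) get NaN distances."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    X = mle_fit.design
    p = X.shape[1]
    mu = mle_fit.mu
    alpha = np.asarray(robust_alpha, dtype=float)[:, None]
    V = mu + alpha * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (counts - mu) / np.sqrt(V)
        w = 1.0 / (1.0 / mu + alpha)
        h = hat_diagonal(X, w)
        D = R**2 / p * h / (1.0 - h) ** 2
    D = np.where(np.abs(1.0 - h) < 1e-8, np.nan, D)
    return D, h


def cooks_cutoff(p: int, m: int, level: float = 0.99) -> float:
    """Flagging threshold: the ``level`` quantile of F(p, m - p)."""
    if m - p <= 0:
        raise ValueError("need more samples than parameters for the F cutoff")
    return float(stats.f.ppf(level, p, m - p))


def flag_outliers(
    distances: np.ndarray,
    cutoff: float,
    condition_codes: np.ndarray,
) -> np.ndarray:
    """Sample-level flags: D above the cutoff, except in conditions with
    two or fewer replicates (insufficient replication to call an
    outlier)."""
    codes = np.asarray(condition_codes)
    counts = np.bincount(codes)
    eligible = counts[codes] > 2  # (m,)
    with np.errstate(invalid="ignore"):
        return (distances > cutoff) & eligible[None, :]


def replacement_counts(counts, normalization, trim: float = TRIM_FRACTION) -> np.ndarray:
    """Imputed replacement values: the trimmed mean (``trim`` fraction
    per tail) of the normalized counts, scaled back by the size factor
    and rounded to an integer count."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    s = np.asarray(normalization, dtype=float)
    s_mat = np.broadcast_to(s, counts.shape) if s.ndim == 1 else s
    q = counts / s_mat
    tmean = stats.trim_mean(q, trim, axis=1)
    return np.round(tmean[:, None] * s_mat).astype(np.int64)


def apply_outlier_policy(
    counts,
    distances: np.ndarray,
    cutoff: float,
    condition_codes: np.ndarray,
    normalization,
) -> CooksDiagnostics:
    """Decide and apply the per-gene action.

    A flagged sample whose condition has <= 6 replicates removes the
    whole gene from testing; if all flagged samples sit in conditions
    with >= 7 replicates, their counts are replaced by the trimmed-mean
    imputation and the gene is marked for refitting.  Returns the
    diagnostics; the modified count matrix is in ``.replaced_counts``.
    """
    counts = np.atleast_2d(np.asarray(counts))
    codes = np.asarray(condition_codes)
    reps = np.bincount(codes)
    flags = flag_outliers(distances, cutoff, codes)
    n = counts.shape[0]
    action = np.array(["none"] * n, dtype=object)
    new_counts = counts.copy()
    replacement = replacement_counts(counts, normalization)
    for i in np.flatnonzero(flags.any(axis=1)):
        sample_idx = np.flatnonzero(flags[i])
        if np.any(reps[codes[sample_idx]] <= 6):
            action[i] = "gene_removed"
        else:
            action[i] = "count_replaced"
            new_counts[i, sample_idx] = replacement[i, sample_idx]
    return CooksDiagnostics(
        distances=distances,
        hat_diag=np.empty(0),
        robust_alpha=np.empty(0),
        cutoff=cutoff,
        flags=flags,
        action=action,
        replaced_counts=new_counts,
    )
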