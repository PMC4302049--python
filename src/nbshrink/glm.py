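"""Negative-binomial GLM likelihood and (ridge-penalized) IRLS fitting.

Counts are modelled as NB(mean mu, dispersion alpha) with log link,
``mu_j = s_j * exp(sum_r x_jr beta_r)`` and variance ``mu + alpha*mu^2``
(NB size parameter 1/alpha).  Coefficients are kept on the natural-log
scale internally; user-facing fold changes are base 2.

The fitter solves the penalized score equations by iteratively
reweighted ridge regression,

    beta <- (X'WX + diag(lambda))^-1 X'W z,

with weights ``w_jj = 1/(1/mu_j + alpha)`` and working response
``z_j = log(mu_j/s_j) + (K_j - mu_j)/mu_j``.  ``lambda_r = 1/sigma_r^2``
is the ridge penalty implied by a zero-centered normal prior on
coefficient r (0 means unpenalized, e.g. the intercept).  A
step-halving guard keeps the penalized log-likelihood non-decreasing.

All fitting routines are vectorized across genes: a whole (genes x
samples) matrix is fit in one call, with per-gene dispersions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GLMFit",
    "nb_log_pmf",
    "nb_log_likelihood",
    "fit_nb_glm_matrix",
    "fit_nb_glm",
    "coefficient_covariance",
    "contrast",
]

LN2 = np.log(2.0)
_MU_FLOOR = 1e-10
_MAX_ITER = 100
_TOL = 1e-8


@dataclass
class GLMFit:
    """Per-gene GLM fits (natural-log coefficients internally)."""

    beta: np.ndarray  # (n, p)
    mu: np.ndarray  # (n, m) fitted means, floored at _MU_FLOOR
    converged: np.ndarray  # (n,) bool
    loglik: np.ndarray  # (n,) penalized log-likelihood at the solution
    design: np.ndarray  # (m, p)
    alpha: np.ndarray  # (n,) dispersions used
    penalty: np.ndarray  # (p,) lambda_r

    @property
    def beta_log2(self) -> np.ndarray:
        """Coefficients on the user-facing log2 scale."""
        return self.beta / LN2

    def weights(self) -> np.ndarray:
        """IRLS diagonal weights w_jj = 1/(1/mu_j + alpha)."""
        return 1.0 / (1.0 / self.mu + self.alpha[:, None])


def nb_log_pmf(k, mu, alpha):
    """Log pmf of NB with mean ``mu`` and dispersion ``alpha``
    (variance ``mu + alpha*mu^2``; size ``r = 1/alpha``)."""
    k = np.asarray(k, dtype=float)
    if np.any(k < 0) or not np.allclose(k, np.round(k)):
        raise ValueError("k must be non-negative integers")
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(mu <= 0) or np.any(alpha <= 0):
        raise ValueError("mu and alpha must be positive")
    r = 1.0 / alpha
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1.0)
        + r * np.log(r / (r + mu))
        + k * np.log(mu / (r + mu))
    )


def nb_log_likelihood(counts: np.ndarray, mu: np.ndarray, alpha) -> np.ndarray:
    """Row sums of the NB log pmf; counts and mu are (n, m), alpha is
    scalar or (n,).  No input validation (hot path)."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim == 1:
        alpha = alpha[:, None]
    r = 1.0 / alpha
    return (
        gammaln(counts + r)
        - gammaln(r)
        - gammaln(counts + 1.0)
        + r * np.log(r / (r + mu))
        + counts * np.log(mu / (r + mu))
    ).sum(axis=1)


def _penalized_loglik(counts, mu, alpha, beta, lam) -> np.ndarray:
    pen = 0.5 * (beta**2 * lam).sum(axis=1)
    return nb_log_likelihood(counts, mu, alpha) - pen


def fit_nb_glm_matrix(
    counts: np.ndarray,
    design: np.ndarray,
    normalization: np.ndarray,
    alpha,
    penalty: np.ndarray | None = None,
    beta_init: np.ndarray | None = None,
    max_iter: int = _MAX_ITER,
    tol: float = _TOL,
) -> GLMFit:
    """Fit NB GLMs for all genes at once.

    Parameters
    ----------
    counts : (n, m) array
    design : (m, p) array
    normalization : (m,) or (n, m) positive factors s
    alpha : scalar or (n,) dispersions
    penalty : (p,) ridge penalties lambda_r (None = unpenalized)
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    n, m = counts.shape
    X = np.asarray(design, dtype=float)
    p = X.shape[1]
    s = np.asarray(normalization, dtype=float)
    if s.ndim == 1:
        s = np.broadcast_to(s, (n, m))
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (n,)).copy()
    lam = np.zeros(p) if penalty is None else np.asarray(penalty, dtype=float)
    if lam.shape != (p,):
        raise ValueError("penalty length must equal the number of design columns")

    log_s = np.log(s)
    all_zero = counts.sum(axis=1) == 0

    # initialization: ridge least squares of log(K/s + 0.5) on X
    if beta_init is not None:
        beta = np.array(beta_init, dtype=float)
    else:
        y0 = np.log(counts / s + 0.5)
        A0 = X.T @ X + np.diag(lam + 1e-6)
        beta = np.linalg.solve(A0, X.T @ y0.T).T  # (n, p)

    def mu_of(beta):
        eta = np.clip(beta @ X.T, -100.0, 100.0)
        return np.maximum(s * np.exp(eta), _MU_FLOOR)

    mu = mu_of(beta)
    obj = _penalized_loglik(counts, mu, alpha, beta, lam)
    converged = np.zeros(n, dtype=bool)
    active = ~all_zero & np.isfinite(obj)

    lam_eye = np.diag(lam)
    for _ in range(max_iter):
        if not np.any(active):
            break
        idx = np.flatnonzero(active)
        K_a, mu_a, s_a, al_a = counts[idx], mu[idx], s[idx], alpha[idx]
        w = 1.0 / (1.0 / mu_a + al_a[:, None])
        z = np.log(mu_a / s_a) + (K_a - mu_a) / mu_a
        XtWX = np.einsum("jr,nj,js->nrs", X, w, X, optimize=True)
        XtWz = np.einsum("jr,nj,nj->nr", X, w, z, optimize=True)
        A = XtWX + lam_eye[None, :, :]
        try:
            beta_prop = np.linalg.solve(A, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # fall back to per-gene least squares for singular systems
            beta_prop = np.stack(
                [np.linalg.lstsq(A[i], XtWz[i], rcond=None)[0] for i in range(len(idx))]
            )

        # step-halving: shrink the step toward the current beta until the
        # penalized log-likelihood does not decrease
        beta_cur = beta[idx]
        obj_cur = obj[idx]
        step = np.ones(len(idx))
        beta_new = beta_prop.copy()
        obj_new = np.full(len(idx), -np.inf)
        for _half in range(20):
            trial = beta_cur + step[:, None] * (beta_prop - beta_cur)
            mu_t = np.maximum(s_a * np.exp(np.clip(trial @ X.T, -100, 100)), _MU_FLOOR)
            obj_t = _penalized_loglik(K_a, mu_t, al_a, trial, lam)
            improve = (obj_t >= obj_cur - 1e-12) | ~np.isfinite(obj_cur)
            first = ~np.isfinite(obj_new) | (obj_t > obj_new)
            take = improve & first
            beta_new[take] = trial[take]
            obj_new[take] = obj_t[take]
            need = ~improve
            if not np.any(need):
                break
            step[need] *= 0.5
        bad = ~np.isfinite(obj_new)
        beta_new[bad] = beta_cur[bad]
        obj_new[bad] = obj_cur[bad]

        done = np.abs(obj_new - obj_cur) < tol * (np.abs(obj_cur) + 0.1)
        beta[idx] = beta_new
        obj[idx] = obj_new
        mu[idx] = np.maximum(s_a * np.exp(np.clip(beta_new @ X.T, -100, 100)), _MU_FLOOR)
        converged[idx[done]] = True
        active[idx[done]] = False

    beta[all_zero] = np.nan
    converged[all_zero] = False
    mu[all_zero] = _MU_FLOOR
    return GLMFit(
        beta=beta,
        mu=mu,
        converged=converged,
        loglik=obj,
        design=X,
        alpha=alpha,
        penalty=lam,
    )


def fit_nb_glm(
    counts_row,
    design,
    normalization,
    alpha: float,
    penalty=None,
) -> GLMFit:
    """Single-gene convenience wrapper around :func:`fit_nb_glm_matrix`."""
    counts_row = np.asarray(counts_row, dtype=float)[None, :]
    s = np.asarray(normalization, dtype=float)
    if s.ndim == 1:
        s = s[None, :] if s.shape[0] == counts_row.shape[1] else s
    return fit_nb_glm_matrix(counts_row, design, s, alpha, penalty=penalty)


def xtwx(design: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Stack of per-gene X'WX matrices; weights is (n, m)."""
    return np.einsum("jr,nj,js->nrs", design, weights, design, optimize=True)


def coefficient_covariance(fit: GLMFit) -> np.ndarray:
    """Sandwich covariance of the (possibly ridge-penalized) estimates,

        Sigma = (X'WX + lambda I)^-1 (X'WX) (X'WX + lambda I)^-1,

    reducing to (X'WX)^-1 when lambda = 0.  Returns an (n, p, p) stack
    on the natural-log scale.
    """
    M = xtwx(fit.design, fit.weights())
    p = fit.design.shape[1]
    A = M + np.diag(fit.penalty)[None, :, :]
    if np.all(fit.penalty == 0):
        ranks = np.linalg.matrix_rank(fit.design)
        if ranks < p:
            raise np.linalg.LinAlgError(
                f"design matrix is rank deficient (rank {ranks} < {p} columns); "
                "X'WX is singular with no ridge penalty"
            )
    Ainv = np.linalg.inv(A)
    return Ainv @ M @ Ainv


def contrast(
    fit: GLMFit, cov: np.ndarray, c: np.ndarray, log2_scale: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Linear combination ``c' beta`` and its standard error
    ``sqrt(c' Sigma c)`` for every gene."""
    c = np.asarray(c, dtype=float)
    if c.shape != (fit.beta.shape[1],):
        raise ValueError(
            f"contrast length {c.shape} does not match {fit.beta.shape[1]} coefficients"
        )
    est = fit.beta @ c
    se = np.sqrt(np.einsum("r,nrs,s->n", c, cov, c))
    if log2_scale:
        return est / LN2, se / LN2
    return est, se
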