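"""Empirical-Bayes dispersion estimation.

Dispersions alpha_i (Var K = mu + alpha*mu^2) are estimated in three
steps that approximate a full empirical-Bayes treatment:

1. **gene-wise MLEs** maximizing the Cox-Reid adjusted profile
   likelihood ``l_CR(alpha) = l(alpha) - 0.5*log det(X'WX)``,
   conditioned on fitted means from an initial fit that uses a rough
   method-of-moments dispersion;
2. **a parametric trend** ``alpha_tr(mu) = a1/mu + alpha0`` fit to the
   gene-wise estimates by iterated gamma-family GLM regression with
   outlier exclusion;
3. **MAP estimates** combining the adjusted likelihood with a
   log-normal prior centered on the trend, whose variance sigma_d^2 is
   the spread of the log residuals minus the expected sampling variance
   of a log dispersion estimate (the trigamma term), floored at 0.25.

Genes whose gene-wise estimate lies more than two residual standard
deviations *above* the trend are dispersion outliers: their final value
is the unshrunken gene-wise estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import polygamma

from .glm import fit_nb_glm_matrix, nb_log_likelihood, xtwx

__all__ = [
    "DispersionModel",
    "initial_dispersion_mom",
    "cr_adjusted_loglik",
    "genewise_dispersion_mle",
    "fit_dispersion_trend",
    "estimate_prior_variance",
    "map_dispersion",
    "classify_dispersion_outliers",
    "estimate_dispersions",
]

LOG_ALPHA_MIN = np.log(1e-8)
LOG_ALPHA_MAX = np.log(30.0)
MOM_FLOOR = 1e-8
_MAD_SCALE = 1.0 / stats.norm.ppf(0.75)


@dataclass
class DispersionModel:
    genewise: np.ndarray
    trend_a1: float
    trend_alpha0: float
    trend_values: np.ndarray
    prior_var: float  # sigma_d^2
    residual_sd: float  # s_lr
    map: np.ndarray
    final: np.ndarray
    outlier_flags: np.ndarray
    m: int
    p: int
    mu0: np.ndarray  # fitted means conditioning both likelihood stages

    def trend(self, mean_counts) -> np.ndarray:
        return self.trend_a1 / np.maximum(np.asarray(mean_counts, float), 1e-300) + self.trend_alpha0


# ----------------------------------------------------------------------
# method-of-moments initialization


def _group_codes(design: np.ndarray) -> np.ndarray:
    _, codes = np.unique(design, axis=0, return_inverse=True)
    return codes


def initial_dispersion_mom(counts, design, normalization) -> np.ndarray:
    """Rough method-of-moments dispersion from within-group variances
    and means of normalized counts: the largest over groups of
    ``(var - mean)/mean^2``, floored at a small positive value."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    s = np.asarray(normalization, dtype=float)
    if s.ndim == 1:
        s = np.broadcast_to(s, counts.shape)
    q = counts / s
    codes = _group_codes(np.asarray(design))
    est = np.full(counts.shape[0], MOM_FLOOR)
    for g in np.unique(codes):
        cols = codes == g
        if cols.sum() < 2:
            continue
        mean = q[:, cols].mean(axis=1)
        var = q[:, cols].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mean > 0, (var - mean) / mean**2, MOM_FLOOR)
        est = np.maximum(est, np.nan_to_num(a, nan=MOM_FLOOR))
    return np.clip(est, MOM_FLOOR, np.exp(LOG_ALPHA_MAX))


# ----------------------------------------------------------------------
# Cox-Reid adjusted likelihood and its vectorized maximization


def cr_adjusted_loglik(alpha, counts, mu0, design) -> np.ndarray:
    """Cox-Reid adjusted NB log-likelihood of the dispersion,
    ``l(alpha) - 0.5 log det(X'WX)``, vectorized over genes.

    ``alpha`` may be scalar or per-gene; ``counts`` and ``mu0`` are
    (n, m); ``design`` is (m, p).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    mu0 = np.atleast_2d(np.asarray(mu0, dtype=float))
    n = counts.shape[0]
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (n,))
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    ll = nb_log_likelihood(counts, mu0, alpha)
    w = 1.0 / (1.0 / mu0 + alpha[:, None])
    sign, logdet = np.linalg.slogdet(xtwx(np.asarray(design, float), w))
    return ll - 0.5 * logdet


def _maximize_log_alpha(objective, n: int, n_coarse: int = 40, iters: int = 40):
    """Vectorized maximizer over log alpha in [LOG_ALPHA_MIN, LOG_ALPHA_MAX].

    ``objective(alpha_vector) -> (n,)``.  A coarse grid brackets the
    maximum per gene, then golden-section search refines it.  Returns
    (alpha_hat, at_bound_flags).
    """
    grid = np.linspace(LOG_ALPHA_MIN, LOG_ALPHA_MAX, n_coarse)
    vals = np.empty((n_coarse, n))
    for i, g in enumerate(grid):
        vals[i] = objective(np.full(n, np.exp(g)))
    best = np.nanargmax(vals, axis=0)
    lo = grid[np.clip(best - 1, 0, n_coarse - 1)]
    hi = grid[np.clip(best + 1, 0, n_coarse - 1)]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.copy(), hi.copy()
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1 = objective(np.exp(x1))
    f2 = objective(np.exp(x2))
    for _ in range(iters):
        left = f1 >= f2  # maximum in [a, x2]
        b = np.where(left, x2, b)
        a = np.where(left, a, x1)
        x1n = b - invphi * (b - a)
        x2n = a + invphi * (b - a)
        # one new evaluation would suffice per gene; evaluating both keeps
        # the bookkeeping simple and is still a single vectorized call
        x1, x2 = x1n, x2n
        f1 = objective(np.exp(x1))
        f2 = objective(np.exp(x2))
    log_alpha = 0.5 * (a + b)
    log_alpha = np.clip(log_alpha, LOG_ALPHA_MIN, LOG_ALPHA_MAX)
    at_bound = (best == 0) | (best == n_coarse - 1)
    return np.exp(log_alpha), at_bound


def genewise_dispersion_mle(
    counts, design, normalization, mu0=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gene-wise Cox-Reid adjusted dispersion MLEs.

    Fits an initial GLM at the method-of-moments dispersion to obtain
    fitted means ``mu0`` (unless given), then maximizes the adjusted
    likelihood over log alpha.  Returns (alpha_gw, at_bound, mu0).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n = counts.shape[0]
    X = np.asarray(design, dtype=float)
    if mu0 is None:
        alpha_init = initial_dispersion_mom(counts, X, normalization)
        fit0 = fit_nb_glm_matrix(counts, X, normalization, np.maximum(alpha_init, 1e-6))
        mu0 = fit0.mu

    def obj(alpha_vec):
        return cr_adjusted_loglik(alpha_vec, counts, mu0, X)

    alpha_gw, at_bound = _maximize_log_alpha(obj, n)
    return alpha_gw, at_bound, mu0


# ----------------------------------------------------------------------
# parametric trend


def fit_dispersion_trend(
    genewise: np.ndarray, mean_counts: np.ndarray, max_outer: int = 10
) -> tuple[float, float, np.ndarray]:
    """Fit ``alpha_tr(mu) = a1/mu + alpha0`` by iterated gamma-family
    GLM regression of the gene-wise estimates on (1/mu, 1).

    At each iteration genes whose ratio of estimate to fitted value is
    outside [1e-4, 15] are excluded; iteration stops when the summed
    squared log-ratio of new to old coefficients falls below 1e-6.
    Falls back to a flat median trend (with a warning) when the fit
    cannot be obtained.
    """
    import statsmodels.api as sm

    genewise = np.asarray(genewise, dtype=float)
    mean_counts = np.asarray(mean_counts, dtype=float)
    usable = np.isfinite(genewise) & (genewise > 0) & (mean_counts > 0)
    y_all = genewise[usable]
    x_all = mean_counts[usable]

    def _fallback(msg):
        warnings.warn(f"dispersion trend fit failed ({msg}); using a flat median trend")
        alpha0 = float(np.median(y_all)) if y_all.size else 0.1
        a1 = 0.0
        tv = np.full_like(mean_counts, alpha0, dtype=float)
        return a1, alpha0, tv

    if y_all.size < 2 or np.unique(x_all).size < 2:
        return _fallback("fewer than two usable genes with distinct means")

    keep = np.ones(y_all.size, dtype=bool)
    coef = None
    for _ in range(max_outer):
        y = y_all[keep]
        Xg = np.column_stack([1.0 / x_all[keep], np.ones(keep.sum())])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(
                    y, Xg, family=sm.families.Gamma(link=sm.families.links.Identity())
                )
                start = coef if coef is not None else np.array(
                    [np.maximum(np.median(y * x_all[keep]), 1e-6), np.maximum(np.median(y) / 2, 1e-6)]
                )
                res = model.fit(start_params=start, maxiter=100)
            new = np.asarray(res.params, dtype=float)
        except Exception as exc:  # statsmodels may fail on degenerate input
            return _fallback(str(exc))
        if not np.all(np.isfinite(new)) or new[1] <= 0 or new[0] < 0:
            new = np.array([max(new[0], 0.0), max(new[1], 1e-8)])
            if not np.all(np.isfinite(new)):
                return _fallback("non-finite coefficients")
        fitted_all = new[0] / x_all + new[1]
        ratio = y_all / fitted_all
        keep = (ratio >= 1e-4) & (ratio <= 15.0)
        if coef is not None:
            change = np.sum(np.log(np.maximum(new, 1e-300) / np.maximum(coef, 1e-300)) ** 2)
            coef = new
            if change < 1e-6:
                break
        else:
            coef = new
    a1, alpha0 = float(coef[0]), float(coef[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        trend_values = np.where(mean_counts > 0, a1 / mean_counts + alpha0, np.nan)
    return a1, alpha0, trend_values


# ----------------------------------------------------------------------
# prior width


def estimate_prior_variance(
    genewise: np.ndarray,
    trend_values: np.ndarray,
    m: int,
    p: int,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Width of the log-normal dispersion prior.

    ``s_lr`` is the MAD (scaled for normal consistency) of the log
    residuals ``log alpha_gw - log alpha_tr``.  The sampling variance of
    a log dispersion estimate is approximately ``psi_1((m-p)/2)``
    (trigamma), so ``sigma_d^2 = max(s_lr^2 - psi_1((m-p)/2), 0.25)``.

    With three or fewer residual degrees of freedom the subtraction is
    unreliable; sigma_d^2 is instead chosen on a grid by matching the
    simulated density of log residuals (log chi^2_{m-p} shifted by
    -log(m-p), plus N(0, sigma_d^2)) to the observed density by minimum
    Kullback-Leibler divergence.

    Returns (sigma_d^2, s_lr).
    """
    genewise = np.asarray(genewise, dtype=float)
    trend_values = np.asarray(trend_values, dtype=float)
    ok = np.isfinite(genewise) & np.isfinite(trend_values) & (genewise > 0) & (trend_values > 0)
    logres = np.log(genewise[ok]) - np.log(trend_values[ok])
    if logres.size == 0:
        return 0.25, 0.0
    s_lr = float(np.median(np.abs(logres - np.median(logres))) * _MAD_SCALE)
    df = m - p
    if df <= 0:
        raise ValueError("need at least one residual degree of freedom")
    if df <= 3:
        return _prior_var_by_kl_matching(logres, df, rng_seed), s_lr
    sigma_lde2 = float(polygamma(1, df / 2.0))
    sigma_d2 = max(s_lr**2 - sigma_lde2, 0.25)
    return sigma_d2, s_lr


def _prior_var_by_kl_matching(
    logres: np.ndarray, df: int, rng_seed: int = 0, n_sim: int = 100_000, n_bins: int = 500
) -> float:
    grid = 0.25 * 1.25 ** np.arange(25)
    rng = np.random.default_rng(rng_seed)
    chi = np.log(rng.chisquare(df, size=n_sim)) - np.log(df)
    normal = rng.standard_normal(n_sim)
    lo = min(logres.min(), chi.min() - 3 * np.sqrt(grid[-1]))
    hi = max(logres.max(), chi.max() + 3 * np.sqrt(grid[-1]))
    edges = np.linspace(lo, hi, n_bins + 1)
    obs, _ = np.histogram(logres, bins=edges, density=False)
    p_obs = (obs + 0.5) / (obs + 0.5).sum()
    best, best_kl = grid[0], np.inf
    for sd2 in grid:
        sim = chi + np.sqrt(sd2) * normal
        simh, _ = np.histogram(sim, bins=edges)
        q = (simh + 0.5) / (simh + 0.5).sum()
        kl = float(np.sum(p_obs * np.log(p_obs / q)))
        if kl < best_kl:
            best_kl, best = kl, sd2
    return float(best)


# ----------------------------------------------------------------------
# MAP and outliers


def map_dispersion(
    counts, mu0, design, trend_values, prior_var: float
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-mode dispersions: maximize ``l_CR(alpha) -
    (log alpha - log alpha_tr)^2 / (2 sigma_d^2)`` over log alpha."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    mu0 = np.atleast_2d(np.asarray(mu0, dtype=float))
    n = counts.shape[0]
    log_trend = np.log(np.broadcast_to(np.asarray(trend_values, float), (n,)))
    X = np.asarray(design, dtype=float)

    def obj(alpha_vec):
        prior = -((np.log(alpha_vec) - log_trend) ** 2) / (2.0 * prior_var)
        return cr_adjusted_loglik(alpha_vec, counts, mu0, X) + prior

    return _maximize_log_alpha(obj, n)


def classify_dispersion_outliers(
    genewise: np.ndarray, trend_values: np.ndarray, s_lr: float
) -> np.ndarray:
    """One-sided outlier rule: ``log alpha_gw > log alpha_tr + 2 s_lr``.
    Genes far *below* the trend are not outliers (they are shrunk up)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log(genewise) > np.log(trend_values) + 2.0 * s_lr


# ----------------------------------------------------------------------
# orchestration


def estimate_dispersions(
    counts, design, normalization, min_positive: int = 2
) -> DispersionModel:
    """Run the full three-step dispersion procedure on a count matrix.

    Genes with zero mean or fewer than ``min_positive`` positive counts
    are excluded from trend and prior fitting (their MAP values are
    still computed from the shared trend/prior).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    X = np.asarray(design, dtype=float)
    n, m = counts.shape
    p = int(np.linalg.matrix_rank(X))
    s = np.asarray(normalization, dtype=float)
    s_mat = np.broadcast_to(s, counts.shape) if s.ndim == 1 else s
    bar_mu = (counts / s_mat).mean(axis=1)

    alpha_gw, at_bound, mu0 = genewise_dispersion_mle(counts, X, normalization)
    informative = (bar_mu > 0) & ((counts > 0).sum(axis=1) >= min_positive) & ~at_bound

    a1, alpha0, trend_values = fit_dispersion_trend(
        np.where(informative, alpha_gw, np.nan), bar_mu
    )
    trend_values = np.where(bar_mu > 0, a1 / np.maximum(bar_mu, 1e-300) + alpha0, np.nan)

    prior_var, s_lr = estimate_prior_variance(
        alpha_gw[informative], trend_values[informative], m, p
    )

    nonzero = bar_mu > 0
    alpha_map = np.full(n, np.nan)
    if np.any(nonzero):
        alpha_map[nonzero], _ = map_dispersion(
            counts[nonzero], mu0[nonzero], X, trend_values[nonzero], prior_var
        )

    flags = np.zeros(n, dtype=bool)
    flags[nonzero] = classify_dispersion_outliers(
        alpha_gw[nonzero], trend_values[nonzero], s_lr
    )
    final = np.where(flags, alpha_gw, alpha_map)
    return DispersionModel(
        genewise=alpha_gw,
        trend_a1=a1,
        trend_alpha0=alpha0,
        trend_values=trend_values,
        prior_var=prior_var,
        residual_sd=s_lr,
        map=alpha_map,
        final=final,
        outlier_flags=flags,
        m=m,
        p=p,
        mu0=mu0,
    )
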