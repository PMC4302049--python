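"""Synthetic negative-binomial benchmark data and performance metrics.

The generator emulates a two-group RNA-seq comparison: per-gene means
are drawn from a wide log-normal, dispersions scatter log-normally
around a decreasing mean-dispersion trend ``a1/mu + alpha0`` (shot-noise
rise at low means, asymptote at high means), 80% of genes are null and
20% carry true fold changes of 2, 3 or 4 with random direction, split
symmetrically between the groups (sqrt(fc) up in one group, down in the
other).  Counts are NB(mu, alpha) draws.

Performance of a differential-expression call set is summarized as
sensitivity (fraction of true DE genes with padj < 0.1), precision
(fraction of true DE genes among the called ones), FDR = 1 - precision,
and the false positive rate at raw p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CountDataset

__all__ = [
    "SimulatedDataset",
    "PerformanceReport",
    "sample_mean_dispersion_pairs",
    "simulate_dataset",
    "evaluate_performance",
]

# generator defaults: log-normal means (natural-log mean 4, sd 2, floored
# at 0.5) and a dispersion trend with asymptote 0.05 and slope 3, with
# log-normal scatter of sd 0.5 around it
MEAN_LOG_MU = 4.0
MEAN_LOG_SD = 2.0
MEAN_FLOOR = 0.5
TREND_A1 = 3.0
TREND_ALPHA0 = 0.05
DISP_LOG_SD = 0.5
DEFAULT_FOLD_CHANGES = (2.0, 3.0, 4.0)


@dataclass
class SimulatedDataset:
    dataset: CountDataset
    is_de: np.ndarray  # (n,) bool truth labels
    true_lfc: np.ndarray  # (n,) signed log2 fold changes
    true_mean: np.ndarray
    true_dispersion: np.ndarray
    seed: int


@dataclass
class PerformanceReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    precision: float
    fdr: float
    fpr_at_001: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "fdr": self.fdr,
            "fpr_at_001": self.fpr_at_001,
        }


def sample_mean_dispersion_pairs(
    n_genes: int,
    seed: int,
    mean_log_mu: float = MEAN_LOG_MU,
    mean_log_sd: float = MEAN_LOG_SD,
    trend_a1: float = TREND_A1,
    trend_alpha0: float = TREND_ALPHA0,
    disp_log_sd: float = DISP_LOG_SD,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (mean, dispersion) pairs from the parametric joint model."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if mean_log_sd < 0 or disp_log_sd < 0 or trend_alpha0 <= 0 or trend_a1 < 0:
        raise ValueError("invalid generator parameters")
    rng = np.random.default_rng(seed)
    means = np.maximum(rng.lognormal(mean_log_mu, mean_log_sd, size=n_genes), MEAN_FLOOR)
    trend = trend_a1 / means + trend_alpha0
    dispersions = trend * rng.lognormal(0.0, disp_log_sd, size=n_genes) if disp_log_sd > 0 else trend
    return means, dispersions


def simulate_dataset(
    n_genes: int = 10_000,
    m: int = 6,
    de_fraction: float = 0.2,
    fold_changes=DEFAULT_FOLD_CHANGES,
    seed: int = 0,
    **generator_params,
) -> SimulatedDataset:
    """Simulate a balanced two-group NB dataset with known truth.

    DE genes are chosen uniformly at random; each gets one of the fold
    changes with random sign, applied as sqrt(fc) up in one group and
    sqrt(fc) down in the other so the group-mean ratio equals fc.
    """
    if m < 4 or m % 2 != 0:
        raise ValueError("m must be an even number of samples, at least 4")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    means, dispersions = sample_mean_dispersion_pairs(
        n_genes, seed=rng.integers(2**31 - 1), **generator_params
    )
    fold_changes = np.asarray(list(fold_changes), dtype=float)

    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True
    fc = np.ones(n_genes)
    if n_de:
        fc[de_idx] = rng.choice(fold_changes, size=n_de)
    sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    true_lfc = np.where(is_de, sign * np.log2(fc), 0.0)

    half = m // 2
    ratio = 2.0 ** (true_lfc / 2.0)  # sqrt(fc) with sign
    mu_a = means / ratio
    mu_b = means * ratio
    mu = np.concatenate(
        [np.repeat(mu_a[:, None], half, axis=1), np.repeat(mu_b[:, None], half, axis=1)],
        axis=1,
    )
    r = 1.0 / dispersions[:, None]
    counts = rng.negative_binomial(r, r / (r + mu))

    sample_info = pd.DataFrame(
        {"condition": ["A"] * half + ["B"] * half},
        index=[f"sample{j+1}" for j in range(m)],
    )
    ds = CountDataset(counts, sample_info)
    return SimulatedDataset(
        dataset=ds,
        is_de=is_de,
        true_lfc=true_lfc,
        true_mean=means,
        true_dispersion=dispersions,
        seed=seed,
    )


def evaluate_performance(
    padj, is_de, pvalues=None, alpha_adj: float = 0.1
) -> PerformanceReport:
    """Confusion counts and rates at the padj < ``alpha_adj`` call level.

    Genes with missing padj count as not called.  Precision (and FDR)
    are NaN when nothing is called.  The FPR is the fraction of raw p
    values below 0.01 among non-missing ones (NaN if none supplied).
    """
    padj = np.asarray(padj, dtype=float)
    is_de = np.asarray(is_de, dtype=bool)
    if padj.shape != is_de.shape:
        raise ValueError("padj and truth labels must have the same length")
    called = np.nan_to_num(padj, nan=np.inf) < alpha_adj
    tp = int(np.sum(called & is_de))
    fp = int(np.sum(called & ~is_de))
    fn = int(np.sum(~called & is_de))
    tn = int(np.sum(~called & ~is_de))
    sensitivity = tp / (tp + fn) if (tp + fn) else np.nan
    precision = tp / (tp + fp) if (tp + fp) else np.nan
    fdr = 1.0 - precision if np.isfinite(precision) else np.nan
    if pvalues is not None:
        p = np.asarray(pvalues, dtype=float)
        ok = np.isfinite(p)
        fpr = float(np.mean(p[ok] < 0.01)) if ok.any() else np.nan
    else:
        fpr = np.nan
    return PerformanceReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sensitivity, precision=precision, fdr=fdr, fpr_at_001=fpr,
    )
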