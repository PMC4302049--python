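"""Core count-data containers and size-factor normalization.

The starting point of an analysis is a matrix of non-negative integer
counts ``K`` with one row per gene and one column per sample, together
with per-sample metadata (factor assignments and numeric covariates).
Counts are modelled as negative binomial with mean ``mu_ij = s_ij *
q_ij``: the normalization constants ``s_ij`` absorb technical effects
such as sequencing depth.  By default a single size factor ``s_j`` per
sample is estimated with the median-of-ratios method; alternatively a
full gene-by-sample normalization matrix may be supplied.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountDataset",
    "estimate_size_factors",
    "normalized_counts",
    "mean_normalized_counts",
]


class CountDataset:
    """Counts, sample metadata and normalization factors.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes as rows, samples as columns.
    sample_info
        DataFrame with one row per sample; columns are factors
        (categorical) or numeric covariates.
    gene_ids
        Row labels; generated as ``gene1..geneN`` when omitted.
    """

    def __init__(
        self,
        counts,
        sample_info: pd.DataFrame | None = None,
        gene_ids: Sequence[str] | None = None,
    ):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (genes x samples)")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        self.counts = counts.astype(np.int64)
        n, m = counts.shape
        if sample_info is None:
            sample_info = pd.DataFrame(index=[f"sample{j+1}" for j in range(m)])
        if len(sample_info) != m:
            raise ValueError(
                f"sample_info has {len(sample_info)} rows but counts has {m} columns"
            )
        self.sample_info = sample_info
        if gene_ids is None:
            gene_ids = [f"gene{i+1}" for i in range(n)]
        if len(gene_ids) != n:
            raise ValueError("gene_ids length must equal the number of genes")
        self.gene_ids = list(gene_ids)
        # per-sample vector s_j or full matrix s_ij, set by the user or
        # by estimate_size_factors
        self._normalization: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def normalization(self) -> np.ndarray:
        if self._normalization is None:
            raise ValueError(
                "normalization factors are not set; call estimate_size_factors "
                "or assign size_factors / normalization_matrix"
            )
        return self._normalization

    @property
    def has_normalization(self) -> bool:
        return self._normalization is not None

    def set_size_factors(self, s: np.ndarray) -> None:
        s = np.asarray(s, dtype=float)
        if s.shape == (self.n_samples,):
            pass
        elif s.shape == self.counts.shape:
            pass
        else:
            raise ValueError(
                "normalization must be per-sample (m,) or a full (n, m) matrix"
            )
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise ValueError("normalization factors must be strictly positive")
        self._normalization = s

    def normalization_matrix(self) -> np.ndarray:
        """Normalization broadcast to the full (genes x samples) shape."""
        s = self.normalization
        if s.ndim == 1:
            return np.broadcast_to(s, self.counts.shape)
        return s

    def zero_genes(self) -> np.ndarray:
        """Boolean mask of genes whose counts are zero in every sample."""
        return self.counts.sum(axis=1) == 0

    def copy(self) -> "CountDataset":
        ds = CountDataset(
            self.counts.copy(), self.sample_info.copy(), list(self.gene_ids)
        )
        if self._normalization is not None:
            ds._normalization = self._normalization.copy()
        return ds


def estimate_size_factors(dataset: CountDataset) -> np.ndarray:
    """Median-of-ratios size factors.

    ``s_j = median_{i: K^R_i != 0} K_ij / K^R_i`` where ``K^R_i`` is the
    geometric mean of gene *i* across samples.  Genes with any zero
    count have ``K^R_i = 0`` and are excluded from the median.

    The estimated factors are stored on the dataset and returned.
    """
    K = dataset.counts
    with np.errstate(divide="ignore"):
        logK = np.log(K.astype(float))
    log_geomean = logK.mean(axis=1)  # -inf for genes with any zero
    usable = np.isfinite(log_geomean)
    if not np.any(usable):
        raise ValueError(
            "no reference genes: every gene has at least one zero count, "
            "so median-of-ratios size factors cannot be estimated"
        )
    log_ratios = logK[usable] - log_geomean[usable, None]
    s = np.exp(np.median(log_ratios, axis=0))
    dataset.set_size_factors(s)
    return s


def normalized_counts(dataset: CountDataset) -> np.ndarray:
    """Counts divided elementwise by the normalization factors."""
    return dataset.counts / dataset.normalization_matrix()


def mean_normalized_counts(dataset: CountDataset) -> np.ndarray:
    """Per-gene arithmetic mean of normalized counts (the expression
    strength used throughout as the filter and trend covariate)."""
    return normalized_counts(dataset).mean(axis=1)
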