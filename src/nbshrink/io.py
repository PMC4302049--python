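"""Reading count matrices / sample metadata and writing result tables.

Counts are accepted as delimited text (TSV or CSV; genes as rows with a
leading ID column, samples as columns) or as MatrixMarket coordinate
triplets with separate row- and column-label files.  Results are
written as TSV with missing values rendered as ``NA``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import CountDataset

__all__ = ["read_counts", "read_sample_info", "write_results", "write_counts"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(
    path,
    sample_info: pd.DataFrame | None = None,
    row_labels=None,
    col_labels=None,
) -> CountDataset:
    """Read a count matrix into a :class:`CountDataset`.

    ``path`` may be TSV/CSV (gene IDs in the first column) or a
    MatrixMarket ``.mtx`` file, in which case ``row_labels`` and
    ``col_labels`` are paths to one-label-per-line text files.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmread

        mat = mmread(str(path))
        if hasattr(mat, "todense"):
            mat = mat.todense()
        mat = np.asarray(mat)
        genes = None
        samples = None
        if row_labels is not None:
            genes = Path(row_labels).read_text().split()
        if col_labels is not None:
            samples = Path(col_labels).read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    values = df.to_numpy()
    if not np.allclose(values, np.round(values)):
        bad = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ValueError(
            f"non-integer count at row {df.index[bad[0]]!r}, column "
            f"{df.columns[bad[1]]!r}: {values[tuple(bad)]!r}"
        )
    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at row {df.index[bad[0]]!r}, column {df.columns[bad[1]]!r}"
        )
    if sample_info is not None and list(sample_info.index) != list(df.columns):
        sample_info = sample_info.loc[df.columns]
    return CountDataset(
        values.astype(np.int64), sample_info, gene_ids=list(df.index.astype(str))
    )


def read_sample_info(path) -> pd.DataFrame:
    """Sample metadata: one row per sample, first column = sample ID."""
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)


def write_counts(dataset: CountDataset, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        dataset.counts,
        index=pd.Index(dataset.gene_ids, name="gene"),
        columns=dataset.sample_info.index,
    )
    df.to_csv(path, sep=_sep_for(path))


def write_results(results: pd.DataFrame, path) -> None:
    """Write the result table as TSV with NA for missing values."""
    results.to_csv(Path(path), sep="\t", na_rep="NA")
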