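"""Per-cell CNV score from inferCNV-style residual matrices.

Consumes a genes × cells matrix of residual expression (the scaled output
of an inferCNV-like caller; the HMM itself is upstream and out of scope).
Each cell's values are min-max rescaled to [−1, 1]:

    y = 2 * (x − min_c) / (max_c − min_c) − 1

with min/max taken per cell, and the CNV score is the mean of y² over
genes — a value in [0, 1] where larger means stronger copy-number
deviation.  Cells with constant input (zero range) carry no signal; they
score 0 and are flagged degenerate rather than erroring, so batches run
through.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_cnv_matrix",
    "rescale_per_cell",
    "cnv_scores",
    "degenerate_cells",
]


def read_cnv_matrix(
    path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> pd.DataFrame:
    """Load a genes × cells matrix from dense TSV or MatrixMarket + id files.

    The TSV layout is the inferCNV convention: gene ids in the first
    column, one column per cell.  For ``.mtx`` input, supply one-id-per-line
    gene and cell files.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        if genes_path is None or cells_path is None:
            raise ValueError("MTX input requires genes_path and cells_path")
        mat = mmread(path)
        if hasattr(mat, "toarray"):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        genes = [line.strip() for line in open(genes_path) if line.strip()]
        cells = [line.strip() for line in open(cells_path) if line.strip()]
        df = pd.DataFrame(mat, index=genes, columns=cells)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate gene or cell ids in CNV matrix")
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        raise ValueError("non-finite entries in CNV matrix")
    return df


def degenerate_cells(matrix: pd.DataFrame) -> pd.Series:
    """Cells whose values are constant across genes (zero range)."""
    vals = matrix.to_numpy(dtype=float)
    flags = vals.max(axis=0) == vals.min(axis=0)
    return pd.Series(flags, index=matrix.columns, name="degenerate_flag")


def rescale_per_cell(matrix: pd.DataFrame, standardize_first: bool = False) -> pd.DataFrame:
    """Min-max rescale each cell (column) to [−1, 1].

    For a cell with values x: y = 2·(x − min)/(max − min) − 1, so every
    non-constant cell attains exactly −1 and +1.  Constant cells map to all
    zeros with a warning (guarded division).  ``standardize_first``
    optionally z-scores each cell across genes before rescaling; off by
    default since min-max rescaling is affine-invariant per cell and the
    score is unchanged for non-constant cells.
    """
    vals = matrix.to_numpy(dtype=float)
    if standardize_first:
        mu = vals.mean(axis=0, keepdims=True)
        sd = vals.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        vals = (vals - mu) / sd
    lo = vals.min(axis=0, keepdims=True)
    hi = vals.max(axis=0, keepdims=True)
    rng = hi - lo
    constant = rng[0] == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant cells rescaled to all zeros",
            stacklevel=2,
        )
    safe_rng = np.where(rng == 0, 1.0, rng)
    out = 2.0 * (vals - lo) / safe_rng - 1.0
    out[:, constant] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def cnv_scores(rescaled: pd.DataFrame) -> pd.DataFrame:
    """Per-cell CNV score: mean over genes of the squared rescaled values.

    Returns a table with columns ``score`` (in [0, 1]) and
    ``degenerate_flag`` (constant cells, which score exactly 0).
    """
    vals = rescaled.to_numpy(dtype=float)
    if vals.min() < -1 - 1e-9 or vals.max() > 1 + 1e-9:
        raise ValueError("input must be per-cell rescaled to [-1, 1]")
    scores = np.mean(vals**2, axis=0)
    flags = (vals.max(axis=0) == 0) & (vals.min(axis=0) == 0)
    return pd.DataFrame(
        {"score": scores, "degenerate_flag": flags},
        index=pd.Index(rescaled.columns, name="cell"),
    )
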