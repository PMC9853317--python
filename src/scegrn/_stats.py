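"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def lognorm_cp10k(counts: sp.spmatrix | np.ndarray) -> np.ndarray:
    """Depth-normalize to counts-per-10k and log1p; returns dense features x cells."""
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts, float)
    totals = dense.sum(axis=0)
    totals[totals == 0] = 1.0
    return np.log1p(dense / totals * 1e4)


def standardize_rows(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance rows (population sd); constant rows become NaN."""
    x = np.asarray(x, float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd > 0, (x - mu) / sd, np.nan)


def pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between paired rows of x and y.

    Rows with zero variance yield NaN rather than raising.
    """
    zx = standardize_rows(np.atleast_2d(x))
    zy = standardize_rows(np.atleast_2d(y))
    return (zx * zy).mean(axis=1)


def pearson_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlation: rows of x against rows of y.

    Returns an (n_x, n_y) matrix; pairs involving a constant profile are NaN.
    """
    zx = standardize_rows(np.atleast_2d(x))
    zy = standardize_rows(np.atleast_2d(y))
    n = zx.shape[1]
    return zx @ zy.T / n
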