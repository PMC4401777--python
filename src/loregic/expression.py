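"""Expression-matrix preparation and Boolean conversion.

Gates operate on binary gene states (1 = on / high expression, 0 = off /
low), so continuous expression must first be binarized.  Each gene is
binarized independently across samples by an *exact* one-dimensional
two-means partition: among all splits of the sorted sample values into a low
and a high group, the one minimizing the within-cluster sum of squares is
chosen, and samples in the higher-mean group become 1.  Solving the 1-D
problem exactly (a scan over the n-1 sorted split points) removes the
initialization nondeterminism of generic k-means.

Matrices are pandas DataFrames with genes as the index and samples as
columns; missing values are NaN and propagate through binarization.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "load_expression",
    "preprocess",
    "binarize_two_cluster",
    "binarize_series",
    "validate_binary",
]

logger = logging.getLogger(__name__)


def load_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene id, header of samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in header")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return df.astype(float)


def preprocess(matrix: pd.DataFrame, mode: str = "none") -> pd.DataFrame:
    """Normalize a continuous expression matrix before binarization.

    Modes
    -----
    ``log1p_standardize``
        Per-sample z-score of log(x + 1) across genes (for RPKM-like,
        non-negative abundance values).
    ``center_per_sample``
        Subtract each sample's mean across genes (for time-course data
        already on a log scale).
    ``none``
        Identity.
    """
    if mode == "none":
        return matrix
    if mode == "log1p_standardize":
        if (matrix < 0).any().any():
            raise ValueError("log1p_standardize requires non-negative values")
        logged = np.log1p(matrix)
        return (logged - logged.mean(axis=0)) / logged.std(axis=0, ddof=0)
    if mode == "center_per_sample":
        return matrix - matrix.mean(axis=0)
    raise ValueError(f"unknown preprocess mode: {mode!r}")


def binarize_series(values: np.ndarray) -> np.ndarray:
    """Exact 2-means binarization of one gene's sample vector.

    NaNs are preserved; constant (zero-spread) vectors come back all zero.
    Returns a float array over {0.0, 1.0, NaN}.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    mask = ~np.isnan(values)
    obs = values[mask]
    if obs.size == 0:
        return out
    if obs.max() == obs.min():
        out[mask] = 0.0
        return out
    order = np.argsort(obs, kind="stable")
    v = obs[order]
    n = v.size
    # within-cluster SS for split after position k (left = v[:k+1]):
    # SS(seg) = sum(x^2) - (sum x)^2 / len; scan all n-1 splits via prefix sums
    csum = np.cumsum(v)
    csq = np.cumsum(v * v)
    k = np.arange(1, n)  # left segment sizes
    left_ss = csq[:-1] - csum[:-1] ** 2 / k
    rsum = csum[-1] - csum[:-1]
    rsq = csq[-1] - csq[:-1]
    right_ss = rsq - rsum**2 / (n - k)
    split = int(np.argmin(left_ss + right_ss)) + 1  # first minimal split
    labels = np.zeros(n)
    labels[order[split:]] = 1.0  # higher-mean cluster -> 1
    out[mask] = labels
    return out


def binarize_two_cluster(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Binarize every gene of a continuous matrix independently.

    Returns the binary matrix (values 0/1/NaN) and the list of
    "uninformative" genes — those with zero spread across observed samples,
    coded all-0 and meant to be excluded from triplet scoring.
    """
    if matrix.shape[1] < 2:
        raise ValueError("binarization needs at least 2 samples")
    binary = pd.DataFrame(
        np.vstack([binarize_series(row) for row in matrix.to_numpy()]),
        index=matrix.index,
        columns=matrix.columns,
    )
    obs_max = matrix.max(axis=1)
    obs_min = matrix.min(axis=1)
    uninformative = list(matrix.index[(obs_max == obs_min) | obs_max.isna()])
    if uninformative:
        logger.warning(
            "%d constant/empty genes coded all-0 and flagged uninformative",
            len(uninformative),
        )
    return binary, uninformative


def validate_binary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a user-supplied matrix contains only 0, 1 and missing values."""
    values = matrix.to_numpy(dtype=float)
    ok = np.isnan(values) | (values == 0) | (values == 1)
    if not ok.all():
        bad = np.argwhere(~ok)[0]
        raise ValueError(
            "binary matrix contains a non-binary value at gene "
            f"{matrix.index[bad[0]]!r}, sample {matrix.columns[bad[1]]!r}: "
            f"{values[bad[0], bad[1]]!r}"
        )
    return matrix.astype(float)
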