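"""Standardization and principal component analysis of index matrices.

Indices are z-scored so each contributes equally, then the sample
covariance of the standardized matrix is eigendecomposed (equivalent to
correlation-matrix PCA).  Loadings follow a deterministic sign
convention: the largest-magnitude entry of each component is positive.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("ecostatus")


@dataclass
class PCAResult:
    component_loadings: pd.DataFrame  # indices x components
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # fractions, sum to 1


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (ddof=1); constant columns are dropped with a
    warning, rows with any non-finite value are dropped with a log."""
    df = matrix.copy().astype(float)
    incomplete = df.index[~np.isfinite(df.to_numpy()).all(axis=1)]
    if len(incomplete):
        logger.warning(
            "dropping %d sample(s) with undefined index values: %s",
            len(incomplete),
            list(incomplete),
        )
        df = df.drop(index=incomplete)
    sd = df.std(ddof=1)
    constant = sd.index[(sd == 0) | ~np.isfinite(sd)]
    if len(constant):
        logger.warning("dropping constant column(s): %s", list(constant))
        df = df.drop(columns=constant)
        sd = sd.drop(index=constant)
    return (df - df.mean()) / sd


def pca(matrix: pd.DataFrame) -> PCAResult:
    """PCA by eigendecomposition of the sample covariance matrix.

    Expects a standardized samples x indices matrix with n >= 3 rows.
    Components are ordered by decreasing variance; variance_explained
    holds the fraction of total variance per component.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 samples")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(eigvec.shape[1]):
        k = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[k, j] < 0:
            eigvec[:, j] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(p)]
    loadings = pd.DataFrame(eigvec, index=matrix.columns, columns=comp_names)
    scores = pd.DataFrame(Xc @ eigvec, index=matrix.index, columns=comp_names)
    total = eigval.sum()
    frac = eigval / total if total > 0 else np.full(p, np.nan)
    return PCAResult(component_loadings=loadings, scores=scores, variance_explained=frac)
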