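"""Correlation and PCA utilities for descriptor tables.

PCA operates on the correlation matrix of the (z-scored) variables —
descriptor units are incommensurable, so covariance-based components
would be dominated by the largest-scaled columns.  Eigenvector signs are
fixed so the largest-magnitude loading of each component is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .som import _as_frame

__all__ = [
    "PCAResult",
    "pearson_cc",
    "correlation_matrix",
    "high_cc_pairs",
    "pca_loadings",
]


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables x components, unit-norm columns
    explained_variance_ratio: np.ndarray  # non-increasing fractions
    scores: pd.DataFrame  # objects x components


def pearson_cc(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.shape[0] != yv.shape[0]:
        raise InputError(
            f"length mismatch: {xv.shape[0]} vs {yv.shape[0]}"
        )
    if xv.shape[0] < 3:
        raise InputError("need at least 3 observations for a correlation")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise InputError("correlation undefined for a constant vector")
    return float(sps.pearsonr(xv, yv).statistic)


def _drop_constant(df: pd.DataFrame, context: str) -> pd.DataFrame:
    constant = df.columns[df.nunique() <= 1]
    if len(constant):
        warnings.warn(
            f"{context}: dropping constant column(s) {list(constant)}",
            stacklevel=3,
        )
        df = df.drop(columns=constant)
    return df


def correlation_matrix(table) -> pd.DataFrame:
    """Symmetric pairwise Pearson correlation matrix with unit diagonal."""
    df = _as_frame(table).astype(float)
    if df.shape[0] < 3:
        raise InputError("need at least 3 objects to correlate columns")
    df = _drop_constant(df, "correlation_matrix")
    if df.shape[1] < 1:
        raise InputError("no non-constant columns left to correlate")
    cm = df.corr(method="pearson")
    np.fill_diagonal(cm.values, 1.0)
    return cm


def high_cc_pairs(
    cm: pd.DataFrame, threshold: float = 0.6
) -> list[tuple[str, str, float]]:
    """Unordered variable pairs with |CC| >= threshold, by |CC| descending."""
    if not (0.0 < threshold <= 1.0):
        raise InputError(f"threshold must lie in (0, 1], got {threshold}")
    names = list(cm.columns)
    pairs = []
    for ia in range(len(names)):
        for ib in range(ia + 1, len(names)):
            cc = float(cm.iloc[ia, ib])
            if abs(cc) >= threshold:
                pairs.append((names[ia], names[ib], cc))
    pairs.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    return pairs


def pca_loadings(table, n_components: int = 2, standardize: bool = True) -> PCAResult:
    """Principal components of a table via the correlation matrix.

    Returns the unit-norm loading vectors, the explained-variance
    fractions (relative to the full spectrum), and per-object scores.
    """
    df = _as_frame(table).astype(float)
    if df.shape[0] < 3:
        raise InputError("need at least 3 objects for PCA")
    if standardize:
        df = _drop_constant(df, "pca_loadings")
        if df.shape[1] < 1:
            raise InputError("no non-constant columns left for PCA")
        Z = (df - df.mean()) / df.std(ddof=1)
        cov = np.corrcoef(df.to_numpy(), rowvar=False)
        cov = np.atleast_2d(cov)
    else:
        Z = df - df.mean()
        cov = np.cov(df.to_numpy(), rowvar=False)
        cov = np.atleast_2d(cov)
    if n_components < 1 or n_components > df.shape[1]:
        raise InputError(
            f"n_components must be in 1..{df.shape[1]}, got {n_components}"
        )
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # Deterministic sign: the largest-magnitude loading of each component
    # points in the positive direction.
    for k in range(eigvecs.shape[1]):
        top = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[top, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    total = eigvals.sum()
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    loadings = pd.DataFrame(
        eigvecs[:, :n_components], index=df.columns, columns=comp_names
    )
    scores = pd.DataFrame(
        Z.to_numpy() @ eigvecs[:, :n_components], index=df.index, columns=comp_names
    )
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=eigvals[:n_components] / total,
        scores=scores,
    )
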