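"""Principal-component reduction of the contemporaneous confounder block.

Model 2 replaces the (large, collinear) block of Wave-1 confounders with
the first k principal components of their correlation matrix, computed
within country.  Ordinal confounders enter as numeric codes; the focal
exposure is never part of the block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import columns as C

logger = logging.getLogger(__name__)


@dataclass
class PCDecomposition:
    eigenvalues: np.ndarray          # descending, sum = n_variables
    loadings: np.ndarray             # columns are components
    cumulative_variance: np.ndarray  # nondecreasing, ends at 1
    columns: list[str]               # confounder columns actually used
    means: np.ndarray
    sds: np.ndarray
    n: int
    country: str | None = None


def pc_decompose(
    block: pd.DataFrame, country: str | None = None
) -> PCDecomposition:
    """Eigendecomposition of the correlation matrix of a confounder block.

    Constant columns are dropped with a notice.  Sign convention: within
    each component, the largest-magnitude loading is positive, so results
    do not flip with the seed or column order.
    """
    usable = []
    for col in block.columns:
        x = block[col].to_numpy(float)
        if np.isnan(x).any():
            raise ValueError(f"confounder '{col}' has missing values; "
                             "run the decomposition on completed data")
        if x.std() == 0:
            logger.info("confounder %s constant; dropped from PCA", col)
            continue
        usable.append(col)
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable confounder columns")

    X = block[usable].to_numpy(float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    Z = (X - means) / sds
    corr = (Z.T @ Z) / len(Z)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    cumvar = np.cumsum(eigval) / eigval.sum()
    return PCDecomposition(eigenvalues=eigval, loadings=eigvec,
                           cumulative_variance=cumvar, columns=usable,
                           means=means, sds=sds, n=len(Z), country=country)


def select_components(decomposition: PCDecomposition, policy="fixed",
                      k: int = 7, fraction: float | None = None) -> int:
    """Number of components to keep: fixed k (default 7) or smallest k
    whose cumulative explained variance reaches ``fraction``."""
    if policy == "fixed":
        return min(k, len(decomposition.eigenvalues))
    if policy == "min_tve":
        if fraction is None or not 0.0 < fraction <= 1.0:
            raise ValueError("min_tve requires a fraction in (0, 1]")
        return int(np.searchsorted(
            decomposition.cumulative_variance, fraction - 1e-12) + 1)
    raise ValueError(f"unknown component policy '{policy}'")


def pc_scores(
    panel: pd.DataFrame, decomposition: PCDecomposition, k: int
) -> pd.DataFrame:
    """First k component scores, standardized using the decomposition's
    means/SDs, returned as ``pc_1 .. pc_k`` columns aligned with panel."""
    missing = [c for c in decomposition.columns if c not in panel.columns]
    if missing:
        raise KeyError(f"panel lacks confounder columns: {missing[:5]}")
    X = panel[decomposition.columns].to_numpy(float)
    Z = (X - decomposition.means) / decomposition.sds
    S = Z @ decomposition.loadings[:, :k]
    return pd.DataFrame(
        S, index=panel.index,
        columns=[f"{C.PC_PREFIX}{j + 1}" for j in range(k)])
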