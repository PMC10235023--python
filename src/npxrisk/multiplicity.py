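"""Multiple-testing correction: effective number of tests and BH-FDR.

The effective number of tests (ENT) is the number of principal components
needed to explain 95% of the variance of the protein matrix; ``0.05 / ENT``
is then used as a Bonferroni-style per-test threshold that accounts for the
strong correlation structure of protein panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["ENTResult", "effective_number_of_tests", "bh_fdr"]

EXPLAINED_TARGET = 0.95


@dataclass
class ENTResult:
    ent: int
    threshold: float
    explained_curve: np.ndarray  # cumulative explained-variance fractions
    n_proteins: int
    n_samples: int


def effective_number_of_tests(matrix: pd.DataFrame | np.ndarray) -> ENTResult:
    """Number of principal components explaining 95% of protein variance.

    Eigendecomposition of the protein correlation matrix.  Missing entries
    are mean-imputed (zero on an already-standardized matrix) solely for the
    decomposition; all-constant proteins are excluded with a warning.
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples for an eigendecomposition")
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean[None, :], X)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("excluding %d all-constant proteins from ENT", int((~keep).sum()))
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("no varying proteins")
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    eig = np.linalg.eigvalsh(R)[::-1]
    eig = np.clip(eig, 0.0, None)
    curve = np.cumsum(eig) / eig.sum()
    ent = int(np.searchsorted(curve, EXPLAINED_TARGET - 1e-12) + 1)
    return ENTResult(
        ent=ent,
        threshold=0.05 / ent,
        explained_curve=curve,
        n_proteins=X.shape[1],
        n_samples=X.shape[0],
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
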