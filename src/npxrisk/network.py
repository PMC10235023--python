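"""Residualized correlations and graphical-LASSO stability networks.

Protein values are first residualized on demographic covariates (default:
age, sex, cohort, smoking status) by per-protein OLS.  Pairwise Pearson
correlations of the residuals are computed separately in cases and
controls.  Sparse conditional-dependence networks are then estimated by
stability selection: the L1-penalized inverse covariance (graphical LASSO)
is refit on many half-sample subsamples, an edge's stability frequency is
the fraction of subsamples in which its precision entry is nonzero, and
edges at or above a stability threshold are declared stable.  The penalty
is chosen on the full group by a StARS-style instability criterion over a
penalty grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "NetworkResult",
    "residualize",
    "pairwise_correlations",
    "stable_network",
]

EDGE_TOL = 1e-8           # |precision entry| above which an edge counts as present
STARS_INSTABILITY = 0.05  # StARS target total edge instability


@dataclass
class NetworkResult:
    """Stability-selected partial-correlation network for one group."""

    group: str
    edges: pd.DataFrame          # protein_a, protein_b, frequency, stable
    degrees: pd.Series           # stable-edge degree per protein
    penalty: float               # chosen L1 penalty
    penalty_grid: np.ndarray
    n_resamples: int
    stability_threshold: float
    instability_curve: pd.Series = field(default_factory=pd.Series)

    @property
    def stable_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["stable"]]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.degrees.index)
        for _, row in self.stable_edges.iterrows():
            g.add_edge(row["protein_a"], row["protein_b"], frequency=row["frequency"])
        return g


def residualize(
    matrix: pd.DataFrame,
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "cohort", "smoking_status"),
) -> pd.DataFrame:
    """Per-protein OLS residuals against demographic covariates.

    Categorical covariates enter as indicator contrasts.  With no
    covariates the matrix is centered only.  Residuals are orthogonal to
    every covariate column in-sample.  Raises ``ValueError`` on a
    rank-deficient design.
    """
    meta = subjects.set_index("sample_id").reindex(matrix.index)
    parts = [pd.Series(1.0, index=matrix.index, name="const")]
    for c in covariates:
        col = meta[c]
        if col.dtype.kind in "biufc":
            parts.append(col.astype(float))
        else:
            parts.append(pd.get_dummies(col, prefix=c, drop_first=True, dtype=float))
    X = pd.concat(parts, axis=1)
    if X.isna().any().any():
        keep = ~X.isna().any(axis=1)
    else:
        keep = pd.Series(True, index=X.index)
    Xk = X.loc[keep].to_numpy()
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        raise ValueError("rank-deficient covariate design in residualization")
    out = pd.DataFrame(np.nan, index=matrix.index, columns=matrix.columns)
    Y = matrix.loc[keep]
    for col in matrix.columns:
        y = Y[col].to_numpy()
        ok = np.isfinite(y)
        if ok.sum() <= Xk.shape[1]:
            continue
        coef, *_ = np.linalg.lstsq(Xk[ok], y[ok], rcond=None)
        resid = y[ok] - Xk[ok] @ coef
        idx = Y.index[ok]
        out.loc[idx, col] = resid
    return out


def pairwise_correlations(
    residual_matrix: pd.DataFrame,
    subjects: pd.DataFrame,
    group: str,
) -> pd.DataFrame:
    """Pearson correlation matrix of residualized proteins within one group.

    ``group`` is ``"cases"`` or ``"controls"``; pairwise-complete
    observations; pairs with fewer than 3 complete observations are NaN.
    """
    if group not in ("cases", "controls"):
        raise ValueError("group must be 'cases' or 'controls'")
    flag = 1 if group == "cases" else 0
    ids = subjects.loc[subjects["case"] == flag, "sample_id"]
    sub = residual_matrix.loc[residual_matrix.index.intersection(ids)]
    return sub.corr(method="pearson", min_periods=3)


def _edge_frequencies(
    X: np.ndarray,
    rng: np.random.Generator,
    penalty: float,
    n_resamples: int,
    subsample_fraction: float,
) -> np.ndarray:
    n, p = X.shape
    m = max(p + 1, int(np.floor(subsample_fraction * n)))
    freq = np.zeros((p, p))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        S = np.corrcoef(X[idx], rowvar=False)
        try:
            with warnings.catch_warnings():
                # tiny negative dual gaps at loose tolerances are benign here
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, prec = graphical_lasso(S, alpha=penalty, max_iter=200)
        except FloatingPointError as exc:  # pragma: no cover - degenerate input
            raise ValueError(f"graphical lasso failed (non-PD input?): {exc}") from exc
        freq += (np.abs(prec) > EDGE_TOL).astype(float)
    freq /= n_resamples
    np.fill_diagonal(freq, 0.0)
    return freq


def stable_network(
    residual_matrix: pd.DataFrame,
    subjects: pd.DataFrame | None,
    group: str,
    penalty_grid: np.ndarray | None = None,
    n_resamples: int = 100,
    subsample_fraction: float = 0.5,
    stability_threshold: float = 0.9,
    seed: int = 0,
) -> NetworkResult:
    """Stability-selected graphical-LASSO network for cases or controls.

    The penalty is chosen over ``penalty_grid`` by the StARS criterion: the
    sparsest-to-densest grid is scanned and the smallest penalty whose
    (monotonized) mean edge instability ``2 f (1 - f)`` stays at or below
    0.05 is used.  Edge stability frequencies at the chosen penalty define
    the stable edge set.  A pure function of (data, parameters, seed).
    """
    if subjects is not None:
        if group not in ("cases", "controls"):
            raise ValueError("group must be 'cases' or 'controls'")
        flag = 1 if group == "cases" else 0
        ids = subjects.loc[subjects["case"] == flag, "sample_id"]
        sub = residual_matrix.loc[residual_matrix.index.intersection(ids)]
    else:
        sub = residual_matrix
    sub = sub.dropna(axis=0, how="any")
    proteins = list(sub.columns)
    p = len(proteins)
    if p < 2:
        raise ValueError("need at least two proteins")
    if n_resamples < 2:
        raise ValueError("need at least two resamples")
    X = sub.to_numpy(dtype=float)
    if penalty_grid is None:
        penalty_grid = np.geomspace(0.02, 0.8, 8)
    penalty_grid = np.sort(np.asarray(penalty_grid, dtype=float))[::-1]  # sparse -> dense

    rng = np.random.default_rng(seed)
    freqs: dict[float, np.ndarray] = {}
    instab = []
    iu = np.triu_indices(p, k=1)
    for lam in penalty_grid:
        f = _edge_frequencies(X, rng, lam, n_resamples, subsample_fraction)
        freqs[lam] = f
        instab.append(float(np.mean(2.0 * f[iu] * (1.0 - f[iu]))))
    # monotonize instability from the sparse end, then pick the densest
    # penalty still within the instability budget
    dbar = np.maximum.accumulate(instab)
    admissible = np.flatnonzero(dbar <= STARS_INSTABILITY)
    chosen = penalty_grid[admissible[-1]] if admissible.size else penalty_grid[0]

    f = freqs[chosen]
    rows = []
    for i, j in zip(*iu):
        rows.append(
            {
                "protein_a": proteins[i],
                "protein_b": proteins[j],
                "frequency": f[i, j],
                "stable": bool(f[i, j] >= stability_threshold),
            }
        )
    edges = pd.DataFrame(rows, columns=["protein_a", "protein_b", "frequency", "stable"])
    degrees = pd.Series(0, index=pd.Index(proteins, name="protein"), dtype=int)
    for _, row in edges[edges["stable"]].iterrows():
        degrees[row["protein_a"]] += 1
        degrees[row["protein_b"]] += 1
    return NetworkResult(
        group=group,
        edges=edges,
        degrees=degrees,
        penalty=float(chosen),
        penalty_grid=penalty_grid,
        n_resamples=n_resamples,
        stability_threshold=stability_threshold,
        instability_curve=pd.Series(instab, index=penalty_grid),
    )
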