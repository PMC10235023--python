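"""Conditional logistic regression for 1:1 matched sets, and linear models
of protein levels on smoking history.

For a 1:1 matched set ``s`` with case covariates ``x_case`` and control
covariates ``x_ctrl``, the conditional likelihood contribution is

    exp(b'x_case) / (exp(b'x_case) + exp(b'x_ctrl)) = sigmoid(b'd_s),

with ``d_s = x_case - x_ctrl``.  The log-likelihood is maximized by Newton
iterations with the analytic gradient and Hessian; Wald standard errors come
from the observed information and 95% confidence intervals are
``exp(b +- 1.96 * se)``.  The odds ratio per SD of a (log2-scale,
cohort-standardized) protein is ``exp(b)``.

A vectorized single-covariate path (:func:`fit_clogit_many`) fits all
proteins of a matrix at once, which the resampling selection algorithm
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, log_expit

__all__ = [
    "AssocResult",
    "SmokingAssocResult",
    "MonotoneLikelihoodError",
    "InsufficientDataError",
    "case_control_differences",
    "clogit_differences",
    "fit_clogit",
    "fit_adjusted_clogit",
    "fit_clogit_many",
    "fit_smoking_linear",
]

SMOKING_COVARIATES = ("cigs_per_day", "years_smoked", "years_since_cessation")
Z95 = 1.959963984540054  # Phi^{-1}(0.975); CIs reported with the conventional 1.96


class MonotoneLikelihoodError(RuntimeError):
    """The conditional likelihood is monotone: no finite maximizer exists."""


class InsufficientDataError(ValueError):
    """Fewer than two usable matched sets."""


@dataclass
class AssocResult:
    """Per-protein matched association estimate."""

    protein: str
    beta: float
    se: float
    or_sd: float
    ci_low: float
    ci_high: float
    p: float
    n_sets: int
    adjusted: bool = False

    def to_dict(self) -> dict:
        return {
            "protein": self.protein,
            "beta": self.beta,
            "se": self.se,
            "or_sd": self.or_sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n_sets": self.n_sets,
            "adjusted": self.adjusted,
        }


@dataclass
class SmokingAssocResult:
    protein: str
    metric: str
    coefficient: float
    se: float
    p: float
    population: str


def case_control_differences(
    values: pd.DataFrame | pd.Series, subjects: pd.DataFrame
) -> pd.DataFrame:
    """Case-minus-control differences per matched set.

    ``values`` is indexed by sample_id (a Series or a samples-by-columns
    frame); returns a sets-by-columns frame indexed by set_id.  Sets without
    exactly one case and one control raise ``ValueError``.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame()
    sub = subjects[["sample_id", "set_id", "case"]]
    counts = sub.groupby("set_id")["case"].agg(["size", "sum"])
    bad = counts[(counts["size"] != 2) | (counts["sum"] != 1)]
    if len(bad):
        raise ValueError(f"sets without exactly one case and one control: {list(bad.index[:5])}")
    cases = sub[sub["case"] == 1].sort_values("set_id")
    ctrls = sub[sub["case"] == 0].sort_values("set_id")
    d = values.reindex(cases["sample_id"]).to_numpy() - values.reindex(ctrls["sample_id"]).to_numpy()
    return pd.DataFrame(d, index=pd.Index(cases["set_id"].to_numpy(), name="set_id"), columns=values.columns)


def _check_monotone(D: np.ndarray, names: list[str]) -> None:
    for j, name in enumerate(names):
        col = D[:, j]
        col = col[np.isfinite(col) & (col != 0)]
        if len(col) and (np.all(col > 0) or np.all(col < 0)):
            raise MonotoneLikelihoodError(
                f"monotone likelihood: all within-set differences of {name!r} share one sign"
            )


def clogit_differences(
    D: np.ndarray, names: list[str] | None = None, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Maximize the 1:1 conditional log-likelihood on a difference matrix.

    Returns ``(beta, se, cov, loglik)``.  Newton-Raphson with step-halving
    on a likelihood decrease; convergence when the max-norm of the score
    falls below ``tol``.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    names = names or [f"x{j}" for j in range(D.shape[1])]
    D = D[np.isfinite(D).all(axis=1)]
    n, k_full = D.shape
    if n < 2:
        raise InsufficientDataError(f"only {n} usable matched sets")
    _check_monotone(D, names)
    # within-set constants cancel in the conditional likelihood: drop them
    varying = np.flatnonzero((D != 0).any(axis=0))
    if varying.size == 0:
        raise InsufficientDataError("no within-set variation in any covariate")
    dropped = [j for j in range(k_full) if j not in set(varying)]
    D = D[:, varying]
    k = D.shape[1]

    beta = np.zeros(k)
    ll = float(log_expit(D @ beta).sum())
    for _ in range(max_iter):
        p = expit(D @ beta)
        score = D.T @ (1.0 - p)
        if np.max(np.abs(score)) < tol:
            break
        w = p * (1.0 - p)
        info = D.T @ (D * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise MonotoneLikelihoodError(f"singular information matrix: {exc}") from exc
        # step-halving on likelihood decrease
        for _ in range(30):
            cand = beta + step
            ll_new = float(log_expit(D @ cand).sum())
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, ll = cand, ll_new
    if np.max(np.abs(beta)) > 30:
        raise MonotoneLikelihoodError("estimates diverged; likelihood appears monotone")
    p = expit(D @ beta)
    info = D.T @ (D * (p * (1.0 - p))[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    if dropped:
        beta_f = np.zeros(k_full)
        se_f = np.full(k_full, np.inf)
        cov_f = np.full((k_full, k_full), np.nan)
        beta_f[varying] = beta
        se_f[varying] = se
        cov_f[np.ix_(varying, varying)] = cov
        return beta_f, se_f, cov_f, ll
    return beta, se, cov, ll


def _assoc_from_fit(protein: str, beta: float, se: float, n_sets: int, adjusted: bool) -> AssocResult:
    z = beta / se
    return AssocResult(
        protein=protein,
        beta=float(beta),
        se=float(se),
        or_sd=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        p=float(2.0 * stats.norm.sf(abs(z))),
        n_sets=int(n_sets),
        adjusted=adjusted,
    )


def fit_clogit(
    matrix: pd.DataFrame,
    subjects: pd.DataFrame,
    protein: str,
    covariates: tuple[str, ...] = (),
) -> AssocResult:
    """Crude (or covariate-adjusted) conditional logistic fit for one protein.

    Sets with a missing protein value in either member are dropped
    (complete-set analysis); ``n_sets`` reports the sets used.  Covariates
    are metadata columns entered as within-set differences alongside the
    protein.
    """
    cols = pd.DataFrame({protein: matrix[protein]})
    for c in covariates:
        cols[c] = subjects.set_index("sample_id")[c].reindex(matrix.index)
    D = case_control_differences(cols, subjects)
    D = D.dropna()
    beta, se, _, _ = clogit_differences(D.to_numpy(), list(cols.columns))
    return _assoc_from_fit(protein, beta[0], se[0], len(D), adjusted=bool(covariates))


def fit_adjusted_clogit(matrix: pd.DataFrame, subjects: pd.DataFrame, protein: str) -> AssocResult:
    """Conditional logistic fit adjusted for smoking intensity, duration,
    and years since cessation (continuous, standardized within cohort)."""
    meta = subjects.set_index("sample_id")
    cov = meta[list(SMOKING_COVARIATES)].copy()
    cov = cov.groupby(meta["cohort"]).transform(lambda s: (s - s.mean()) / s.std(ddof=1))
    cols = pd.DataFrame({protein: matrix[protein]})
    for c in SMOKING_COVARIATES:
        cols[c] = cov[c].reindex(matrix.index)
    D = case_control_differences(cols, subjects).dropna()
    beta, se, _, _ = clogit_differences(D.to_numpy(), list(cols.columns))
    return _assoc_from_fit(protein, beta[0], se[0], len(D), adjusted=True)


def fit_clogit_many(
    diffs: pd.DataFrame | np.ndarray,
    max_iter: int = 60,
    min_sets: int = 2,
) -> pd.DataFrame:
    """Vectorized single-covariate conditional logistic fits.

    ``diffs`` holds per-set case-minus-control differences, one column per
    protein (NaN = incomplete set, dropped per protein).  Proteins with a
    monotone likelihood or fewer than ``min_sets`` usable sets get NaN
    estimates.  Returns a frame with beta, se, z, p, n_sets per protein.
    """
    if isinstance(diffs, pd.DataFrame):
        cols = diffs.columns
        D = diffs.to_numpy(dtype=float)
    else:
        D = np.asarray(diffs, dtype=float)
        cols = pd.RangeIndex(D.shape[1])
    finite = np.isfinite(D)
    Dz = np.where(finite, D, 0.0)
    n_sets = finite.sum(axis=0)

    pos = ((Dz > 0) & finite).sum(axis=0)
    neg = ((Dz < 0) & finite).sum(axis=0)
    nonzero = pos + neg
    monotone = (nonzero > 0) & ((pos == 0) | (neg == 0))
    usable = (~monotone) & (n_sets >= min_sets)

    beta = np.zeros(D.shape[1])
    for _ in range(max_iter):
        eta = Dz * beta[None, :]
        p = expit(eta)
        # masked entries have Dz == 0 so contribute nothing to score/info
        score = (Dz * (1.0 - p)).sum(axis=0)
        info = (Dz * Dz * p * (1.0 - p)).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(usable & (info > 0), score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -4.0, 4.0)
        beta = beta + step
        if np.max(np.abs(step[usable]), initial=0.0) < 1e-10:
            break
    p = expit(Dz * beta[None, :])
    info = (Dz * Dz * p * (1.0 - p)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(usable & (info > 0), 1.0 / np.sqrt(info), np.nan)
    beta = np.where(usable, beta, np.nan)
    z = beta / se
    out = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "z": z,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
            "n_sets": n_sets,
        },
        index=cols,
    )
    return out


def fit_smoking_linear(
    matrix: pd.DataFrame,
    subjects: pd.DataFrame,
    protein: str,
    metric: str,
    population: str = "controls-only",
) -> SmokingAssocResult:
    """OLS of a standardized protein on one smoking metric.

    Adjusts for cohort (indicator contrasts), age, sex, and smoking status;
    the ``combined`` population additionally adjusts for case status.
    Former-smoker metrics (years since cessation) are fit among former
    smokers only.  Raises ``ValueError`` on a rank-deficient design.
    """
    if population not in ("controls-only", "combined"):
        raise ValueError(f"unknown population {population!r}")
    meta = subjects.set_index("sample_id").copy()
    meta["y"] = matrix[protein]
    if population == "controls-only":
        meta = meta[meta["case"] == 0]
    if metric == "years_since_cessation":
        meta = meta[meta["smoking_status"].str.startswith("former")]
    meta = meta.dropna(subset=["y", metric, "age", "sex", "cohort", "smoking_status"])
    X = pd.DataFrame({"metric": meta[metric], "age": meta["age"]}, index=meta.index)
    X = pd.concat(
        [
            X,
            pd.get_dummies(meta["sex"], prefix="sex", drop_first=True, dtype=float),
            pd.get_dummies(meta["cohort"], prefix="cohort", drop_first=True, dtype=float),
            pd.get_dummies(meta["smoking_status"], prefix="smk", drop_first=True, dtype=float),
        ],
        axis=1,
    )
    if population == "combined":
        X["case"] = meta["case"].astype(float)
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient adjustment design (collinear covariates)")
    fit = sm.OLS(meta["y"].to_numpy(), X.to_numpy()).fit()
    j = list(X.columns).index("metric")
    return SmokingAssocResult(
        protein=protein,
        metric=metric,
        coefficient=float(fit.params[j]),
        se=float(fit.bse[j]),
        p=float(fit.pvalues[j]),
        population=population,
    )
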