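"""Stratum-specific odds ratios, heterogeneity/trend tests, and incremental
discrimination over a baseline risk score.

Heterogeneity across strata is tested with Cochran's Q on the stratum log
odds ratios with inverse-variance weights (chi-square, k-1 df).  For
ordered strata (lead-time categories), a linear trend is tested by
inverse-variance-weighted regression of the stratum log OR on the category
score.  Discrimination is the Mann-Whitney concordance (AUC, ties counted
one half) of the baseline score alone versus the fitted linear combination
of baseline score and protein from an unconditional logistic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .models import AssocResult, InsufficientDataError, MonotoneLikelihoodError, fit_clogit

__all__ = [
    "StratifiedResult",
    "DiscriminationResult",
    "LEAD_TIME_BINS",
    "assign_strata",
    "stratified_or",
    "cochran_q",
    "trend_test",
    "delta_auc",
]

# lead-time categories in years: <1, 1-2, 2-3
LEAD_TIME_BINS = (0.0, 1.0, 2.0, np.inf)
LEAD_TIME_LABELS = ("<1y", "1-2y", "2-3y")

ORDINAL_STRATA = {"lead_time": list(LEAD_TIME_LABELS), "stage": ["early", "late"]}


@dataclass
class StratifiedResult:
    protein: str
    stratum_var: str
    strata: dict[str, AssocResult]
    q_stat: float
    p_het: float
    trend_slope: float | None = None
    p_trend: float | None = None
    omitted: list[str] = field(default_factory=list)


@dataclass
class DiscriminationResult:
    protein: str
    auc_baseline: float
    auc_with_protein: float

    @property
    def delta_auc(self) -> float:
        return self.auc_with_protein - self.auc_baseline


def assign_strata(subjects: pd.DataFrame, stratum_var: str) -> pd.Series:
    """Stratum label per matched set.

    Case attributes (histology, stage, lead time) label the set by its case;
    attributes shared by matching (cohort, smoking status) by either member.
    Stage is grouped early (TNM 1-2) vs late (TNM 3-4); lead time into
    <1, 1-2, and 2-3 year categories.
    """
    cases = subjects[subjects["case"] == 1].set_index("set_id")
    if stratum_var in ("cohort", "smoking_status", "sex"):
        return cases[stratum_var]
    if stratum_var == "histology":
        return cases["histology"]
    if stratum_var == "stage":
        stage = cases["stage"]
        return pd.Series(
            np.where(stage.isna(), None, np.where(stage <= 2, "early", "late")),
            index=stage.index,
        )
    if stratum_var == "lead_time":
        return pd.cut(cases["lead_time"], bins=LEAD_TIME_BINS, labels=LEAD_TIME_LABELS,
                      right=False, include_lowest=True).astype(object)
    raise ValueError(f"unknown stratum variable {stratum_var!r}")


def cochran_q(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    """Cochran's Q on stratum estimates with inverse-variance weights."""
    w = 1.0 / np.asarray(ses, float) ** 2
    b = np.asarray(betas, float)
    bw = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - bw) ** 2))
    df = len(b) - 1
    p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return q, p


def trend_test(betas: np.ndarray, ses: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Inverse-variance-weighted linear regression of beta on category score.

    Returns (slope, two-sided p) from the weighted-least-squares slope and
    its fixed-effect standard error.
    """
    w = 1.0 / np.asarray(ses, float) ** 2
    b = np.asarray(betas, float)
    x = np.asarray(scores, float)
    xbar = np.sum(w * x) / np.sum(w)
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx <= 0:
        raise ValueError("degenerate trend design: all category scores equal")
    slope = float(np.sum(w * (x - xbar) * b) / sxx)
    se = float(1.0 / np.sqrt(sxx))
    p = float(2.0 * stats.norm.sf(abs(slope / se)))
    return slope, p


def stratified_or(
    matrix: pd.DataFrame,
    subjects: pd.DataFrame,
    protein: str,
    stratum_var: str,
    min_sets: int = 10,
) -> StratifiedResult:
    """Conditional logistic OR per stratum plus heterogeneity/trend tests.

    Strata with fewer than ``min_sets`` usable sets (or a degenerate fit)
    are omitted and listed in ``omitted``.
    """
    labels = assign_strata(subjects, stratum_var)
    results: dict[str, AssocResult] = {}
    omitted: list[str] = []
    for level in sorted({str(v) for v in labels.dropna().unique()}):
        sets = labels.index[labels.astype(str) == level]
        sub_subjects = subjects[subjects["set_id"].isin(sets)]
        sub_matrix = matrix.loc[matrix.index.intersection(sub_subjects["sample_id"])]
        try:
            res = fit_clogit(sub_matrix, sub_subjects, protein)
        except (MonotoneLikelihoodError, InsufficientDataError):
            omitted.append(level)
            continue
        if res.n_sets < min_sets:
            omitted.append(level)
            continue
        results[level] = res
    if len(results) < 2:
        raise InsufficientDataError(
            f"fewer than two usable strata for {protein} by {stratum_var}"
        )
    betas = np.array([r.beta for r in results.values()])
    ses = np.array([r.se for r in results.values()])
    q, p_het = cochran_q(betas, ses)
    slope = p_trend = None
    if stratum_var in ORDINAL_STRATA:
        order = [lv for lv in ORDINAL_STRATA[stratum_var] if lv in results]
        if len(order) >= 2:
            scores = np.array([ORDINAL_STRATA[stratum_var].index(lv) for lv in order], float)
            b = np.array([results[lv].beta for lv in order])
            s = np.array([results[lv].se for lv in order])
            slope, p_trend = trend_test(b, s, scores)
    return StratifiedResult(
        protein=protein,
        stratum_var=stratum_var,
        strata=results,
        q_stat=q,
        p_het=p_het,
        trend_slope=slope,
        p_trend=p_trend,
        omitted=omitted,
    )


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-concordance AUC with ties counted one half."""
    labels = np.asarray(labels, int)
    if labels.min() == labels.max():
        raise ValueError("need both cases and controls to compute an AUC")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def delta_auc(
    matrix: pd.DataFrame,
    subjects: pd.DataFrame,
    protein: str,
    baseline_col: str = "baseline_score",
) -> DiscriminationResult:
    """AUC gain from adding one protein to a baseline risk score.

    The baseline AUC is the concordance of the baseline score for case
    status.  The protein is added through an unconditional logistic model of
    case status on (baseline score, protein); the with-protein AUC is the
    concordance of that model's linear predictor.  Computed on the matched
    sample as-is, so the values are conditional on the matched design.
    """
    meta = subjects.set_index("sample_id")
    df = pd.DataFrame(
        {
            "case": meta["case"].reindex(matrix.index),
            "base": meta[baseline_col].reindex(matrix.index),
            "prot": matrix[protein],
        }
    ).dropna()
    y = df["case"].to_numpy(int)
    if y.min() == y.max():
        raise ValueError("need both cases and controls")
    auc0 = auc_mann_whitney(df["base"].to_numpy(), y)
    X = df[["base", "prot"]].to_numpy()
    # near-unpenalized fit; stays finite under complete separation
    lr = LogisticRegression(C=1e6, max_iter=5000, tol=1e-10)
    lr.fit(X, y)
    lin = X @ lr.coef_[0]
    auc1 = auc_mann_whitney(lin, y)
    return DiscriminationResult(protein=protein, auc_baseline=auc0, auc_with_protein=auc1)
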