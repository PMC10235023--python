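"""Preclinical stage back-calculation and post-diagnosis survival models.

Stage at blood draw is back-calculated deterministically from the diagnosed
stage using mean preclinical sojourn times specific to stage, sex, and
histology: starting at the diagnosed stage, the stage's mean sojourn time
is subtracted from the lead time; while the remainder is positive the walk
steps to the next-lower stage and subtracts its sojourn time; the stage in
which the remainder first becomes non-positive is the estimated stage at
draw (a remainder exceeding the whole preclinical window returns the lowest
modelled stage).

Post-diagnosis all-cause mortality is modelled with Cox proportional
hazards on time from diagnosis to death, stratifying the baseline hazard by
cohort and sex, adjusting for age, and including a protein x lead-time
interaction so the protein main effect is its log hazard ratio at the time
of diagnosis (lead time 0).  Ties are handled with Efron's approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

__all__ = [
    "SojournTable",
    "SurvivalResult",
    "default_sojourn_table",
    "stage_at_blood_draw",
    "summarize_stage_shift",
    "fit_cox",
]

STAGE_ORDER = [1, 2, 3, 4]


@dataclass
class SojournTable:
    """Mean preclinical sojourn time (years) by stage x sex x histology."""

    table: pd.DataFrame  # columns: stage, sex, histology, years

    def __post_init__(self) -> None:
        required = {"stage", "sex", "histology", "years"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sojourn table missing columns: {sorted(missing)}")
        if (self.table["years"] <= 0).any():
            raise ValueError("sojourn times must be positive")
        self._lookup = self.table.set_index(["stage", "sex", "histology"])["years"]

    def sojourn(self, stage: int, sex: str, histology: str) -> float:
        try:
            return float(self._lookup.loc[(stage, sex, histology)])
        except KeyError as exc:
            raise KeyError(
                f"no sojourn time for stage={stage}, sex={sex!r}, histology={histology!r}"
            ) from exc


def default_sojourn_table(
    histologies: tuple[str, ...] = ("adenocarcinoma", "squamous", "large_cell", "small_cell", "other"),
) -> SojournTable:
    """Synthetic default sojourn-time table (stand-in values, not estimates
    from any screening model).

    Dwell times shrink with advancing stage, small-cell histology is
    fastest-growing, and women have slightly longer sojourn times — the
    qualitative pattern of published natural-history models — but the
    numbers themselves are invented defaults for simulation and testing.
    """
    base = {1: 2.0, 2: 1.2, 3: 0.9, 4: 0.6}
    hist_factor = {
        "adenocarcinoma": 1.3,
        "squamous": 1.0,
        "large_cell": 0.9,
        "small_cell": 0.5,
        "other": 1.0,
    }
    rows = []
    for stage, yrs in base.items():
        for sex, sex_f in (("M", 1.0), ("F", 1.15)):
            for h in histologies:
                rows.append(
                    {"stage": stage, "sex": sex, "histology": h,
                     "years": round(yrs * sex_f * hist_factor.get(h, 1.0), 3)}
                )
    return SojournTable(pd.DataFrame(rows))


def stage_at_blood_draw(
    diagnosed_stage: int,
    sex: str,
    histology: str,
    lead_time: float,
    sojourn_table: SojournTable,
) -> int:
    """Deterministic backward walk from diagnosed stage through mean sojourn
    times; see module docstring.  Lead time 0 returns the diagnosed stage."""
    if lead_time < 0:
        raise ValueError("lead time must be non-negative")
    if not (diagnosed_stage == diagnosed_stage) or diagnosed_stage not in STAGE_ORDER:
        raise ValueError(f"invalid diagnosed stage: {diagnosed_stage!r}")
    stage = int(diagnosed_stage)
    remainder = float(lead_time)
    while True:
        remainder -= sojourn_table.sojourn(stage, sex, histology)
        if remainder <= 0 or stage == STAGE_ORDER[0]:
            return stage
        stage -= 1


def summarize_stage_shift(cases: pd.DataFrame, sojourn_table: SojournTable) -> pd.DataFrame:
    """Distribution of estimated stage at blood draw over a case series.

    ``cases`` needs columns stage, sex, histology, lead_time; rows with
    missing stage or histology are excluded (counted in the output attrs).
    Returns one row per stage with the proportion at draw, plus cumulative
    early-stage (stage <= 2 and stage <= 1) proportions in ``attrs``.
    """
    usable = cases.dropna(subset=["stage", "histology", "lead_time"])
    if not len(usable):
        raise ValueError("no cases with complete stage/histology/lead-time information")
    est = [
        stage_at_blood_draw(int(r["stage"]), r["sex"], r["histology"], float(r["lead_time"]), sojourn_table)
        for _, r in usable.iterrows()
    ]
    est = pd.Series(est, index=usable.index, name="stage_at_draw")
    counts = est.value_counts().reindex(STAGE_ORDER, fill_value=0)
    out = pd.DataFrame(
        {
            "stage": STAGE_ORDER,
            "n_at_draw": counts.to_numpy(),
            "prop_at_draw": counts.to_numpy() / len(est),
        }
    )
    out.attrs["n_cases_used"] = int(len(est))
    out.attrs["n_cases_excluded"] = int(len(cases) - len(usable))
    out.attrs["prop_stage_le_2"] = float((est <= 2).mean())
    out.attrs["prop_stage_le_1"] = float((est <= 1).mean())
    out.attrs["per_case"] = est
    return out


@dataclass
class SurvivalResult:
    protein: str
    log_hr_at_dx: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    interaction_coef: float
    interaction_se: float
    interaction_p: float
    n_cases: int
    n_events: int


def fit_cox(
    cases: pd.DataFrame,
    protein_values: pd.Series,
    protein: str = "protein",
) -> SurvivalResult:
    """Stratified Cox model of post-diagnosis all-cause mortality.

    Baseline hazard stratified by cohort x sex; covariates are age, the
    protein, and protein x lead time, so ``log_hr_at_dx`` (the protein main
    effect) is the log hazard ratio per SD at diagnosis.  ``cases`` needs
    columns surv_time, death, cohort, sex, age, lead_time.
    """
    df = cases[["surv_time", "death", "cohort", "sex", "age", "lead_time"]].copy()
    df["protein"] = protein_values.reindex(cases.index if "sample_id" not in cases else cases["sample_id"]).to_numpy()
    df = df.dropna()
    if not len(df):
        raise ValueError("no usable cases")
    df["protein_x_lead"] = df["protein"] * df["lead_time"]
    events_per_stratum = df.groupby(["cohort", "sex"])["death"].sum()
    if (events_per_stratum == 0).all():
        raise ValueError("no deaths in any cohort x sex stratum")
    cph = CoxPHFitter()
    cph.fit(
        df[["surv_time", "death", "cohort", "sex", "age", "protein", "protein_x_lead"]],
        duration_col="surv_time",
        event_col="death",
        strata=["cohort", "sex"],
    )
    s = cph.summary
    prot = s.loc["protein"]
    inter = s.loc["protein_x_lead"]
    return SurvivalResult(
        protein=protein,
        log_hr_at_dx=float(prot["coef"]),
        hr=float(np.exp(prot["coef"])),
        ci_low=float(np.exp(prot["coef lower 95%"])),
        ci_high=float(np.exp(prot["coef upper 95%"])),
        p=float(prot["p"]),
        interaction_coef=float(inter["coef"]),
        interaction_se=float(inter["se(coef)"]),
        interaction_p=float(inter["p"]),
        n_cases=int(len(df)),
        n_events=int(df["death"].sum()),
    )
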