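"""Sojourn-time backward walk and stratified Cox survival models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npxrisk.clinical import (
    SojournTable,
    default_sojourn_table,
    fit_cox,
    stage_at_blood_draw,
    summarize_stage_shift,
)


@pytest.fixture(scope="module")
def simple_table():
    rows = []
    for stage, yrs in [(1, 2.0), (2, 1.5), (3, 1.0), (4, 0.5)]:
        for sex in ("M", "F"):
            rows.append({"stage": stage, "sex": sex, "histology": "adenocarcinoma", "years": yrs})
    return SojournTable(pd.DataFrame(rows))


class TestBackwardWalk:
    def test_zero_lead_time_returns_diagnosed_stage(self, simple_table):
        for stage in (1, 2, 3, 4):
            assert stage_at_blood_draw(stage, "M", "adenocarcinoma", 0.0, simple_table) == stage

    def test_worked_example_stage_three_to_two(self, simple_table):
        # L=2.0: 2.0 - sojourn(3)=1.0 leaves 1.0 < sojourn(2)=1.5 -> stage 2
        assert stage_at_blood_draw(3, "M", "adenocarcinoma", 2.0, simple_table) == 2

    def test_lead_time_exceeding_window_returns_lowest_stage(self, simple_table):
        assert stage_at_blood_draw(4, "M", "adenocarcinoma", 50.0, simple_table) == 1

    def test_long_sojourns_freeze_stage(self):
        rows = [{"stage": s, "sex": "M", "histology": "other", "years": 10.0} for s in (1, 2, 3, 4)]
        table = SojournTable(pd.DataFrame(rows))
        for stage in (1, 2, 3, 4):
            assert stage_at_blood_draw(stage, "M", "other", 3.0, table) == stage

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        stage=st.sampled_from([1, 2, 3, 4]),
        l1=st.floats(0.0, 6.0),
        dl=st.floats(0.0, 3.0),
    )
    def test_monotone_in_lead_time(self, simple_table, stage, l1, dl):
        """A larger lead time never yields a later stage at draw."""
        early = stage_at_blood_draw(stage, "F", "adenocarcinoma", l1 + dl, simple_table)
        late = stage_at_blood_draw(stage, "F", "adenocarcinoma", l1, simple_table)
        assert early <= late

    def test_negative_lead_time_rejected(self, simple_table):
        with pytest.raises(ValueError):
            stage_at_blood_draw(2, "M", "adenocarcinoma", -0.5, simple_table)

    def test_missing_table_entry_raises(self, simple_table):
        with pytest.raises(KeyError):
            stage_at_blood_draw(2, "M", "small_cell", 1.0, simple_table)


class TestStageShift:
    def brute_force(self, cases, table):
        """Per-case oracle: literal re-application of the stated rule."""
        out = []
        for _, r in cases.iterrows():
            stage, rem = int(r["stage"]), float(r["lead_time"])
            while True:
                rem -= table.sojourn(stage, r["sex"], r["histology"])
                if rem <= 0 or stage == 1:
                    break
                stage -= 1
            out.append(stage)
        return np.array(out)

    def test_matches_per_case_oracle(self, simple_table):
        rng = np.random.default_rng(0)
        n = 500
        cases = pd.DataFrame(
            {
                "stage": rng.choice([1, 2, 3, 4], n).astype(float),
                "sex": rng.choice(["M", "F"], n),
                "histology": "adenocarcinoma",
                "lead_time": rng.uniform(0, 3, n),
            }
        )
        out = summarize_stage_shift(cases, simple_table)
        oracle = self.brute_force(cases, simple_table)
        assert (out.attrs["per_case"].to_numpy() == oracle).all()
        assert out.attrs["prop_stage_le_2"] == pytest.approx((oracle <= 2).mean())

    def test_zero_lead_times_reproduce_diagnosed_distribution(self, simple_table):
        cases = pd.DataFrame(
            {
                "stage": [1.0, 2.0, 3.0, 4.0, 4.0],
                "sex": "M",
                "histology": "adenocarcinoma",
                "lead_time": 0.0,
            }
        )
        out = summarize_stage_shift(cases, simple_table)
        assert list(out["n_at_draw"]) == [1, 1, 1, 2]

    def test_incomplete_cases_excluded_and_counted(self, simple_table):
        cases = pd.DataFrame(
            {
                "stage": [3.0, np.nan],
                "sex": ["M", "M"],
                "histology": ["adenocarcinoma", "adenocarcinoma"],
                "lead_time": [1.0, 1.0],
            }
        )
        out = summarize_stage_shift(cases, simple_table)
        assert out.attrs["n_cases_used"] == 1
        assert out.attrs["n_cases_excluded"] == 1

    def test_nonpositive_sojourn_rejected(self):
        with pytest.raises(ValueError):
            SojournTable(pd.DataFrame([{"stage": 1, "sex": "M", "histology": "x", "years": 0.0}]))


def simulate_survival(seed, n=1500, beta=0.3, interaction=-0.1):
    rng = np.random.default_rng(seed)
    cohort = rng.choice(["A", "B"], n)
    sex = rng.choice(["M", "F"], n)
    age = rng.normal(65, 8, n)
    lead = rng.uniform(0, 3, n)
    x = rng.standard_normal(n)
    base = np.where(cohort == "A", 3.0, 6.0) * np.where(sex == "M", 1.0, 1.4)
    lin = (beta + interaction * lead) * x
    t_death = rng.exponential(base * np.exp(-lin))
    t_cens = rng.exponential(8.0, n)
    df = pd.DataFrame(
        {
            "surv_time": np.minimum(t_death, t_cens),
            "death": (t_death <= t_cens).astype(int),
            "cohort": cohort,
            "sex": sex,
            "age": age,
            "lead_time": lead,
        }
    )
    return df, pd.Series(x, index=df.index)


class TestCox:
    def test_null_protein_ci_covers_one(self):
        covered = 0
        for seed in range(10):
            df, x = simulate_survival(seed, n=800, beta=0.0, interaction=0.0)
            res = fit_cox(df, x)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 8

    def test_planted_coefficients_recovered(self):
        df, x = simulate_survival(99, n=4000)
        res = fit_cox(df, x)
        assert res.log_hr_at_dx == pytest.approx(0.3, abs=0.1)
        assert res.interaction_coef == pytest.approx(-0.1, abs=0.07)
        assert res.ci_low < np.exp(0.3) < res.ci_high

    def test_invariant_to_time_rescaling(self):
        df, x = simulate_survival(5)
        a = fit_cox(df, x)
        df2 = df.copy()
        df2["surv_time"] *= 37.0
        b = fit_cox(df2, x)
        assert b.log_hr_at_dx == pytest.approx(a.log_hr_at_dx, rel=1e-6)
        assert b.interaction_coef == pytest.approx(a.interaction_coef, rel=1e-6)

    def test_stratified_partial_likelihood_decomposes_over_strata(self):
        """The stratified partial log-likelihood equals the sum of the
        per-stratum partial log-likelihoods at the same coefficients
        (Breslow evaluator; continuous times, so no ties)."""
        from lifelines import CoxPHFitter

        def breslow_ll(d, beta_vec, cols):
            t = d["surv_time"].to_numpy()
            e = d["death"].to_numpy()
            eta = d[cols].to_numpy() @ beta_vec
            order = np.argsort(-t)  # decreasing time
            t, e, eta = t[order], e[order], eta[order]
            cum = np.logaddexp.accumulate(eta)
            # risk set of an event at time t_i: all with t_j >= t_i
            ll = 0.0
            for i in range(len(t)):
                if e[i]:
                    ll += eta[i] - cum[i]
            return ll

        df, x = simulate_survival(17, n=600)
        df = df.copy()
        df["protein"] = x
        df["protein_x_lead"] = x * df["lead_time"]
        cols = ["age", "protein", "protein_x_lead"]
        cph = CoxPHFitter()
        cph.fit(df[["surv_time", "death", "cohort", "sex"] + cols],
                duration_col="surv_time", event_col="death", strata=["cohort", "sex"])
        beta_vec = cph.params_.to_numpy()
        total = sum(breslow_ll(g, beta_vec, cols) for _, g in df.groupby(["cohort", "sex"]))
        assert cph.log_likelihood_ == pytest.approx(total, rel=1e-6)

    def test_unstratified_fit_biased_when_baselines_differ(self):
        """Strata with very different baseline hazards correlated with the
        covariate: the stratified fit stays near truth, a pooled
        unstratified fit drifts."""
        rng = np.random.default_rng(8)
        n = 4000
        cohort = rng.choice(["A", "B"], n)
        sex = np.repeat("M", n)
        x = rng.standard_normal(n) + np.where(cohort == "A", 1.0, -1.0)
        base = np.where(cohort == "A", 1.0, 20.0)
        t_death = rng.exponential(base * np.exp(-0.3 * x))
        df = pd.DataFrame(
            {
                "surv_time": t_death,
                "death": 1,
                "cohort": cohort,
                "sex": sex,
                "age": rng.normal(65, 8, n),
                "lead_time": rng.uniform(0, 3, n),
            }
        )
        strat = fit_cox(df, pd.Series(x, index=df.index))
        from lifelines import CoxPHFitter

        pooled = CoxPHFitter()
        d2 = df[["surv_time", "death", "age"]].copy()
        d2["protein"] = x
        pooled.fit(d2, duration_col="surv_time", event_col="death")
        bias_strat = abs(strat.log_hr_at_dx - 0.3)
        bias_pooled = abs(pooled.params_["protein"] - 0.3)
        assert bias_strat < 0.07
        assert bias_pooled > 2 * bias_strat

    def test_no_events_rejected(self):
        df, x = simulate_survival(3, n=50)
        df["death"] = 0
        with pytest.raises(ValueError):
            fit_cox(df, x)


def test_default_table_covers_generator_categories():
    table = default_sojourn_table()
    for stage in (1, 2, 3, 4):
        for sex in ("M", "F"):
            for hist in ("adenocarcinoma", "squamous", "large_cell", "small_cell", "other"):
                assert table.sojourn(stage, sex, hist) > 0
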