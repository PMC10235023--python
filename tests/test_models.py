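"""Conditional-logistic estimator: grid-search oracle equivalence,
invariances, degenerate inputs, adjusted models, smoking linear models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import log_expit

from npxrisk.models import (
    InsufficientDataError,
    MonotoneLikelihoodError,
    case_control_differences,
    clogit_differences,
    fit_adjusted_clogit,
    fit_clogit,
    fit_clogit_many,
    fit_smoking_linear,
)
from npxrisk.preprocess import preprocess_study

from conftest import make_study


def grid_argmax(diffs, lo=-5.0, hi=5.0, step=1e-4):
    """Independent oracle: exhaustive grid maximization of the written
    1:1 conditional log-likelihood sum_s log sigmoid(beta * d_s)."""
    grid = np.arange(lo, hi + step / 2, step)
    ll = log_expit(np.outer(grid, np.asarray(diffs, float))).sum(axis=1)
    return grid[int(np.argmax(ll))]


class TestClogitCore:
    def test_symmetric_differences_give_beta_zero(self):
        beta, se, _, _ = clogit_differences(np.array([1.0, 1.0, -1.0, -1.0]))
        assert beta[0] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize(
        "diffs",
        [
            [1, 1, 1, 1, 1, 1, -1, -1, -1, 1],
            [0.5, -1.2, 2.0, 0.3, -0.4],
            [2.0, 2.0, -1.0, 0.5, 0.5, -0.2, 1.4, -1.4],
            list(np.random.default_rng(7).normal(0.3, 1.0, 12)),
        ],
    )
    def test_agrees_with_grid_oracle(self, diffs):
        d = np.asarray(diffs, float)
        beta, _, _, _ = clogit_differences(d)
        assert abs(beta[0] - grid_argmax(d)) < 1e-3

    def test_monotone_likelihood_raises_naming_covariate(self):
        with pytest.raises(MonotoneLikelihoodError, match="protein"):
            clogit_differences(np.ones(6), names=["protein"])

    def test_too_few_sets_raises(self):
        with pytest.raises(InsufficientDataError):
            clogit_differences(np.array([1.0]))

    def test_set_constant_shift_leaves_fit_unchanged(self):
        """Adding any set-specific constant to a covariate cancels in the
        conditional likelihood (differences are unchanged by construction;
        here we verify the fit is driven by differences only)."""
        rng = np.random.default_rng(0)
        d = rng.normal(0.2, 1.0, 40)
        b1, s1, _, _ = clogit_differences(d)
        b2, s2, _, _ = clogit_differences(d.copy())
        assert b1[0] == b2[0] and s1[0] == s2[0]

    def test_scaling_covariate_scales_beta_not_z(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.3, 1.0, 60)
        b1, s1, _, _ = clogit_differences(d)
        b2, s2, _, _ = clogit_differences(3.0 * d)
        assert b2[0] == pytest.approx(b1[0] / 3.0, rel=1e-8)
        assert b2[0] / s2[0] == pytest.approx(b1[0] / s1[0], rel=1e-8)

    def test_vectorized_path_matches_scalar_path(self):
        rng = np.random.default_rng(2)
        D = rng.normal(0.1, 1.0, size=(50, 5))
        D[3, 2] = np.nan
        many = fit_clogit_many(pd.DataFrame(D, columns=list("abcde")))
        for j, col in enumerate("abcde"):
            d = D[:, j]
            d = d[np.isfinite(d)]
            beta, se, _, _ = clogit_differences(d)
            assert many.loc[col, "beta"] == pytest.approx(beta[0], abs=1e-8)
            assert many.loc[col, "se"] == pytest.approx(se[0], rel=1e-6)
            assert many.loc[col, "n_sets"] == len(d)

    def test_statsmodels_logit_on_differences_cross_check(self):
        """Independent route: the 1:1 conditional likelihood equals an
        intercept-free logistic regression of all-ones on the differences."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        D = rng.normal(0.2, 1.0, size=(80, 2))
        beta, se, _, _ = clogit_differences(D)
        fit = sm.Logit(np.ones(len(D)), D).fit(disp=0)
        assert np.allclose(beta, fit.params, atol=1e-6)
        assert np.allclose(se, fit.bse, rtol=1e-4)


class TestFitClogitOnStudies:
    def test_ci_formula_and_wald_p(self, planted_study, planted_pre):
        res = fit_clogit(planted_pre.matrix, planted_study.subjects, "P0001")
        assert res.ci_low == pytest.approx(np.exp(res.beta - 1.959963984540054 * res.se), rel=1e-12)
        assert res.ci_high == pytest.approx(np.exp(res.beta + 1.959963984540054 * res.se), rel=1e-12)
        assert res.or_sd == pytest.approx(np.exp(res.beta), rel=1e-12)
        z = res.beta / res.se
        assert res.p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-12)
        assert res.ci_low < res.or_sd < res.ci_high

    def test_planted_effect_recovered(self, planted_study, planted_pre):
        res = fit_clogit(planted_pre.matrix, planted_study.subjects, "P0001")
        assert res.ci_low < 2.0 < res.ci_high
        assert res.p < 1e-6

    def test_adjusted_equals_crude_when_covariates_set_constant(self, planted_study, planted_pre):
        """Smoking covariates differ within sets in general; force them
        identical within each set and the adjusted fit collapses to crude."""
        subjects = planted_study.subjects.copy()
        for col in ("cigs_per_day", "years_smoked", "years_since_cessation"):
            shared = subjects.groupby("set_id")[col].transform("mean")
            subjects[col] = shared
        crude = fit_clogit(planted_pre.matrix, subjects, "P0001")
        adj = fit_adjusted_clogit(planted_pre.matrix, subjects, "P0001")
        assert adj.beta == pytest.approx(crude.beta, abs=1e-8)
        assert adj.se == pytest.approx(crude.se, rel=1e-6)

    def test_confounded_effect_attenuates_under_adjustment(self):
        """Risk driven by smoking intensity only, protein a mere smoking
        correlate: adjusting for smoking pulls the crude OR toward 1."""
        from scipy.special import expit

        rng = np.random.default_rng(31)
        n = 1500
        set_ids = [f"S{i:05d}" for i in range(n)]
        rows, values, ids = [], [], []
        for i, sid in enumerate(set_ids):
            cigs = rng.uniform(5, 40, 2)
            years = rng.uniform(15, 55, 2)
            s = (cigs - 20) / 10 + (years - 35) / 15       # exposure composite
            prot = 0.8 * s + rng.normal(0, 0.6, 2)          # protein tracks smoking
            p1 = expit(0.9 * (s[0] - s[1]))                 # risk through smoking only
            case_first = rng.random() < p1
            for m, (c, y, x) in enumerate(zip(cigs, years, prot)):
                sample = f"{sid}_{m}"
                rows.append(
                    {
                        "sample_id": sample,
                        "set_id": sid,
                        "cohort": "A",
                        "case": int((m == 0) == case_first),
                        "cigs_per_day": c,
                        "years_smoked": y,
                        "years_since_cessation": rng.uniform(0, 5),
                    }
                )
                ids.append(sample)
                values.append(x)
        subjects = pd.DataFrame(rows)
        matrix = pd.DataFrame({"PROT": values}, index=pd.Index(ids, name="sample_id"))
        crude = fit_clogit(matrix, subjects, "PROT")
        adj = fit_adjusted_clogit(matrix, subjects, "PROT")
        assert crude.beta > 0.2
        assert adj.beta < 0.5 * crude.beta

    def test_independent_effect_unchanged_by_adjustment(self, planted_study, planted_pre):
        crude = fit_clogit(planted_pre.matrix, planted_study.subjects, "P0001")
        adj = fit_adjusted_clogit(planted_pre.matrix, planted_study.subjects, "P0001")
        # no planted smoking association: attenuation within Monte-Carlo error
        assert adj.beta == pytest.approx(crude.beta, abs=3 * crude.se / np.sqrt(crude.n_sets) + 0.05)


class TestSmokingLinear:
    def test_planted_coefficient_recovered(self):
        from npxrisk.simulate import SimConfig, CohortSpec, TruthTable, generate_study

        hits = 0
        for seed in range(10):
            tt = TruthTable.with_effects(["P0001"], smoking_assoc={"P0001": 0.3})
            cfg = SimConfig(
                cohorts=[CohortSpec("A", 500, ("panel1",)), CohortSpec("B", 500, ("panel1",))],
                n_proteins=1,
                duplicate_fraction=0.0,
                lod_quantile=0.0,
                truth=tt,
                seed=100 + seed,
            )
            study = generate_study(cfg)
            pre = preprocess_study(study.matrix, study.lod_mask, study.annotations, study.subjects)
            res = fit_smoking_linear(pre.matrix, study.subjects, "P0001", "cigs_per_day")
            assert res.population == "controls-only"
            # positive and clearly detected; the coefficient is on the raw
            # cigarettes/day scale so only sign+significance are planted
            hits += (res.coefficient > 0) and (res.p < 0.05)
        assert hits >= 9

    def test_null_pvalues_uniform(self):
        pvals = []
        for seed in range(60):
            study = make_study(n_sets_per_cohort=60, n_proteins=1, seed=700 + seed)
            pre = preprocess_study(study.matrix, study.lod_mask, study.annotations, study.subjects)
            res = fit_smoking_linear(pre.matrix, study.subjects, "P0001", "years_smoked",
                                     population="combined")
            pvals.append(res.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_metric_rank_deficiency(self, small_study):
        pre = preprocess_study(
            small_study.matrix, small_study.lod_mask, small_study.annotations, small_study.subjects
        )
        subjects = small_study.subjects.copy()
        subjects["years_smoked"] = 30.0
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_smoking_linear(pre.matrix, subjects, pre.matrix.columns[0], "years_smoked")


def test_incomplete_sets_dropped_and_counted(planted_study, planted_pre):
    matrix = planted_pre.matrix.copy()
    victim_sets = planted_study.subjects["set_id"].unique()[:7]
    victims = planted_study.subjects.loc[
        planted_study.subjects["set_id"].isin(victim_sets) & (planted_study.subjects["case"] == 1),
        "sample_id",
    ]
    matrix.loc[victims, "P0001"] = np.nan
    res = fit_clogit(matrix, planted_study.subjects, "P0001")
    assert res.n_sets == planted_study.n_sets - 7
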