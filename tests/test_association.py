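"""Survival-time construction, Cox/logistic fits, KM curves, diagnostics."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from apoekit.association import (
    ModelFit,
    SurvivalConfig,
    build_survival_times,
    fit_cox,
    fit_logistic,
    km_by_dose,
    schoenfeld_diagnostics,
)
from apoekit.simulate import SimulationConfig, simulate_cohort


class TestBuildSurvivalTimes:
    @staticmethod
    def _cohort():
        return pd.DataFrame(
            {
                "sample_id": ["case", "control", "early_case"],
                "diplotype": ["e3/e4", "e3/e3", "e4/e4"],
                "dementia_status": [True, False, True],
                "age_at_diagnosis": [73.3, np.nan, 55.0],
                "birth_year": [1950.0, 1980.0, 1958.0],
                "age_at_recruitment": [70.0, 40.0, 62.0],
            }
        )

    def test_case_time_from_age_sixteen(self):
        surv = build_survival_times(self._cohort(), SurvivalConfig())
        row = surv[surv.sample_id == "case"].iloc[0]
        assert row["duration"] == pytest.approx(73.3 - 16)
        assert bool(row["event"])

    def test_control_censored_at_admin_date(self):
        surv = build_survival_times(self._cohort(), SurvivalConfig())
        row = surv[surv.sample_id == "control"].iloc[0]
        assert row["duration"] == pytest.approx(2024.92 - 1980 - 16)
        assert not bool(row["event"])

    def test_late_origin_excludes_early_case(self):
        config = SurvivalConfig(origin_age=60.0,
                                restrict_to_recruited_after_origin=True)
        surv = build_survival_times(self._cohort(), config)
        assert "early_case" not in set(surv.sample_id)
        assert "control" not in set(surv.sample_id)  # recruited at 40
        assert set(surv.sample_id) == {"case"}

    def test_e1_carriers_excluded_by_default(self):
        cohort = self._cohort()
        cohort.loc[0, "diplotype"] = "e1/e3"
        surv = build_survival_times(cohort, SurvivalConfig())
        assert "case" not in set(surv.sample_id)
        kept = build_survival_times(cohort, SurvivalConfig(exclude_e1=False))
        assert "case" in set(kept.sample_id)

    def test_left_truncation_entry_column(self):
        surv = build_survival_times(
            self._cohort(), SurvivalConfig(left_truncation=True)
        )
        row = surv[surv.sample_id == "control"].iloc[0]
        assert row["entry"] == pytest.approx(40.0 - 16.0)


@pytest.fixture(scope="module")
def cox_fit(small_cohort):
    return fit_cox(small_cohort, SurvivalConfig())


class TestCoxModel:
    def test_reference_emits_no_term(self, cox_fit):
        terms = {r.term for r in cox_fit.results}
        assert "e3/e3" not in terms

    def test_sample_order_invariance(self, small_cohort):
        shuffled = small_cohort.sample(frac=1.0, random_state=0)
        a = fit_cox(small_cohort, SurvivalConfig(coding="additive"))
        b = fit_cox(shuffled, SurvivalConfig(coding="additive"))
        assert a.result("e4_dose").estimate == pytest.approx(
            b.result("e4_dose").estimate, abs=1e-10
        )

    def test_matches_r_coxph_oracle(self, tmp_path, small_cohort):
        """Efron-ties partial likelihood against survival::coxph."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        config = SurvivalConfig(covariates=("age_at_recruitment", "gender"),
                                coding="additive")
        fit = fit_cox(small_cohort, config)
        fit.data.to_csv(tmp_path / "d.tsv", sep="\t", index=False)
        script = (
            "library(survival);"
            f"d <- read.delim('{tmp_path / 'd.tsv'}');"
            "m <- coxph(Surv(duration, event) ~ e4_dose + "
            "age_at_recruitment + male, data=d, ties='efron');"
            "cat(sprintf('%.10f %.10f', coef(m)['e4_dose'], "
            "sqrt(vcov(m)['e4_dose','e4_dose'])))"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True).stdout.split()
        r_coef, r_se = float(out[0]), float(out[1])
        assert fit.result("e4_dose").estimate == pytest.approx(r_coef,
                                                               abs=1e-5)
        assert fit.result("e4_dose").se == pytest.approx(r_se, abs=1e-5)

    def test_zero_event_category_flagged(self, study_cohort):
        # e2/e2 is so rare that many study-scale cohorts have no such case
        fit = fit_cox(study_cohort, SurvivalConfig())
        flagged = {r.term for r in fit.results
                   if "non_estimable" in r.flags}
        estimable = {r.term for r in fit.results if np.isfinite(r.estimate)}
        assert {"e3/e4", "e4/e4"} <= estimable
        assert flagged == set(fit.dropped_terms)

    def test_gender_stratified_returns_per_stratum_fits(self, small_cohort):
        fits = fit_cox(small_cohort,
                       SurvivalConfig(coding="additive",
                                      stratify_gender=True))
        assert set(fits) == {"male", "female"}
        for fit in fits.values():
            assert "male" not in {r.term for r in fit.results}
            assert np.isfinite(fit.result("e4_dose").estimate)

    def test_additive_between_het_and_hom_on_log_scale(self):
        """Per-allele estimate brackets the genotypic contrasts when the
        truth is exactly multiplicative per allele."""
        log_h = math.log(1.8)
        config = SimulationConfig(
            n_samples=30_000,
            baseline_hazard=3e-3,
            true_log_hr={"e2/e2": 0.0, "e2/e3": 0.0, "e3/e3": 0.0,
                         "e2/e4": log_h, "e3/e4": log_h, "e4/e4": 2 * log_h},
            seed=23,
        )
        cohort = simulate_cohort(config)
        genotypic = fit_cox(cohort, SurvivalConfig())
        additive = fit_cox(cohort, SurvivalConfig(coding="additive"))
        het = genotypic.result("e3/e4").estimate
        hom = genotypic.result("e4/e4").estimate / 2
        dose = additive.result("e4_dose").estimate
        assert min(het, hom) - 0.05 <= dose <= max(het, hom) + 0.05


class TestLogisticModel:
    def test_reference_change_identity(self, rich_e2_cohort):
        """log OR(e4/e4 vs e2/e2) equals the difference of the e3/e3-
        referenced contrasts; both parameterise the same likelihood."""
        vs_e33 = fit_logistic(rich_e2_cohort, SurvivalConfig())
        vs_e22 = fit_logistic(rich_e2_cohort,
                              SurvivalConfig(reference="e2/e2"))
        direct = vs_e22.result("e4/e4").estimate
        composed = (vs_e33.result("e4/e4").estimate
                    - vs_e33.result("e2/e2").estimate)
        assert direct == pytest.approx(composed, abs=1e-5)

    def test_rare_outcome_or_approximates_hr(self):
        config = SimulationConfig(n_samples=40_000, baseline_hazard=1e-3,
                                  seed=24)
        cohort = simulate_cohort(config)
        cox = fit_cox(cohort, SurvivalConfig(coding="additive"))
        logit = fit_logistic(cohort, SurvivalConfig(coding="additive"))
        hr = cox.result("e4_dose").ratio
        orr = logit.result("e4_dose").ratio
        assert abs(math.log(orr) - math.log(hr)) < 0.1

    def test_no_reference_cases_flagged(self):
        # constructed cohort where the e2/e2 reference has zero cases
        rng = np.random.default_rng(5)
        n = 2000
        dips = np.array(["e2/e2"] * 100 + ["e3/e3"] * 1500 +
                        ["e3/e4"] * 300 + ["e2/e3"] * 50 +
                        ["e2/e4"] * 25 + ["e4/e4"] * 25)
        status = rng.random(n) < 0.05
        status[dips == "e2/e2"] = False
        cohort = pd.DataFrame({
            "diplotype": dips, "dementia_status": status,
            "gender": np.where(rng.random(n) < 0.5, "male", "female"),
            "ancestry": "Bangladeshi",
            "age_at_recruitment": rng.uniform(20, 70, n),
            **{f"pc{i}": rng.standard_normal(n) for i in range(1, 11)},
        })
        fit = fit_logistic(cohort, SurvivalConfig(reference="e2/e2"))
        genotype_flags = [r.flags for r in fit.results
                          if "/" in r.term and "non_estimable" not in r.flags]
        assert genotype_flags
        assert all("reference_no_events" in f for f in genotype_flags)


class TestKaplanMeier:
    def test_no_events_constant_one(self, small_cohort):
        cohort = small_cohort.copy()
        cohort["dementia_status"] = False
        cohort["age_at_diagnosis"] = np.nan
        curves = km_by_dose(cohort, SurvivalConfig())
        for frame in curves.values():
            assert (frame["survival"] == 1.0).all()

    def test_curves_start_at_one_and_decrease(self, small_cohort):
        curves = km_by_dose(small_cohort, SurvivalConfig())
        for frame in curves.values():
            s = frame["survival"].to_numpy()
            assert s[0] == 1.0
            assert (np.diff(s) <= 1e-12).all()

    def test_single_event_step_size(self):
        cohort = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(10)],
            "diplotype": ["e3/e3"] * 10,
            "dementia_status": [True] + [False] * 9,
            "age_at_diagnosis": [50.0] + [np.nan] * 9,
            "birth_year": [1950.0] * 10,
            "age_at_recruitment": [40.0] * 10,
        })
        curves = km_by_dose(cohort, SurvivalConfig())
        frame = curves[0]
        at_event = frame.loc[frame.index >= 34.0, "survival"].iloc[0]
        assert at_event == pytest.approx(1 - 1 / 10)

    def test_high_dose_curve_dominated(self, study_cohort):
        curves = km_by_dose(study_cohort, SurvivalConfig())
        joint = curves[0].join(curves[2], how="inner",
                               lsuffix="_0", rsuffix="_2")
        late = joint[joint.index > 40]
        assert (late["survival_2"] <= late["survival_0"] + 1e-12).all()


class TestSchoenfeldDiagnostics:
    def test_reports_per_covariate_and_global(self, cox_fit):
        diag = schoenfeld_diagnostics(cox_fit)
        assert "GLOBAL" in diag.index
        assert diag.loc["GLOBAL", "df"] == len(diag) - 1
        assert ((diag["p"] >= 0) & (diag["p"] <= 1)).all()

    def test_few_events_skipped(self, small_cohort):
        tiny = pd.concat([
            small_cohort[small_cohort.dementia_status].head(3),
            small_cohort[~small_cohort.dementia_status].head(200),
        ])
        fit = fit_cox(tiny, SurvivalConfig(coding="additive",
                                           covariates=("gender",)))
        assert schoenfeld_diagnostics(fit) is None

    def test_null_calibration_of_global_test(self):
        """Under exact proportional hazards the global test rejects at
        roughly the nominal 5% rate."""
        rejections = 0
        n_seeds = 60
        for seed in range(n_seeds):
            config = SimulationConfig(
                n_samples=1500, baseline_hazard=4e-3, seed=300 + seed
            )
            cohort = simulate_cohort(config)
            fit = fit_cox(cohort, SurvivalConfig(
                coding="additive",
                covariates=("age_at_recruitment", "gender", "pc1"),
            ))
            diag = schoenfeld_diagnostics(fit)
            rejections += diag.loc["GLOBAL", "p"] < 0.05
        rate = rejections / n_seeds
        se = math.sqrt(0.05 * 0.95 / n_seeds)
        assert rate < 0.05 + 3 * se

    def test_power_against_time_varying_effect(self):
        """A covariate whose effect reverses over follow-up must be
        detected; effect +1 before the median event time, -1 after."""
        rng = np.random.default_rng(9)
        n = 20_000
        x = rng.integers(0, 2, n).astype(float)
        # piecewise-constant hazard: rate exp(x) before t=5, exp(-x) after
        t1 = rng.exponential(1 / (0.05 * np.exp(x)))
        t2 = 5 + rng.exponential(1 / (0.05 * np.exp(-x)))
        t = np.where(t1 < 5, t1, t2)
        event = t < 30
        data = pd.DataFrame({
            "duration": np.minimum(t, 30.0), "event": event.astype(int),
            "x": x,
        })
        from lifelines import CoxPHFitter

        cph = CoxPHFitter().fit(data, "duration", "event")
        fit = ModelFit(results=[], model="cox_tv", fitter=cph, data=data)
        diag = schoenfeld_diagnostics(fit)
        assert diag.loc["GLOBAL", "p"] < 1e-6
        assert diag.loc["x", "p"] < 1e-6
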