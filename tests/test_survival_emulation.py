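import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reposign.survival_emulation import (
    CohortError,
    FitError,
    build_cohort,
    code_matches,
    _compile_patterns,
    cox_fit,
    duration_sensitivity,
    km_estimator,
    long_short_term_contrast,
    negative_control,
    ph_test,
    propensity_match,
    standardized_mean_differences,
)
from reposign.synthetic_data import (
    gen_survival_cohort,
    healthy_user_confounding,
)

UC_DX = ["556.x", "K51.x"]
EXCLUSION = ["153.x", "555.x"]
OUTCOME = ["45.8"]  # colectomy procedure code
EXPOSURE = ["atorvastatin"]
COMPARATOR = ["losartan", "metformin"]


def _ev(sid, date, kind, code):
    return {"subject_id": sid, "date": date, "kind": kind, "code": code}


@pytest.fixture
def event_stream():
    """Six hand-written subjects, one per inclusion/exclusion rule.

    A: diagnosed, atorvastatin after dx, colectomy later        -> treated, event
    B: diagnosed, losartan after dx, censored at last visit     -> comparator, censored
    C: prescription before diagnosis only                       -> excluded
    D: carries an exclusion diagnosis (Crohn's 555.9)           -> excluded
    E: no qualifying diagnosis                                  -> excluded
    F: colectomy on the index date (time must be positive)      -> excluded
    """
    rows = [
        # A: index 2010-02-01, colectomy 2010-08-01 -> time 181, event
        _ev("A", "2010-01-01", "dx", "556.9"),
        _ev("A", "2010-02-01", "rx", "atorvastatin"),
        _ev("A", "2010-08-01", "px", "45.8"),
        # B: index 2011-03-10, last visit 2012-03-10 -> time 366, censored
        _ev("B", "2011-01-10", "dx", "K51.0"),
        _ev("B", "2011-03-10", "rx", "losartan"),
        _ev("B", "2012-03-10", "visit", "v"),
        # C: rx predates diagnosis
        _ev("C", "2010-01-01", "rx", "atorvastatin"),
        _ev("C", "2010-06-01", "dx", "556.9"),
        # D: exclusion diagnosis
        _ev("D", "2010-01-01", "dx", "556.9"),
        _ev("D", "2010-02-01", "dx", "555.9"),
        _ev("D", "2010-03-01", "rx", "atorvastatin"),
        # E: no qualifying dx
        _ev("E", "2010-01-01", "dx", "401.9"),
        _ev("E", "2010-02-01", "rx", "losartan"),
        # F: outcome on index date
        _ev("F", "2010-01-01", "dx", "556.9"),
        _ev("F", "2010-02-01", "rx", "atorvastatin"),
        _ev("F", "2010-02-01", "px", "45.8"),
    ]
    return pd.DataFrame(rows)


class TestCodeMatching:
    def test_prefix_and_exact(self):
        pats = _compile_patterns(["153.x", "230.3", "K51.x"])
        assert code_matches("153.4", pats)
        assert code_matches("153", pats)
        assert code_matches("230.3", pats)
        assert not code_matches("230.31", pats)
        assert code_matches("K51.9", pats)
        assert not code_matches("K52.9", pats)

    def test_packaged_exclusion_codes(self):
        from importlib import resources
        from reposign.survival_emulation import load_code_list
        with resources.as_file(
            resources.files("reposign.data").joinpath("exclusion_codes.txt")
        ) as p:
            codes = load_code_list(p)
        pats = _compile_patterns(codes)
        assert code_matches("555.9", pats)    # Crohn's
        assert code_matches("C18.4", pats)    # colorectal cancer
        assert not code_matches("556.9", pats)  # UC itself is not excluded


class TestBuildCohort:
    def test_hand_worked_fixture(self, event_stream):
        cohort, attrition = build_cohort(
            event_stream, UC_DX, EXPOSURE, COMPARATOR, EXCLUSION, OUTCOME
        )
        assert attrition["included"] == 2
        assert attrition["rx_only_before_dx"] == 1
        assert attrition["exclusion_dx"] == 1
        assert attrition["no_diagnosis"] == 1
        assert attrition["prior_or_index_outcome"] == 1
        cohort = cohort.set_index("subject_id")
        assert set(cohort.index) == {"A", "B"}
        assert cohort.loc["A", "exposure"] == 1
        assert cohort.loc["A", "event"] == 1
        assert cohort.loc["A", "time_days"] == 181.0
        assert cohort.loc["B", "exposure"] == 0
        assert cohort.loc["B", "event"] == 0
        assert cohort.loc["B", "time_days"] == 366.0

    def test_both_drug_classes_assigned_to_treatment_at_first_exposure(self):
        rows = [
            _ev("X", "2010-01-01", "dx", "556.9"),
            _ev("X", "2010-02-01", "rx", "losartan"),
            _ev("X", "2010-05-01", "rx", "atorvastatin"),
            _ev("X", "2011-01-01", "visit", "v"),
        ]
        cohort, attrition = build_cohort(
            pd.DataFrame(rows), UC_DX, EXPOSURE, COMPARATOR, EXCLUSION, OUTCOME
        )
        assert attrition["both_drug_classes"] == 1
        row = cohort.iloc[0]
        assert row["exposure"] == 1
        assert row["index_date"] == pd.Timestamp("2010-05-01")

    def test_covariates_and_demographics(self, event_stream):
        demo = pd.DataFrame({
            "subject_id": ["A", "B"],
            "birth_date": ["1950-02-01", "1980-03-10"],
            "sex": ["F", "M"],
        })
        cohort, _ = build_cohort(
            event_stream, UC_DX, EXPOSURE, COMPARATOR, EXCLUSION, OUTCOME,
            demographics=demo,
            comorbidity_codes={"cad": ["414.x"]},
        )
        cohort = cohort.set_index("subject_id")
        assert cohort.loc["A", "sex"] == 0 and cohort.loc["B", "sex"] == 1
        assert np.isclose(cohort.loc["A", "age"], 60.0, atol=0.1)
        assert cohort.loc["A", "cad"] == 0
        assert cohort.loc["B", "rx_losartan"] == 1
        assert cohort.loc["A", "rx_losartan"] == 0

    def test_extra_outcome_columns(self, event_stream):
        cohort, _ = build_cohort(
            event_stream, UC_DX, EXPOSURE, COMPARATOR, EXCLUSION, OUTCOME,
            extra_outcomes={"pneumonia": ["486"]},
        )
        assert {"time_pneumonia_days", "event_pneumonia"} <= set(cohort.columns)
        assert (cohort["event_pneumonia"] == 0).all()


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimator([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.allclose(km["survival"], [2 / 3, 1 / 3, 0.0])

    def test_no_events_flat_survival(self):
        km = km_estimator([1.0, 2.0], [0, 0])
        assert km.empty  # no event rows; survival stays 1 throughout

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines import KaplanMeierFitter
        t = rng.exponential(100, 300).round(0) + 1  # induce ties
        e = rng.random(300) < 0.7
        km = km_estimator(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_.loc[km["t"], "KM_estimate"].to_numpy()
        assert np.allclose(km["survival"].to_numpy(), ref, atol=1e-12)

    def test_survival_non_increasing_from_one(self, rng):
        t = rng.exponential(50, 200)
        e = rng.random(200) < 0.5
        km = km_estimator(t, e)
        s = km["survival"].to_numpy()
        assert (s <= 1.0).all()
        assert (np.diff(s) <= 1e-12).all()


def toy_no_ties():
    return pd.DataFrame({
        "time_days": [2.0, 3.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0],
        "event": [1, 1, 0, 1, 1, 0, 1, 1],
        "exposure": [1, 0, 1, 0, 1, 0, 1, 0],
    })


class TestCoxFit:
    def test_matches_brute_force_grid_maximization(self):
        data = toy_no_ties()
        fit = cox_fit(data, ["exposure"])

        def neg_partial_loglik(b):
            # written out directly from the definition, no ties
            t = data["time_days"].to_numpy()
            d = data["event"].to_numpy().astype(bool)
            x = data["exposure"].to_numpy()
            ll = 0.0
            for i in np.flatnonzero(d):
                risk = t >= t[i]
                ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
            return -ll

        from scipy.optimize import minimize_scalar
        res = minimize_scalar(neg_partial_loglik, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert abs(fit.coef["exposure"] - res.x) < 1e-6
        assert np.isclose(fit.loglik, -neg_partial_loglik(res.x), atol=1e-9)

    def test_matches_lifelines_multivariate(self):
        from lifelines import CoxPHFitter
        cohort, _ = gen_survival_cohort(400, true_hr=0.7, seed=7)
        covs = ["exposure", "age", "sex", "comorbidity_1"]
        fit = cox_fit(cohort, covs)
        cph = CoxPHFitter().fit(cohort[["time_days", "event"] + covs],
                                "time_days", "event")
        for c in covs:
            assert abs(fit.coef[c] - cph.params_[c]) < 1e-4
            assert abs(fit.se[c] - cph.standard_errors_[c]) < 1e-4

    def test_efron_ties_match_lifelines(self):
        from lifelines import CoxPHFitter
        cohort, _ = gen_survival_cohort(300, true_hr=0.6, seed=8)
        cohort["time_days"] = np.ceil(cohort["time_days"] / 150) * 150  # heavy ties
        fit = cox_fit(cohort, ["exposure", "age"])
        cph = CoxPHFitter().fit(cohort[["time_days", "event", "exposure", "age"]],
                                "time_days", "event")
        assert abs(fit.coef["exposure"] - cph.params_["exposure"]) < 1e-4

    def test_breslow_ties_match_reference(self):
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        cohort, _ = gen_survival_cohort(300, true_hr=0.6, seed=8)
        cohort["time_days"] = np.ceil(cohort["time_days"] / 150) * 150
        fit = cox_fit(cohort, ["exposure", "age"], ties="breslow")
        y = np.array(
            [(bool(e), t) for e, t in zip(cohort["event"], cohort["time_days"])],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        ref = CoxPHSurvivalAnalysis(ties="breslow").fit(
            cohort[["exposure", "age"]].to_numpy(), y
        )
        assert np.allclose(
            [fit.coef["exposure"], fit.coef["age"]], ref.coef_, atol=1e-4
        )

    def test_duplicated_covariate_is_singular(self):
        data = toy_no_ties()
        data["exposure2"] = data["exposure"]
        with pytest.raises(FitError, match="singular|collinear"):
            cox_fit(data, ["exposure", "exposure2"])

    def test_time_scaling_invariance(self):
        data = toy_no_ties()
        fit1 = cox_fit(data, ["exposure"])
        data2 = data.assign(time_days=data["time_days"] * 2)
        fit2 = cox_fit(data2, ["exposure"])
        assert np.isclose(fit1.coef["exposure"], fit2.coef["exposure"], atol=1e-12)

    def test_sign_matches_logrank_direction(self, rng):
        from lifelines.statistics import logrank_test
        cohort, _ = gen_survival_cohort(300, true_hr=0.5, seed=15)
        fit = cox_fit(cohort, ["exposure"])
        lr = logrank_test(
            cohort.loc[cohort.exposure == 1, "time_days"],
            cohort.loc[cohort.exposure == 0, "time_days"],
            cohort.loc[cohort.exposure == 1, "event"],
            cohort.loc[cohort.exposure == 0, "event"],
        )
        assert fit.coef["exposure"] < 0 and lr.p_value < 0.05

    def test_no_events_rejected(self):
        data = toy_no_ties().assign(event=0)
        with pytest.raises(FitError):
            cox_fit(data, ["exposure"])

    def test_ci_coverage_at_true_hr(self):
        hits = 0
        for s in range(200):
            cohort, _ = gen_survival_cohort(400, true_hr=0.66, censor_rate=0.3,
                                            seed=3000 + s, control_outcome=False)
            fit = cox_fit(cohort, ["exposure"])
            lo, hi = fit.ci95["exposure"]
            hits += lo <= 0.66 <= hi
        assert 180 <= hits <= 198  # 90-99% coverage of the 95% CI


class TestPHTest:
    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter
        from lifelines.statistics import proportional_hazard_test
        cohort, _ = gen_survival_cohort(400, true_hr=0.7, seed=7)
        covs = ["exposure", "age", "sex"]
        fit = cox_fit(cohort, covs)
        mine = ph_test(fit, time_transform="km")
        cph = CoxPHFitter().fit(cohort[["time_days", "event"] + covs],
                                "time_days", "event")
        ref = proportional_hazard_test(cph, cohort[["time_days", "event"] + covs],
                                       time_transform="km")
        for c in covs:
            assert np.isclose(mine[c], ref.summary.loc[c, "p"], rtol=0.05, atol=0.005)

    def test_uniform_under_proportional_hazards(self):
        ps = []
        for s in range(200):
            cohort, _ = gen_survival_cohort(150, true_hr=1.0, censor_rate=0.2,
                                            seed=5000 + s, control_outcome=False)
            fit = cox_fit(cohort, ["exposure"])
            ps.append(ph_test(fit)["exposure"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_time_varying_effect(self, rng):
        # exposure protects early and harms late: a strong PH violation
        rejections = 0
        for s in range(40):
            r = np.random.default_rng(s)
            n = 300
            expo = r.integers(0, 2, n)
            lam_early = np.where(expo, 0.004, 0.01)
            lam_late = np.where(expo, 0.02, 0.01)
            t1 = r.exponential(1 / lam_early)
            t = np.where(t1 < 100, t1, 100 + r.exponential(1 / lam_late))
            cohort = pd.DataFrame({"time_days": t, "event": 1, "exposure": expo})
            fit = cox_fit(cohort, ["exposure"])
            rejections += ph_test(fit)["exposure"] < 0.05
        assert rejections >= 32  # >= 80% power


class TestPropensityMatch:
    def test_identical_covariates_keep_near_zero_smds(self):
        cohort, _ = gen_survival_cohort(1500, true_hr=1.0, seed=30)  # no confounding
        covs = ["age", "sex", "comorbidity_1"]
        matched, balance = propensity_match(cohort, covs, seed=0)
        assert (balance["smd_before"].abs() < 0.12).all()
        assert (balance["smd_after"].abs() < 0.12).all()

    def test_strong_confounding_balanced_after_matching(self):
        cohort, _ = gen_survival_cohort(
            4000, true_hr=0.7, exposure_prob=0.25,
            confounders=healthy_user_confounding(1.0), seed=11,
        )
        covs = ["age", "comorbidity_1", "comorbidity_2", "comorbidity_3"]
        matched, balance = propensity_match(cohort, covs + ["sex"], seed=0)
        assert (balance.loc[covs, "smd_before"].abs() > 0.3).all()
        assert (balance["smd_after"].abs() < 0.1).all()

    def test_without_replacement_when_treated_majority(self):
        cohort, _ = gen_survival_cohort(600, true_hr=1.0, exposure_prob=0.7, seed=31)
        n_comp = int((cohort["exposure"] == 0).sum())
        matched, _ = propensity_match(cohort, ["age", "sex"], seed=0)
        assert (matched["exposure"] == 0).sum() == n_comp
        assert matched[matched["exposure"] == 0]["subject_id"].is_unique

    def test_no_comparators_rejected(self):
        cohort, _ = gen_survival_cohort(100, true_hr=1.0, seed=32)
        with pytest.raises(CohortError):
            propensity_match(cohort[cohort["exposure"] == 1], ["age"], seed=0)


class TestDurationAnalyses:
    @staticmethod
    def _cohort_with_durations(seed=40, duration_dependent=False, n=4000):
        """Treated subjects get an on-therapy duration; optionally only
        long-term therapy (>= 183 days) confers the protective effect."""
        r = np.random.default_rng(seed)
        expo = r.integers(0, 2, n)
        dur = np.where(expo == 1, r.exponential(300, n), 0.0)
        if duration_dependent:
            hr = np.where((expo == 1) & (dur >= 183), 0.4, 1.0)
        else:
            hr = np.where(expo == 1, 0.6, 1.0)
        lam = (1 / 1500) * hr
        t = r.exponential(1 / lam)
        c = r.exponential(3000, n)
        cohort = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "exposure": expo,
            "time_days": np.minimum(t, c),
            "event": (t <= c).astype(int),
        })
        durations = pd.Series(dur, index=cohort["subject_id"].to_numpy())
        return cohort, durations

    def test_zero_threshold_identical_to_unrestricted(self):
        cohort, dur = self._cohort_with_durations()
        grid = duration_sensitivity(cohort, dur, [0.0], covariate_names=["exposure"])
        full = cox_fit(cohort, ["exposure"])
        assert np.isclose(grid.loc[0, "hr"], full.hr["exposure"], atol=1e-12)

    def test_duration_independent_effect_stable_across_grid(self):
        cohort, dur = self._cohort_with_durations(duration_dependent=False)
        grid = duration_sensitivity(cohort, dur, [0, 30, 90, 180, 365],
                                    covariate_names=["exposure"])
        assert grid["stable"].all()
        # every grid HR falls inside every other grid point's 95% CI
        for _, a in grid.iterrows():
            for _, b in grid.iterrows():
                assert b["hr_lo95"] <= a["hr"] <= b["hr_hi95"]

    def test_extreme_threshold_marked_unstable(self):
        cohort, dur = self._cohort_with_durations(n=300)
        grid = duration_sensitivity(cohort, dur, [1e9], covariate_names=["exposure"])
        assert not grid.loc[0, "stable"]

    def test_long_term_effect_detected_in_contrast(self):
        cohort, dur = self._cohort_with_durations(duration_dependent=True)
        fit = long_short_term_contrast(cohort, dur, min_followup_days=720)
        assert fit.hr["long_term"] < 1.0
        assert fit.ci95["long_term"][1] < 1.0


class TestNegativeControl:
    def test_identical_outcome_identical_fit(self):
        cohort, _ = gen_survival_cohort(800, true_hr=0.6, seed=50)
        cohort["time_control_days"] = cohort["time_days"]
        cohort["event_control"] = cohort["event"]
        primary = cox_fit(cohort, ["exposure"])
        control = negative_control(cohort, ["exposure"])
        assert np.isclose(primary.coef["exposure"], control.coef["exposure"], atol=1e-12)

    def test_missing_columns_rejected(self):
        cohort, _ = gen_survival_cohort(100, true_hr=1.0, seed=51, control_outcome=False)
        with pytest.raises(CohortError):
            negative_control(cohort, ["exposure"])
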