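"""Onset summaries, exposure classification, counting-process construction,
and time-varying Cox fits with robust clustered errors."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_cohort
from riskhapscan.dosage import firth_logistic
from riskhapscan.simulate import simulate_survival_cohort
from riskhapscan.survival import (
    ExposureDefinition,
    build_counting_process,
    carriers_subset,
    classify_exposure,
    cox_tv_fit,
    firth_modifier_model,
    onset_summary,
    ph_check,
)

DEF5 = ExposureDefinition(landmark_years=5.0)
DEF2 = ExposureDefinition(landmark_years=2.0)


def case(onset, **kw):
    base = {"status": "case", "age_onset_years": onset,
            "age_last_followup_years": onset + 1.0}
    base.update(kw)
    return base


class TestOnsetSummary:
    def test_single_case_degenerate(self):
        df = make_cohort([case(3.0, sex="F")]).table
        (s,) = onset_summary(df)
        assert (s.median, s.q25, s.q75) == (3.0, 3.0, 3.0)

    def test_five_point_median(self):
        df = make_cohort([case(float(a), sex="M") for a in range(1, 6)]).table
        (s,) = onset_summary(df)
        assert s.median == 3.0

    def test_quantiles_match_numpy_oracle(self, rng):
        ages = np.round(rng.uniform(0.5, 8.0, size=23), 2)
        df = make_cohort([case(float(a), sex="M",
                               age_last_followup_years=12.0)
                          for a in ages]).table
        (s,) = onset_summary(df)
        srt = np.sort(ages)
        assert s.q25 == pytest.approx(np.quantile(srt, 0.25))
        assert s.median == pytest.approx(np.quantile(srt, 0.5))
        assert s.q75 == pytest.approx(np.quantile(srt, 0.75))


class TestExposure:
    def row(self, **kw):
        base = dict(dog_id="d", status="case", age_onset_years=4.0,
                    gonadal_status="gonadectomized",
                    age_gonadectomy_years=2.0)
        base.update(kw)
        return base

    def test_pre_onset_pre_landmark_exposed(self):
        assert classify_exposure(self.row(), DEF5) is True

    def test_post_onset_unexposed(self):
        r = self.row(age_gonadectomy_years=3.0, age_onset_years=2.5)
        assert classify_exposure(r, DEF5) is False

    def test_late_control_unexposed(self):
        r = self.row(status="control", age_onset_years=np.nan,
                     age_gonadectomy_years=6.0)
        assert classify_exposure(r, DEF5) is False

    def test_intact_unexposed(self):
        r = self.row(gonadal_status="intact", age_gonadectomy_years=np.nan)
        assert classify_exposure(r, DEF5) is False

    def test_stricter_landmark_is_subset(self, rng):
        rows = []
        for _ in range(200):
            onset = float(rng.uniform(0.5, 8))
            rows.append(self.row(
                status=rng.choice(["case", "control"]),
                age_onset_years=onset,
                age_gonadectomy_years=float(rng.uniform(0.2, 8)),
            ))
            if rows[-1]["status"] == "control":
                rows[-1]["age_onset_years"] = np.nan
        e2 = {i for i, r in enumerate(rows) if classify_exposure(r, DEF2)}
        e5 = {i for i, r in enumerate(rows) if classify_exposure(r, DEF5)}
        assert e2 <= e5


class TestCountingProcess:
    def test_case_neutered_before_onset_two_intervals(self):
        df = make_cohort([case(4.0, gonadal_status="gonadectomized",
                               age_gonadectomy_years=2.0)]).table
        cp = build_counting_process(df, DEF5)
        assert len(cp) == 2
        assert cp.iloc[0][["start", "stop", "exposed", "event"]].tolist() == \
            [0.0, 2.0, 0, 0]
        assert cp.iloc[1][["start", "stop", "exposed", "event"]].tolist() == \
            [2.0, 4.0, 1, 1]

    def test_intact_control_single_interval(self):
        df = make_cohort([{"status": "control",
                           "age_last_followup_years": 8.0}]).table
        cp = build_counting_process(df, DEF5)
        assert len(cp) == 1
        assert cp.iloc[0][["start", "stop", "exposed", "event"]].tolist() == \
            [0.0, 8.0, 0, 0]

    def test_post_onset_neuter_single_interval(self):
        df = make_cohort([case(3.0, age_last_followup_years=6.0,
                               gonadal_status="gonadectomized",
                               age_gonadectomy_years=4.5)]).table
        cp = build_counting_process(df, DEF5)
        assert len(cp) == 1
        assert cp.iloc[0][["start", "stop", "exposed", "event"]].tolist() == \
            [0.0, 3.0, 0, 1]

    def test_rows_partition_zero_to_endpoint(self, rng):
        cohort = simulate_survival_cohort(120, seed=5, male_log_HR=0.5,
                                          gonadectomy_log_HR=0.4)
        df = cohort.table.copy()
        df["dosage"] = 1
        cp = build_counting_process(df, DEF5)
        for dog, sub in cp.groupby("dog_id"):
            sub = sub.sort_values("start")
            assert sub.start.iloc[0] == 0.0
            assert np.all(sub.stop.to_numpy()[:-1] == sub.start.to_numpy()[1:])
            assert sub.exposed.is_monotonic_increasing
        assert cp.event.sum() == (df.status == "case").sum()

    def test_neuter_at_endpoint_single_unexposed_interval(self):
        df = make_cohort([case(4.0, gonadal_status="gonadectomized",
                               age_gonadectomy_years=4.0)]).table
        cp = build_counting_process(df, DEF5)
        assert len(cp) == 1
        assert cp.attrs["zero_length_dropped"] == ["D1"]


class TestModifierModel:
    def test_delegates_to_shared_firth(self):
        rows = []
        rng = np.random.default_rng(3)
        for _ in range(60):
            is_case = rng.random() < 0.5
            gon = rng.random() < 0.5
            onset = float(rng.uniform(1, 6)) if is_case else np.nan
            rows.append(dict(
                status="case" if is_case else "control",
                sex=rng.choice(["M", "F"]),
                age_onset_years=onset,
                age_last_followup_years=(onset + 1) if is_case else 9.0,
                gonadal_status="gonadectomized" if gon else "intact",
                age_gonadectomy_years=float(rng.uniform(0.5, 7)) if gon
                else np.nan,
            ))
        df = make_cohort(rows).table
        fit = firth_modifier_model(df, DEF5)
        exposed = df.apply(lambda r: classify_exposure(r, DEF5), axis=1)
        X = np.column_stack([np.ones(len(df)),
                             exposed.astype(float),
                             (df.sex == "M").astype(float)])
        y = (df.status == "case").astype(float).to_numpy()
        direct = firth_logistic(X, y, terms=["intercept", "exposed", "male"])
        np.testing.assert_allclose(fit.beta, direct.beta, atol=1e-12)

    def test_recovers_exposure_or_on_simulated_design(self, rng):
        # known odds ratio for exposure, no sex effect
        n = 400
        exposed = rng.random(n) < 0.4
        male = rng.random(n) < 0.5
        beta = np.log(6.0)
        p = 1 / (1 + np.exp(-(-1.5 + beta * exposed)))
        is_case = rng.random(n) < p
        rows = []
        for i in range(n):
            onset = float(rng.uniform(1, 4.5)) if is_case[i] else np.nan
            gon_age = float(rng.uniform(0.2, min(onset, 4.9) if is_case[i]
                                        else 4.9)) if exposed[i] else np.nan
            rows.append(dict(
                status="case" if is_case[i] else "control",
                sex="M" if male[i] else "F",
                age_onset_years=onset,
                age_last_followup_years=(onset + 1) if is_case[i] else 9.0,
                gonadal_status="gonadectomized" if exposed[i] else "intact",
                age_gonadectomy_years=gon_age,
            ))
        fit = firth_modifier_model(make_cohort(rows).table, DEF5)
        j = fit.terms.index("exposed")
        assert abs(fit.beta[j] - beta) < 2 * fit.se[j]

    def test_finite_under_separated_cells(self):
        # exposure separates status perfectly; sex varies within groups
        rows = (
            [case(3.0, sex="M", gonadal_status="gonadectomized",
                  age_gonadectomy_years=1.0)] * 4
            + [case(3.0, sex="F", gonadal_status="gonadectomized",
                    age_gonadectomy_years=1.0)] * 4
            + [{"status": "control", "sex": "F",
                "age_last_followup_years": 9.0}] * 5
            + [{"status": "control", "sex": "M",
                "age_last_followup_years": 9.0}] * 3
        )
        fit = firth_modifier_model(make_cohort(rows).table, DEF5)
        assert fit.converged and np.all(np.isfinite(fit.beta))


class TestCoxTv:
    def test_no_events_rejected(self):
        df = make_cohort([{"status": "control",
                           "age_last_followup_years": 8.0}] * 5).table
        cp = build_counting_process(df, DEF5)
        with pytest.raises(ValueError, match="events"):
            cox_tv_fit(cp)

    def test_time_fixed_reduction_matches_plain_cox(self):
        from lifelines import CoxPHFitter

        cohort = simulate_survival_cohort(250, seed=8, male_log_HR=np.log(2),
                                          frac_gonadectomized=0.0)
        cp = build_counting_process(cohort.table.assign(dosage=1), DEF5)
        fit = cox_tv_fit(cp, robust=False)
        df = cp[["stop", "event", "male"]].rename(columns={"stop": "T"})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="event")
        j = fit.terms.index("male")
        assert fit.log_hr[j] == pytest.approx(cph.params_["male"], abs=1e-6)

    def test_recovers_male_log_hr(self):
        cohort = simulate_survival_cohort(
            400, seed=21, male_log_HR=np.log(3.0),
            gonadectomy_log_HR=0.0, censor_age=9.0)
        cp = build_counting_process(cohort.table.assign(dosage=1), DEF5)
        fit = cox_tv_fit(cp)
        j = fit.terms.index("male")
        assert abs(fit.log_hr[j] - np.log(3.0)) < 2 * fit.se[j]

    def test_monotone_likelihood_flagged(self):
        # every event occurs in the exposed state
        rows = []
        for i in range(12):
            rows.append(case(4.0 + 0.1 * i, gonadal_status="gonadectomized",
                             age_gonadectomy_years=1.0))
        for i in range(12):
            rows.append({"status": "control", "age_last_followup_years": 9.0})
        cp = build_counting_process(make_cohort(rows).table, DEF5)
        fit = cox_tv_fit(cp)
        assert fit.monotone_flag


class TestPhCheck:
    def test_residuals_exist_only_at_event_times(self):
        from riskhapscan.survival import _schoenfeld_residuals

        cohort = simulate_survival_cohort(120, seed=9, male_log_HR=0.4)
        cp = build_counting_process(cohort.table.assign(dosage=1), DEF5)
        fit = cox_tv_fit(cp)
        t, r, _ = _schoenfeld_residuals(cp, fit.terms, fit.log_hr)
        assert len(t) == cp.event.sum()
        event_times = set(cp.loc[cp.event == 1, "stop"])
        assert set(t) <= event_times

    def test_proportional_data_mostly_non_significant(self):
        hits = 0
        n_reps = 60
        for rep in range(n_reps):
            cohort = simulate_survival_cohort(
                150, seed=1000 + rep, male_log_HR=np.log(2),
                gonadectomy_log_HR=0.3)
            cp = build_counting_process(cohort.table.assign(dosage=1), DEF5)
            fit = cox_tv_fit(cp, robust=False)
            res = ph_check(fit, cp)
            hits += (res.loc[res.term == "male", "p"].iloc[0] < 0.05)
        assert hits <= round(0.10 * n_reps) + 2

    def test_strong_time_varying_effect_detected(self):
        # decaying male effect: hazard ratio 3 before age 2, then 1 -- the
        # male log-HR declines with time, a textbook PH violation
        hits = 0
        n_reps = 40
        for rep in range(n_reps):
            r = np.random.default_rng(2000 + rep)
            n = 300
            male = r.random(n) < 0.5
            E = r.exponential(size=n)
            t_f = E / 0.25
            t_m = np.where(E <= 1.5, E / 0.75, 2 + (E - 1.5) / 0.25)
            t = np.where(male, t_m, t_f)
            event = t < 8.0
            t = np.minimum(t, 8.0)
            cp = pd.DataFrame(dict(
                dog_id=[f"d{i}" for i in range(n)], start=0.0, stop=t,
                exposed=(r.random(n) < 0.5).astype(int),
                event=event.astype(int), male=male.astype(int)))
            fit = cox_tv_fit(cp, robust=False)
            res = ph_check(fit, cp)
            hits += res.loc[res.term == "male", "p"].iloc[0] < 0.05
        assert hits >= round(0.8 * n_reps)
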