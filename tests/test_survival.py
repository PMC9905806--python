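"""Survival statistics: KM/log-rank, Cox models, concordance, AUROC, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import chi2 as chi2_dist

import mqeasl as mq
from mqeasl.exceptions import ValidationError
from mqeasl.survival import breslow_cumulative_hazard

from conftest import make_survival_frame


class TestSplitCohort:
    def test_published_cohort_sizes(self):
        df = pd.DataFrame({"id": range(129)})
        train, valid = mq.split_cohort(df, ratio=0.7, seed=0)
        assert (len(train), len(valid)) == (90, 39)

    def test_deterministic_partition(self):
        df = pd.DataFrame({"id": range(40)})
        a1, b1 = mq.split_cohort(df, seed=5)
        a2, b2 = mq.split_cohort(df, seed=5)
        assert a1["id"].tolist() == a2["id"].tolist()
        assert b1["id"].tolist() == b2["id"].tolist()

    def test_disjoint_and_exhaustive(self):
        df = pd.DataFrame({"id": range(53)})
        train, valid = mq.split_cohort(df, seed=3)
        ids = set(train["id"]) | set(valid["id"])
        assert ids == set(range(53))
        assert not set(train["id"]) & set(valid["id"])


class TestKaplanMeier:
    def test_all_events_at_same_time(self):
        est = mq.km_median([5.0] * 8, [1] * 8)
        assert est.median_months == pytest.approx(5.0)

    def test_exponential_median_closed_form(self, rng):
        t = rng.exponential(20.0 / np.log(2.0), 5000)
        est = mq.km_median(t, np.ones(5000, int))
        assert est.median_months == pytest.approx(20.0, abs=1.0)

    def test_matches_hand_product_limit_table(self):
        # times 1, 2+, 3, 4+, 5 -> S = 4/5, 4/5, 8/15, 8/15, 0
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        events = [1, 0, 1, 0, 1]
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter().fit(times, events)
        s = kmf.survival_function_["KM_estimate"]
        assert s.loc[1.0] == pytest.approx(4 / 5)
        assert s.loc[3.0] == pytest.approx(4 / 5 * 2 / 3)
        assert s.loc[5.0] == pytest.approx(0.0)
        assert mq.km_median(times, events).median_months == pytest.approx(5.0)

    def test_undefined_median_reported_as_nan(self):
        est = mq.km_median([10.0, 12.0, 15.0, 20.0], [1, 0, 0, 0])
        assert np.isnan(est.median_months)
        assert np.isnan(est.ci95[1])

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = np.sort(rng.exponential(10.0, 200))
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter().fit(t, np.ones(200, int))
        for q in (t[20], t[100], t[180]):
            empirical = np.mean(t > q)
            assert float(kmf.predict(q)) == pytest.approx(empirical, abs=1e-12)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [2.0, 4.0, 6.0, 8.0]
        e = [1, 1, 0, 1]
        stat, p = mq.logrank(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_o_minus_e(self):
        # two tiny groups, no tied event times across groups
        ta, ea = [1.0, 3.0, 5.0], [1, 1, 0]
        tb, eb = [2.0, 4.0, 6.0], [1, 0, 1]
        times = np.array(ta + tb)
        events = np.array(ea + eb)
        group = np.array([0, 0, 0, 1, 1, 1])
        o_minus_e = 0.0
        var = 0.0
        for t in np.sort(times[events == 1]):
            at_risk = times >= t
            n = at_risk.sum()
            n_a = (at_risk & (group == 0)).sum()
            d = ((times == t) & (events == 1)).sum()
            d_a = ((times == t) & (events == 1) & (group == 0)).sum()
            o_minus_e += d_a - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected_stat = o_minus_e**2 / var
        stat, p = mq.logrank(ta, ea, tb, eb)
        assert stat == pytest.approx(expected_stat, rel=1e-9)
        assert p == pytest.approx(chi2_dist.sf(expected_stat, 1), rel=1e-9)

    def test_power_under_strong_hazard_ratio(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ta = rng.exponential(10.0, 200)
            tb = rng.exponential(30.0, 200)
            _, p = mq.logrank(ta, np.ones(200), tb, np.ones(200))
            rejections += p < 0.001
        assert rejections >= 19

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mq.logrank([], [], [1.0], [1])


def _single_covariate_cox_oracle(times, events, x):
    times = np.asarray(times, float)
    x = np.asarray(x, float)
    events = np.asarray(events, bool)

    def neg_loglik(b):
        ll = 0.0
        for i in np.where(events)[0]:
            at_risk = times >= times[i]
            ll += b * x[i] - np.log(np.sum(np.exp(b * x[at_risk])))
        return -ll

    return minimize_scalar(neg_loglik, bounds=(-5, 5), method="bounded").x


class TestCoxFitting:
    def test_single_binary_covariate_matches_partial_likelihood_oracle(self):
        rng = np.random.default_rng(1)
        x = np.repeat([0, 1], 40)
        t = rng.exponential(np.where(x == 1, 8.0, 20.0))
        df = make_survival_frame(t, np.ones(80, int), arm=x)
        spec = mq.fit_cox_multivariate(df, ["arm"])
        assert spec.coefficients["arm"] == pytest.approx(
            _single_covariate_cox_oracle(t, np.ones(80, bool), x), abs=1e-3
        )

    def test_null_covariates_near_zero(self):
        rng = np.random.default_rng(2)
        n = 600
        df = make_survival_frame(
            rng.exponential(15.0, n),
            np.ones(n, int),
            metastasis=rng.integers(0, 2, n),
            pvtt=rng.integers(0, 2, n),
        )
        spec = mq.fit_cox_multivariate(df, ["metastasis", "pvtt"])
        for coef in spec.coefficients.values():
            assert abs(coef) < 0.25

    def test_few_events_per_variable_warns(self):
        rng = np.random.default_rng(3)
        df = make_survival_frame(
            rng.exponential(10.0, 25),
            np.ones(25, int),
            metastasis=rng.integers(0, 2, 25),
            pvtt=rng.integers(0, 2, 25),
            subsequent_treatment=rng.integers(0, 4, 25),
        )
        with pytest.warns(UserWarning, match="events per variable"):
            mq.fit_cox_multivariate(df, ["metastasis", "pvtt", "subsequent_treatment"])

    def test_published_model_recovery_from_responder_driven_hazard(self):
        records, _ = mq.generate_cohort(
            mq.CohortSpec(n=2000, seed=11, vc_effect="responder")
        )
        ann = mq.annotate_cohort(records)
        res = mq.ResponseCoxModel(ann, response_marker="mqeasl").fit()
        truth = {
            "metastasis": 1.88,
            "pvtt": 0.92,
            "subsequent_treatment": -0.36,
            "responder": -1.41,
        }
        for name, true_coef in truth.items():
            assert res.spec.coefficients[name] == pytest.approx(true_coef, abs=0.25)

    def test_univariate_screen_selects_real_effect(self):
        records, _ = mq.generate_cohort(mq.CohortSpec(n=1000, seed=4))
        screen = mq.univariate_screen(records, ["metastasis", "pvtt"])
        assert bool(screen.loc["metastasis", "selected"])
        assert screen.loc["metastasis", "coef"] > 0


class TestLinearPredictor:
    def test_published_model1_arithmetic(self):
        patient = {"metastasis": 1, "pvtt": 1, "subsequent_treatment": 0, "responder": 0}
        assert mq.linear_predictor(mq.MODEL1_PUBLISHED, patient) == pytest.approx(3.11)

    def test_published_model2_zero_patient(self):
        patient = {"metastasis": 0, "pvtt": 0, "subsequent_treatment": 0, "responder": 0}
        assert mq.linear_predictor(mq.MODEL2_PUBLISHED, patient) == 0.0

    def test_published_model2_mixed_patient(self):
        patient = {"metastasis": 0, "pvtt": 0, "subsequent_treatment": 3, "responder": 1}
        assert mq.linear_predictor(mq.MODEL2_PUBLISHED, patient) == pytest.approx(-2.49)

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValidationError):
            mq.linear_predictor(mq.MODEL2_PUBLISHED, {"metastasis": 1})


class TestHarrellsC:
    def test_perfect_anti_ranking_gives_one(self, rng):
        t = rng.uniform(1, 50, 40)
        c, se = mq.harrells_c(-t, t, np.ones(40, int))
        assert c == 1.0

    def test_random_predictor_near_half(self, rng):
        t = rng.exponential(10, 2000)
        lp = rng.normal(0, 1, 2000)
        c, se = mq.harrells_c(lp, t, np.ones(2000, int))
        assert c == pytest.approx(0.5, abs=0.03)
        assert 0 < se < 0.05

    def test_matches_brute_force_enumeration(self, rng):
        n = 25
        t = rng.uniform(1, 30, n)
        e = rng.integers(0, 2, n)
        lp = rng.normal(0, 1, n)
        conc = usable = 0.0
        for i in range(n):
            for j in range(n):
                if t[i] < t[j] and e[i] == 1:
                    usable += 1
                    conc += 1.0 if lp[i] > lp[j] else (0.5 if lp[i] == lp[j] else 0.0)
        c, _ = mq.harrells_c(lp, t, e)
        assert c == pytest.approx(conc / usable, abs=1e-12)
        # cross-check against an established implementation (no ties here)
        from lifelines.utils import concordance_index

        assert c == pytest.approx(1.0 - concordance_index(t, lp, e), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        t = rng.exponential(10, 150)
        e = rng.integers(0, 2, 150)
        lp = rng.normal(0, 1, 150)
        c1, _ = mq.harrells_c(lp, t, e)
        c2, _ = mq.harrells_c(np.exp(3 * lp) + 7, t, e)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_binary_marker_direction_agrees_with_logrank(self, rng):
        marker = np.repeat([0, 1], 150)
        t = rng.exponential(np.where(marker == 1, 6.0, 18.0))
        e = np.ones(300, int)
        c, _ = mq.harrells_c(marker.astype(float), t, e)
        med_pos = mq.km_median(t[marker == 1], e[marker == 1]).median_months
        med_neg = mq.km_median(t[marker == 0], e[marker == 0]).median_months
        assert (c > 0.5) == (med_pos < med_neg)


class TestTdAuroc:
    def test_perfect_predictor_gives_one(self, rng):
        t = rng.uniform(1, 40, 120)
        auc, lo, hi = mq.td_auroc(-t, t, np.ones(120, int), 15.0, n_bootstrap=0)
        assert auc == pytest.approx(1.0)

    def test_null_predictor_near_half(self, rng):
        t = rng.exponential(15, 1000)
        lp = rng.normal(0, 1, 1000)
        auc, *_ = mq.td_auroc(lp, t, np.ones(1000, int), 12.0, n_bootstrap=0)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_ipcw_matches_direct_count_without_censoring(self, rng):
        t = rng.uniform(1, 30, 80)
        lp = rng.normal(0, 1, 80)
        e = np.ones(80, int)
        h = 12.0
        ipcw, *_ = mq.td_auroc(lp, t, e, h, n_bootstrap=0)
        cases, controls = lp[t <= h], lp[t > h]
        direct = np.mean([(ci > cj) + 0.5 * (ci == cj) for ci in cases for cj in controls])
        assert ipcw == pytest.approx(direct, abs=1e-9)

    def test_bootstrap_ci_brackets_estimate(self, rng):
        t = rng.exponential(15, 300)
        lp = -np.log(t) + rng.normal(0, 0.5, 300)
        auc, lo, hi = mq.td_auroc(lp, t, np.ones(300, int), 12.0, n_bootstrap=100, seed=1)
        assert lo <= auc <= hi

    def test_no_events_before_horizon_rejected(self):
        with pytest.raises(ValidationError):
            mq.td_auroc([1.0, 2.0], [30.0, 40.0], [1, 1], 5.0, n_bootstrap=0)


class TestCalibration:
    def test_self_consistent_simulation_calibrated(self):
        records, _ = mq.generate_cohort(
            mq.CohortSpec(n=2000, seed=21, vc_effect="responder")
        )
        ann = mq.annotate_cohort(records)
        res = mq.ResponseCoxModel(ann, response_marker="mqeasl").fit()
        tab = res.calibration_table(horizon=12.0)
        assert len(tab) == 3
        for _, row in tab.iterrows():
            assert row["predicted_survival"] == pytest.approx(
                row["observed_survival"], abs=0.05
            )

    def test_constant_predictor_matches_marginal_km(self, rng):
        n = 400
        t = rng.exponential(20.0, n)
        e = (rng.random(n) < 0.85).astype(int)
        tab = mq.calibration_table(np.full(n, 0.6), t, e, horizon=12.0)
        assert len(tab) == 1
        from lifelines import KaplanMeierFitter

        km = float(KaplanMeierFitter().fit(t, e).predict(12.0))
        assert tab.iloc[0]["observed_survival"] == pytest.approx(km, abs=1e-9)

    def test_misspecified_model_still_produces_monotone_table(self):
        records, _ = mq.generate_cohort(
            mq.CohortSpec(n=1500, seed=22, beta_metastasis=2.5)
        )
        ann = mq.annotate_cohort(records)
        # omit the strong metastasis effect on purpose
        res = mq.ResponseCoxModel(
            ann, response_marker="mqeasl", covariates=("pvtt", "subsequent_treatment")
        ).fit()
        tab = res.calibration_table(horizon=12.0)
        pred = tab["predicted_survival"].to_numpy()
        assert np.all(np.diff(pred) > 0)

    def test_breslow_baseline_matches_hand_computation(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        lp = np.array([0.0, np.log(2.0), 0.0, 0.0])
        times, H = breslow_cumulative_hazard(lp, t, e)
        # risk sets: t=1 -> 1+2+1+1=5 ; t=2 -> 2+1+1=4 ; t=4 -> 1
        assert np.allclose(times, [1.0, 2.0, 4.0])
        assert np.allclose(H, np.cumsum([1 / 5, 1 / 4, 1 / 1]))


class TestSummaries:
    def test_summary_table_contents(self, annotated_cohort):
        ann, _ = annotated_cohort
        res = mq.ResponseCoxModel(ann, response_marker="mqeasl").fit()
        summ = res.summary()
        assert set(summ.index) == {"metastasis", "pvtt", "subsequent_treatment", "responder"}
        assert {"coef", "se(coef)", "HR", "z", "p"} <= set(summ.columns)
        assert res.spec.coefficients["responder"] < 0  # response is protective

    def test_performance_report_structure(self, annotated_cohort):
        ann, _ = annotated_cohort
        train, valid = mq.split_cohort(ann, seed=1)
        res = mq.ResponseCoxModel(train, response_marker="mqeasl").fit()
        rep = res.performance_report(valid, horizons=(12.0,), n_bootstrap=20)
        assert 0.0 <= rep["c_index"] <= 1.0
        assert 12.0 in rep["auroc"]
        assert rep["calibration"][12.0]

    def test_responder_comparison_medians_ordered(self, annotated_cohort):
        ann, _ = annotated_cohort
        cmp = mq.compare_responder_survival(ann, "mqeasl")
        assert cmp.logrank_p < 0.05
        assert (
            np.isnan(cmp.responder.median_months)
            or cmp.responder.median_months > cmp.non_responder.median_months
        )
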