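import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from cmrpump.cohortsim import CohortSpec, generate_cohort
from cmrpump.errors import DomainError, ValidationError
from cmrpump.stats import (
    CutoffSet,
    classify,
    compare_groups,
    cox_fit,
    derive_cutoffs,
    km_estimate,
    logrank,
    run_survival_suite,
)


class TestCutoffs:
    @pytest.mark.parametrize(
        "mean, sd, direction, expected",
        [
            (61.0, 4.0, "below", 53.0),  # LVEF
            (56.0, 4.0, "below", 48.0),  # RVEF
            (16.0, 2.0, "below", 12.0),  # LV-AVPD
            (29.0, 9.0, "above", 47.0),  # lateral metrics cut upward
            (10.0, 0.0, "below", 10.0),  # zero spread collapses to the mean
        ],
    )
    def test_two_sd_rule_from_summary(self, mean, sd, direction, expected):
        cuts = CutoffSet.from_summary({"m": (mean, sd)}, {"m": direction})
        assert cuts["m"].value == expected

    def test_derive_from_control_rows_uses_sample_sd(self):
        controls = pd.DataFrame({"lv_avpd": [14.0, 16.0, 18.0]})
        cuts = derive_cutoffs(controls, {"lv_avpd": "below"})
        assert cuts["lv_avpd"].control_sd == pytest.approx(2.0)  # ddof=1
        assert cuts["lv_avpd"].value == pytest.approx(12.0)

    def test_missing_metric_rejected(self):
        with pytest.raises(ValidationError):
            derive_cutoffs(pd.DataFrame({"x": [1.0, 2.0]}), {"lv_avpd": "below"})

    def test_classification_boundary_rule(self):
        cuts = CutoffSet.from_summary(
            {"lv_avpd": (16.0, 2.0), "lv_sv_lat_pct": (29.0, 8.95)},
            {"lv_avpd": "below", "lv_sv_lat_pct": "above"},
        )
        row = {"lv_avpd": 10.0, "lv_sv_lat_pct": 50.0}
        got = classify(row, cuts)
        assert got["lv_avpd"] == "altered"  # 10 < 12.0
        assert got["lv_sv_lat_pct"] == "altered"  # 50 > 46.9
        exactly = classify({"lv_avpd": 12.0, "lv_sv_lat_pct": 46.9}, cuts)
        assert exactly["lv_avpd"] == "within_limits"  # equality is within
        assert exactly["lv_sv_lat_pct"] == "within_limits"
        assert classify({"lv_avpd": float("nan"), "lv_sv_lat_pct": 1.0}, cuts)["lv_avpd"] == "missing"


class TestCompareGroups:
    def test_identical_samples_not_different(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        res = compare_groups(a, a.copy())
        assert res.p > 0.9

    def test_separated_normals_detected(self):
        rng = np.random.default_rng(1)
        res = compare_groups(rng.normal(0, 1, 50), rng.normal(5, 1, 50))
        assert res.p < 1e-6

    def test_skewed_data_routes_to_mann_whitney(self):
        rng = np.random.default_rng(2)
        res = compare_groups(rng.exponential(1.0, 60), rng.exponential(1.0, 60))
        assert res.test == "mann-whitney"

    def test_chi_square_perfect_association(self):
        a = np.array(["x"] * 10)
        b = np.array(["y"] * 10)
        res = compare_groups(a, b, kind="nominal")
        assert res.test == "chi-square"
        assert res.statistic == pytest.approx(20.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            compare_groups([], [1.0, 2.0, 3.0])


class TestKaplanMeier:
    def test_no_events_stays_at_one(self):
        est = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(est.survival == 1.0)
        assert np.isnan(est.median)

    def test_hand_product_limit(self):
        est = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert est.at(1.0) == pytest.approx(2.0 / 3.0)
        assert est.at(2.0) == pytest.approx(1.0 / 3.0)
        assert est.at(3.0) == pytest.approx(0.0)
        assert est.median == pytest.approx(2.0)

    def test_single_censored_subject(self):
        est = km_estimate([5.0], [0])
        assert est.at(5.0) == 1.0 and np.isnan(est.median)

    def test_without_censoring_matches_empirical_survival(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(2.0, 200)
        est = km_estimate(times, np.ones_like(times))
        for t in [0.5, 1.0, 2.0, 4.0]:
            assert est.at(t) == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_bad_event_flag_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([1.0, 2.0], [0, 2])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 0]
        stat, p = logrank(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_textbook_toy_matches_hand_computation(self):
        """A: events at 1, 2; B: censored at 3, 3.
        O-E = 7/6, Var = 17/36 -> chi2 = 49/17."""
        stat, p = logrank([1.0, 2.0], [1, 1], [3.0, 3.0], [0, 0])
        assert stat == pytest.approx(49.0 / 17.0, rel=1e-9)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(4)
        ta = rng.exponential(1.0, 100)
        tb = rng.exponential(3.0, 100)
        stat, p = logrank(ta, np.ones(100), tb, np.ones(100))
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            logrank([], [], [1.0], [1])


def hand_breslow_neg_loglik(beta, times, events, x):
    """Independent oracle: Breslow partial log-likelihood, brute force."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        dead = (times == t) & (events == 1)
        risk = times >= t
        ll += beta * x[dead].sum() - dead.sum() * np.log(np.sum(np.exp(beta * x[risk])))
    return -ll


def survival_frame(times, events, **covs):
    return pd.DataFrame({"followup_years": times, "event": events, **covs})


class TestCox:
    def test_matches_hand_partial_likelihood_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        x = [1.0, 0.0, 1.0, 0.0]
        res = optimize.minimize_scalar(
            hand_breslow_neg_loglik, bounds=(-5, 5), args=(times, events, x), method="bounded"
        )
        fit = cox_fit(survival_frame(times, events, x=x), ["x"])
        assert np.log(fit.effect("x").hr) == pytest.approx(res.x, abs=1e-4)

    def test_breslow_ties_match_oracle(self):
        times = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0]
        events = [1, 1, 1, 0, 1, 0]
        x = [2.0, 0.0, 1.0, 0.5, 0.0, 1.5]
        res = optimize.minimize_scalar(
            hand_breslow_neg_loglik, bounds=(-5, 5), args=(times, events, x), method="bounded"
        )
        fit = cox_fit(survival_frame(times, events, x=x), ["x"], ties="breslow")
        assert np.log(fit.effect("x").hr) == pytest.approx(res.x, abs=1e-4)

    def test_negated_covariate_gives_reciprocal_hr(self):
        table = generate_cohort(CohortSpec(n_pah=200), seed=10)
        pah = table[table["group"] == "pah"]
        up = cox_fit(pah, ["lv_avpd"])
        down = cox_fit(pah, ["lv_avpd"], per_decrease={"lv_avpd"})
        assert down.effect("lv_avpd").hr == pytest.approx(1.0 / up.effect("lv_avpd").hr, rel=1e-8)

    def test_null_covariate_hr_near_one(self):
        table = generate_cohort(CohortSpec(n_pah=500, log_hr={}), seed=11)
        pah = table[table["group"] == "pah"]
        fit = cox_fit(pah, ["rv_sv_lat_pct"])
        assert 0.9 < fit.effect("rv_sv_lat_pct").hr < 1.1

    def test_too_few_events_rejected(self):
        with pytest.raises(DomainError):
            cox_fit(survival_frame([1.0, 2.0], [0, 0], x=[1.0, 0.0]), ["x"])

    def test_wald_ci_brackets_hr(self):
        table = generate_cohort(CohortSpec(n_pah=300), seed=12)
        pah = table[table["group"] == "pah"]
        fit = cox_fit(pah, ["lv_avpd"], per_decrease={"lv_avpd"})
        eff = fit.effect("lv_avpd")
        assert eff.ci_low < eff.hr < eff.ci_high
        assert eff.hr > 0


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortSpec(n_control=60, n_pah=300), seed=13)


class TestSurvivalSuite:

    def test_avpd_linked_hazard_is_detected_and_null_metric_is_not(self, cohort):
        controls = cohort[cohort["group"] == "control"]
        from cmrpump.stats import DEFAULT_DIRECTIONS

        directions = {m: d for m, d in DEFAULT_DIRECTIONS.items() if m in cohort.columns}
        cuts = derive_cutoffs(controls, directions)
        report = run_survival_suite(cohort, cuts)
        cox = report.cox
        uni = cox[cox["model"] == "univariate"].set_index("covariate")
        assert uni.loc["lv_avpd", "p"] < 0.05
        assert uni.loc["rv_avpd", "p"] < 0.05
        assert uni.loc["sv_sept_pct", "p"] > 0.05
        assert uni.loc["lv_avpd", "hr"] > 1.0  # per mm decrease
        # adjusted models exist for the screened covariates
        assert (cox["model"] == "bivariate").any()
        assert (cox["model"] == "multivariate").any()

    def test_km_tables_and_dichotomized_hr(self):
        # strong threshold effect so the dichotomized comparison is decisive
        strong = generate_cohort(
            CohortSpec(n_control=60, n_pah=300, log_hr={"lv_avpd": 0.3}), seed=13
        )
        controls = strong[strong["group"] == "control"]
        cuts = derive_cutoffs(controls, {"lv_avpd": "below"})
        report = run_survival_suite(strong, cuts)
        cmp = report.km["lv_avpd"]
        assert cmp.km_altered.survival[-1] <= cmp.km_within.survival[-1]
        assert cmp.logrank_p < 0.05
        assert cmp.dichotomized_hr is not None and cmp.dichotomized_hr > 1.0

    def test_zero_events_aborts_with_diagnostic(self):
        table = pd.DataFrame(
            {
                "group": ["pah"] * 5,
                "followup_years": [1.0, 2.0, 3.0, 4.0, 5.0],
                "event": [0, 0, 0, 0, 0],
                "lv_avpd": [10.0] * 5,
            }
        )
        cuts = CutoffSet.from_summary({"lv_avpd": (16.0, 2.0)}, {"lv_avpd": "below"})
        with pytest.raises(DomainError):
            run_survival_suite(table, cuts)

    def test_one_sided_metric_skipped_with_warning(self, caplog):
        table = pd.DataFrame(
            {
                "group": ["pah"] * 6,
                "followup_years": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 0, 1, 0, 1, 0],
                "lv_avpd": [5.0, 6.0, 5.5, 4.0, 6.5, 5.2],  # all altered
            }
        )
        cuts = CutoffSet.from_summary({"lv_avpd": (16.0, 2.0)}, {"lv_avpd": "below"})
        with caplog.at_level("WARNING"):
            report = run_survival_suite(table, cuts)
        assert "lv_avpd" in report.skipped_metrics
        assert any("one side" in rec.message for rec in caplog.records)
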