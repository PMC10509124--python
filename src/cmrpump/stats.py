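"""Normal-range cutoffs, group comparisons and transplantation-free
survival analysis.

Cutoffs are mean +- 2 SD of the healthy-control distribution; a value is
*altered* when strictly beyond the cutoff ("more than 2 SD") and *within
limits* at or inside it.  Group comparisons use an independent-samples
t-test when both samples pass Shapiro-Wilk at alpha = 0.05, otherwise the
Mann-Whitney U test; nominal data use a two-sided chi-square without
continuity correction.  Survival uses the Kaplan-Meier product-limit
estimator with two-group log-rank tests, and Cox proportional-hazards
regression (Breslow tie handling by default, Efron by flag) with Wald
confidence intervals.  Metric covariates are negated before fitting so
hazard ratios are reported per one-unit *decrease*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from statsmodels.duration.hazard_regression import PHReg

from .errors import ConvergenceError, DomainError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Cutoff",
    "CutoffSet",
    "derive_cutoffs",
    "classify",
    "compare_groups",
    "GroupTest",
    "km_estimate",
    "KMEstimate",
    "logrank",
    "cox_fit",
    "CovariateEffect",
    "SurvivalFit",
    "run_survival_suite",
    "SurvivalReport",
    "DEFAULT_DIRECTIONS",
    "TABLE_COVARIATES",
]

_Z95 = float(sps.norm.ppf(0.975))

#: Default alteration directions: function metrics are abnormal when low,
#: lateral contributions when high.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "lv_avpd": "below",
    "rv_avpd": "below",
    "tapse": "below",
    "lv_sv_long_pct": "below",
    "rv_sv_long_pct": "below",
    "sv_sept_pct": "below",
    "lvef": "below",
    "rvef": "below",
    "lv_sv_lat_pct": "above",
    "rv_sv_lat_pct": "above",
}

#: Continuous covariates of the Cox regression ladder, in report order.
TABLE_COVARIATES: tuple[str, ...] = (
    "lv_avpd",
    "rv_avpd",
    "sv_sept_pct",
    "lv_sv_lat_pct",
    "rv_sv_lat_pct",
    "lv_sv_long_pct",
    "rv_sv_long_pct",
    "lvef",
    "rvef",
    "rvsv",
    "lvedv",
    "rvedv",
    "tapse",
)


# --------------------------------------------------------------------------
# cutoffs
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class Cutoff:
    metric: str
    value: float
    direction: str  # "below" | "above"
    control_mean: float
    control_sd: float


@dataclass
class CutoffSet:
    cutoffs: dict[str, Cutoff] = field(default_factory=dict)

    def __getitem__(self, metric: str) -> Cutoff:
        return self.cutoffs[metric]

    def __iter__(self):
        return iter(self.cutoffs.values())

    def __contains__(self, metric: str) -> bool:
        return metric in self.cutoffs

    @classmethod
    def from_summary(
        cls, summaries: dict[str, tuple[float, float]], directions: dict[str, str]
    ) -> "CutoffSet":
        """Build cutoffs from printed control summaries (mean, SD)."""
        out = cls()
        for metric, direction in directions.items():
            if metric not in summaries:
                raise ValidationError(f"no control summary for metric {metric!r}")
            mean, sd = summaries[metric]
            out.cutoffs[metric] = _make_cutoff(metric, mean, sd, direction)
        return out

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metric": c.metric,
                    "cutoff": c.value,
                    "direction": c.direction,
                    "control_mean": c.control_mean,
                    "control_sd": c.control_sd,
                }
                for c in self
            ]
        )


def _make_cutoff(metric: str, mean: float, sd: float, direction: str) -> Cutoff:
    if direction not in ("below", "above"):
        raise ValidationError(f"metric {metric}: direction must be 'below' or 'above'")
    value = mean - 2.0 * sd if direction == "below" else mean + 2.0 * sd
    return Cutoff(metric=metric, value=value, direction=direction, control_mean=mean, control_sd=sd)


def derive_cutoffs(controls: pd.DataFrame, directions: dict[str, str]) -> CutoffSet:
    """Cutoffs at 2 sample SDs (n-1 denominator) from the control mean.

    ``controls`` holds one row per control subject with a column per metric.
    """
    out = CutoffSet()
    for metric, direction in directions.items():
        if metric not in controls.columns:
            raise ValidationError(f"metric {metric!r} absent from control table")
        values = pd.to_numeric(controls[metric], errors="coerce").dropna()
        if len(values) < 2:
            raise DomainError(f"metric {metric}: need >= 2 control values")
        out.cutoffs[metric] = _make_cutoff(
            metric, float(values.mean()), float(values.std(ddof=1)), direction
        )
    return out


def classify(row, cutoffs: CutoffSet) -> dict[str, str]:
    """Classify one subject's metrics as 'altered' (strictly beyond the
    cutoff), 'within_limits' (equality counts as within) or 'missing'."""
    out = {}
    for cut in cutoffs:
        value = row.get(cut.metric) if hasattr(row, "get") else getattr(row, cut.metric, None)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            out[cut.metric] = "missing"
            continue
        if cut.direction == "below":
            altered = value < cut.value
        else:
            altered = value > cut.value
        out[cut.metric] = "altered" if altered else "within_limits"
    return out


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class GroupTest:
    test: str
    statistic: float
    p: float


def compare_groups(a, b, kind: str = "continuous") -> GroupTest:
    """Two-group comparison with the test-selection rule used for the
    cohort tables.

    Continuous: Shapiro-Wilk on each sample at alpha = 0.05; both normal ->
    independent-samples t-test, otherwise Mann-Whitney U (two-sided).
    Nominal: samples of category labels -> two-sided chi-square on the
    2 x k contingency table, no continuity correction.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size == 0 or b.size == 0:
        raise DomainError("empty sample")
    if kind == "nominal":
        cats = sorted(set(a) | set(b))
        table = np.array(
            [[np.sum(a == cat) for cat in cats], [np.sum(b == cat) for cat in cats]]
        )
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        return GroupTest(test="chi-square", statistic=float(stat), p=float(p))
    if kind != "continuous":
        raise DomainError(f"unknown comparison kind {kind!r}")
    a = a.astype(float)
    b = b.astype(float)
    if a.size < 3 or b.size < 3:
        raise DomainError("need >= 3 observations per continuous sample")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normal = sps.shapiro(a).pvalue > 0.05 and sps.shapiro(b).pvalue > 0.05
    if normal:
        stat, p = sps.ttest_ind(a, b)
        return GroupTest(test="t-test", statistic=float(stat), p=float(p))
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupTest(test="mann-whitney", statistic=float(stat), p=float(p))


# --------------------------------------------------------------------------
# survival
# --------------------------------------------------------------------------
def _check_survival(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise DomainError("empty survival sample")
    if np.any(times <= 0):
        raise ValidationError("survival times must be positive")
    if not np.all(np.isin(events, [0, 1])):
        raise ValidationError("event flags must be 0 or 1")
    return times, events.astype(int)


@dataclass
class KMEstimate:
    """Kaplan-Meier step function: S(t) just after each event time."""

    timeline: np.ndarray
    survival: np.ndarray
    median: float  # nan when the curve never reaches 0.5
    n: int
    n_events: int

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMEstimate:
    """Product-limit survival estimate honouring right-censoring."""
    times, events = _check_survival(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    if np.isinf(median):
        median = float("nan")
    return KMEstimate(
        timeline=timeline,
        survival=survival,
        median=median,
        n=len(times),
        n_events=int(events.sum()),
    )


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    ta, ea = _check_survival(times_a, events_a)
    tb, eb = _check_survival(times_b, events_b)
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CovariateEffect:
    name: str
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class SurvivalFit:
    effects: list[CovariateEffect]
    model: str  # univariate | bivariate | multivariate
    per_decrease: frozenset
    n: int
    n_events: int

    def effect(self, name: str) -> CovariateEffect:
        for eff in self.effects:
            if eff.name == name:
                return eff
        raise KeyError(name)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "covariate": e.name,
                    "model": self.model,
                    "hr": e.hr,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p": e.p,
                }
                for e in self.effects
            ]
        )


def cox_fit(
    table: pd.DataFrame,
    covariates: list[str],
    per_decrease: set[str] | frozenset = frozenset(),
    ties: str = "breslow",
    model: str = "univariate",
) -> SurvivalFit:
    """Cox proportional-hazards fit maximizing the partial likelihood.

    Covariates listed in ``per_decrease`` are negated before fitting so the
    reported hazard ratio is per one-unit decrease.  Wald 95% CIs and
    p-values.  Ties are handled with Breslow's approximation by default
    (``ties="efron"`` for Efron's).
    """
    needed = list(covariates) + ["followup_years", "event"]
    frame = table[needed].apply(pd.to_numeric, errors="coerce").dropna()
    times, events = _check_survival(frame["followup_years"], frame["event"])
    if events.sum() < 2:
        raise DomainError("Cox regression needs >= 2 events")
    exog = frame[covariates].astype(float).copy()
    for name in per_decrease:
        if name in exog.columns:
            exog[name] = -exog[name]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod = PHReg(times, exog.to_numpy(), status=events, ties=ties)
        try:
            res = mod.fit(maxiter=100, disp=False)
        except Exception as exc:  # singular information matrix etc.
            raise ConvergenceError(f"Cox fit failed: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
        raise ConvergenceError("Cox fit did not converge")
    if np.any(np.abs(params) > 50):
        raise ConvergenceError("complete separation suspected in Cox fit")

    effects = []
    for name, beta, se in zip(covariates, params, bse):
        z = beta / se if se > 0 else np.inf
        effects.append(
            CovariateEffect(
                name=name,
                hr=float(np.exp(beta)),
                ci_low=float(np.exp(beta - _Z95 * se)),
                ci_high=float(np.exp(beta + _Z95 * se)),
                p=float(2.0 * sps.norm.sf(abs(z))),
            )
        )
    return SurvivalFit(
        effects=effects,
        model=model,
        per_decrease=frozenset(per_decrease),
        n=len(frame),
        n_events=int(events.sum()),
    )


# --------------------------------------------------------------------------
# the full survival suite
# --------------------------------------------------------------------------
@dataclass
class KMComparison:
    metric: str
    km_within: KMEstimate
    km_altered: KMEstimate
    logrank_statistic: float
    logrank_p: float
    dichotomized_hr: float | None
    dichotomized_ci: tuple[float, float] | None


@dataclass
class SurvivalReport:
    km: dict[str, KMComparison]
    cox: pd.DataFrame  # covariate x model table of HRs/CIs/p-values
    skipped_metrics: list[str]

    def km_frame(self, metric: str) -> pd.DataFrame:
        cmp = self.km[metric]
        rows = []
        for label, est in (("within_limits", cmp.km_within), ("altered", cmp.km_altered)):
            for t, s in zip(est.timeline, est.survival):
                rows.append({"metric": metric, "group": label, "time_years": t, "survival": s})
        return pd.DataFrame(rows)


def run_survival_suite(
    table: pd.DataFrame, cutoffs: CutoffSet, screen_alpha: float = 0.1
) -> SurvivalReport:
    """Dichotomized Kaplan-Meier/log-rank per metric plus the continuous
    Cox ladder (univariate; age-adjusted bivariate for univariate p below
    ``screen_alpha``; multivariate adjusting for age and incident status).
    """
    pah = table[table["group"] == "pah"].copy()
    pah = pah.dropna(subset=["followup_years", "event"])
    if pah.empty or pah["event"].sum() == 0:
        raise DomainError("survival suite needs PAH rows with events")

    km: dict[str, KMComparison] = {}
    skipped: list[str] = []
    for cut in cutoffs:
        if cut.metric not in pah.columns:
            skipped.append(cut.metric)
            logger.warning("metric %s absent from cohort; KM skipped", cut.metric)
            continue
        status = pah.apply(lambda row: classify(row, cutoffs)[cut.metric], axis=1)
        within = pah[status == "within_limits"]
        altered = pah[status == "altered"]
        if within.empty or altered.empty:
            skipped.append(cut.metric)
            logger.warning(
                "metric %s: all subjects on one side of the cutoff; KM skipped",
                cut.metric,
            )
            continue
        stat, p = logrank(
            within["followup_years"], within["event"], altered["followup_years"], altered["event"]
        )
        pah_dich = pah.loc[status != "missing"].copy()
        pah_dich["altered"] = (status.loc[pah_dich.index] == "altered").astype(int)
        try:
            dich = cox_fit(pah_dich, ["altered"], model="dichotomized")
            hr_eff = dich.effect("altered")
            dich_hr, dich_ci = hr_eff.hr, (hr_eff.ci_low, hr_eff.ci_high)
        except (ConvergenceError, DomainError):
            dich_hr, dich_ci = None, None
        km[cut.metric] = KMComparison(
            metric=cut.metric,
            km_within=km_estimate(within["followup_years"], within["event"]),
            km_altered=km_estimate(altered["followup_years"], altered["event"]),
            logrank_statistic=stat,
            logrank_p=p,
            dichotomized_hr=dich_hr,
            dichotomized_ci=dich_ci,
        )

    # continuous Cox ladder
    rows = []
    metric_covs = [c for c in TABLE_COVARIATES if c in pah.columns]
    per_decrease = set(metric_covs)
    for cov in metric_covs:
        try:
            uni = cox_fit(pah, [cov], per_decrease, model="univariate")
        except (ConvergenceError, DomainError) as exc:
            logger.warning("univariate Cox for %s failed: %s", cov, exc)
            continue
        rows.append(uni.as_frame().iloc[0].to_dict())
        if uni.effect(cov).p < screen_alpha and "age_years" in pah.columns:
            bi = cox_fit(pah, [cov, "age_years"], per_decrease, model="bivariate")
            rows.append(bi.as_frame().iloc[0].to_dict())
            if "incident" in pah.columns:
                multi = cox_fit(
                    pah, [cov, "age_years", "incident"], per_decrease, model="multivariate"
                )
                rows.append(multi.as_frame().iloc[0].to_dict())
    if "age_years" in pah.columns:
        age_fit = cox_fit(pah, ["age_years"], model="univariate")
        rows.append(age_fit.as_frame().iloc[0].to_dict())
    if "incident" in pah.columns and pah["incident"].notna().any():
        inc = cox_fit(pah.dropna(subset=["incident"]), ["incident"], model="univariate")
        rows.append(inc.as_frame().iloc[0].to_dict())
        if "age_years" in pah.columns:
            inc_bi = cox_fit(
                pah.dropna(subset=["incident"]), ["incident", "age_years"], model="bivariate"
            )
            rows.append(inc_bi.as_frame().iloc[0].to_dict())

    return SurvivalReport(km=km, cox=pd.DataFrame(rows), skipped_metrics=skipped)
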