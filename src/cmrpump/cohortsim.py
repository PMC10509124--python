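"""Simulated cohorts with the statistical structure of a PAH outcome study.

Each subject's imaging metrics are drawn from group-specific normal
distributions (truncated at physiologic bounds); the default means and SDs
are the healthy-control and PAH summaries of the study population this
package models (20 controls, 71 patients).  Ventricular EDV and EF are
derived from the drawn ESV and SV so that SV = EDV - ESV and EF = SV/EDV
hold exactly within each subject.

Transplantation-free survival for patients follows an exponential
proportional-hazards model: the hazard is ``baseline_hazard *
exp(sum_m log_hr[m] * (mean_m - x_m))``, so a *decrease* of one unit in a
metric with positive ``log_hr`` multiplies the hazard by ``exp(log_hr)``
(the per-unit-decrease convention used in the survival reports).
Administrative censoring is uniform over the accrual horizon.  Controls
carry no survival data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError

__all__ = ["MetricSpec", "CohortSpec", "generate_cohort", "DEFAULT_METRICS"]


@dataclass(frozen=True)
class MetricSpec:
    """Group means/SDs and the truncation bounds of one drawn metric."""

    control_mean: float
    control_sd: float
    pah_mean: float
    pah_sd: float
    low: float = -np.inf
    high: float = np.inf


#: Default per-metric summaries (control mean+-SD / PAH mean+-SD).
#: CMR-TAPSE has no published summary; its defaults are a synthetic choice
#: placed above the RV-AVPD mean (lateral excursion exceeds the RV mean).
DEFAULT_METRICS: dict[str, MetricSpec] = {
    "heart_rate": MetricSpec(61, 10, 79, 14, low=30),
    "lv_avpd": MetricSpec(16, 2, 11, 3, low=0),
    "rv_avpd": MetricSpec(22, 3, 12, 4, low=0),
    "tapse": MetricSpec(25, 4, 14, 5, low=0),
    "lv_sv_long_pct": MetricSpec(57, 8, 51, 11),
    "rv_sv_long_pct": MetricSpec(85, 11, 72, 19),
    "lv_sv_lat_pct": MetricSpec(29, 9, 48, 17),
    "rv_sv_lat_pct": MetricSpec(27, 9, 34, 16),
    "sv_sept_pct": MetricSpec(9, 4, 4, 14),
    "lvesv": MetricSpec(65, 15, 59, 19, low=5),
    "lvsv": MetricSpec(101, 21, 68, 21, low=5),
    "rvesv": MetricSpec(80, 21, 161, 70, low=5),
    "rvsv": MetricSpec(103, 24, 78, 21, low=5),
}


@dataclass
class CohortSpec:
    n_control: int = 20
    n_pah: int = 71
    metrics: dict[str, MetricSpec] = field(default_factory=lambda: dict(DEFAULT_METRICS))
    baseline_hazard: float = 0.25  # events per year at the PAH metric means
    log_hr: dict[str, float] = field(
        default_factory=lambda: {"lv_avpd": 0.15, "rv_avpd": 0.10}
    )
    censor_horizon: float = 8.0  # years of accrual/administrative follow-up
    incident_fraction: float = 0.69
    age_control: tuple[float, float] = (58.0, 15.0)
    age_pah: tuple[float, float] = (57.0, 19.0)
    women_fraction_control: float = 0.70
    women_fraction_pah: float = 0.65
    seed: int = 0

    def validate(self) -> None:
        if self.n_control <= 0 or self.n_pah <= 0:
            raise DomainError("group sizes must be positive")
        if self.baseline_hazard <= 0:
            raise DomainError("baseline hazard must be positive")
        if not 0 <= self.incident_fraction <= 1:
            raise DomainError("incident_fraction must be in [0, 1]")
        for name, m in self.metrics.items():
            if m.control_sd <= 0 or m.pah_sd <= 0:
                raise DomainError(f"metric {name}: SDs must be positive")
        for name in self.log_hr:
            if name not in self.metrics:
                raise DomainError(f"log_hr names unknown metric {name!r}")


def _draw(rng, mean, sd, low, high, size) -> np.ndarray:
    if np.isinf(low) and np.isinf(high):
        return rng.normal(mean, sd, size)
    a, bnd = (low - mean) / sd, (high - mean) / sd
    u = rng.uniform(size=size)
    return sps.truncnorm.ppf(u, a, bnd, loc=mean, scale=sd)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort table, fully reproducible from the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    frames = []
    for group, n in (("control", spec.n_control), ("pah", spec.n_pah)):
        rows: dict[str, np.ndarray | list] = {
            "subject_id": [f"{group[:3]}-{i:04d}" for i in range(n)],
            "group": [group] * n,
        }
        age_mean, age_sd = spec.age_control if group == "control" else spec.age_pah
        rows["age_years"] = _draw(rng, age_mean, age_sd, 18.0, 95.0, n)
        women = (
            spec.women_fraction_control if group == "control" else spec.women_fraction_pah
        )
        rows["sex"] = np.where(rng.uniform(size=n) < women, "F", "M")
        for name, m in spec.metrics.items():
            mean, sd = (
                (m.control_mean, m.control_sd)
                if group == "control"
                else (m.pah_mean, m.pah_sd)
            )
            rows[name] = _draw(rng, mean, sd, m.low, m.high, n)
        frame = pd.DataFrame(rows)
        # volumes are internally consistent per subject: EDV = ESV + SV
        for side in ("lv", "rv"):
            if f"{side}esv" in frame and f"{side}sv" in frame:
                frame[f"{side}edv"] = frame[f"{side}esv"] + frame[f"{side}sv"]
                frame[f"{side}ef"] = 100.0 * frame[f"{side}sv"] / frame[f"{side}edv"]

        if group == "pah":
            frame["incident"] = (rng.uniform(size=n) < spec.incident_fraction).astype(int)
            lp = np.zeros(n)
            for name, beta in spec.log_hr.items():
                lp += beta * (spec.metrics[name].pah_mean - frame[name].to_numpy())
            hazard = spec.baseline_hazard * np.exp(lp)
            event_time = rng.exponential(1.0 / hazard)
            censor_time = np.maximum(rng.uniform(0.0, spec.censor_horizon, n), 0.01)
            frame["event"] = (event_time <= censor_time).astype(int)
            frame["followup_years"] = np.minimum(event_time, censor_time)
        else:
            frame["incident"] = np.nan
            frame["event"] = np.nan
            frame["followup_years"] = np.nan
        frames.append(frame)

    cohort = pd.concat(frames, ignore_index=True)
    front = ["subject_id", "group", "age_years", "sex", "followup_years", "event", "incident"]
    return cohort[front + [c for c in cohort.columns if c not in front]]
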