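"""Survival-analysis layer: outcome construction, Kaplan-Meier estimation,
log-rank tests, Cox proportional-hazards hazard ratios and Harrell's C.

Conventions
-----------
* Time is measured in months since follow-up start; calendar dates are
  converted by exact day counts divided by 30.4375 (the mean Gregorian
  month length).
* A follow-up horizon of ``h`` years is applied as administrative
  censoring at ``12 * h`` months, and each horizon gets its own model fit.
* For non-fatal outcomes (unplanned hospitalization, ICU admission)
  subjects are censored at death if death occurs first.
* Kaplan-Meier confidence intervals use the Greenwood variance with the
  log(-log) transform, which keeps the bounds inside [0, 1] — required by
  the coverage index downstream.
* Cox models use Efron tie handling (identical to Breslow when there are
  no ties) with the fit group as the reference stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_concordance
from scipy import stats

from .exceptions import ConfigError, DataError

DAYS_PER_MONTH = 30.4375

OUTCOME_COLUMNS = {
    "all_cause_mortality": "death_date",
    "unplanned_hospitalization": "first_unplanned_hosp_date",
    "icu_admission": "first_icu_date",
}

GROUP_ORDER = ("fit", "mild", "moderate", "severe")


@dataclass(frozen=True)
class OutcomeSpec:
    """Which adverse outcome to analyse, over which horizon.

    ``censor_at_death`` is forced to True for the non-fatal outcomes and
    False for all-cause mortality; it is derived, not chosen.
    """

    outcome: str
    horizon_years: float

    def __post_init__(self):
        if self.outcome not in OUTCOME_COLUMNS:
            raise ConfigError(
                f"outcome: unknown value {self.outcome!r}; expected one of "
                f"{sorted(OUTCOME_COLUMNS)}"
            )
        if self.horizon_years <= 0:
            raise ConfigError("horizon_years: must be positive")

    @property
    def censor_at_death(self) -> bool:
        return self.outcome != "all_cause_mortality"

    @property
    def horizon_months(self) -> float:
        return 12.0 * self.horizon_years

    @property
    def event_column(self) -> str:
        return OUTCOME_COLUMNS[self.outcome]


def _months_since(dates: pd.Series, start: pd.Series) -> np.ndarray:
    """Exact day counts / 30.4375; NaT maps to NaN."""
    delta = (pd.to_datetime(dates) - pd.to_datetime(start)).dt.days
    return delta.to_numpy(dtype=float) / DAYS_PER_MONTH


def build_outcome(
    subjects: pd.DataFrame, spec: OutcomeSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (time in months, event indicator) for one outcome spec.

    time = months from ``followup_start`` to the earliest of: the
    outcome's own event date, death (when the outcome censors at death),
    the administrative censoring date, and the horizon. The event flag is
    1 iff the outcome's own event date attains that minimum.
    """
    start = subjects["followup_start"]
    event_m = _months_since(subjects[spec.event_column], start)
    if np.nanmin(event_m, initial=np.inf) < 0:
        raise DataError(f"{spec.event_column}: event date before followup_start")

    censor_m = _months_since(subjects["admin_censor_date"], start)
    if np.any(np.isnan(censor_m)):
        raise DataError("admin_censor_date: missing values")
    candidates = [np.where(np.isnan(event_m), np.inf, event_m),
                  censor_m,
                  np.full(len(subjects), spec.horizon_months)]
    if spec.censor_at_death:
        death_m = _months_since(subjects["death_date"], start)
        if np.nanmin(death_m, initial=np.inf) < 0:
            raise DataError("death_date: event date before followup_start")
        candidates.append(np.where(np.isnan(death_m), np.inf, death_m))
    time = np.minimum.reduce(candidates)
    event = (candidates[0] <= time).astype(int)
    return time, event


@dataclass
class SurvivalCurve:
    """Product-limit estimate with Greenwood variance and log(-log) CIs.

    Arrays are aligned on the distinct event times (ascending); the curve
    is a right-continuous step function equal to 1 before the first event.
    """

    times: np.ndarray          # distinct event times, months
    surv: np.ndarray           # S(t) just after each event time
    variance: np.ndarray       # Greenwood variance of S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray        # subjects at risk just before each event time
    n_events: int
    n_subjects: int

    def evaluate(self, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Step-evaluate (S, ci_lower, ci_upper) at arbitrary times."""
        grid = np.asarray(grid, dtype=float)
        if self.times.size == 0:
            ones = np.ones_like(grid)
            return ones, ones.copy(), ones.copy()
        idx = np.searchsorted(self.times, grid, side="right") - 1
        s = np.where(idx >= 0, self.surv[np.maximum(idx, 0)], 1.0)
        lo = np.where(idx >= 0, self.ci_lower[np.maximum(idx, 0)], 1.0)
        hi = np.where(idx >= 0, self.ci_upper[np.maximum(idx, 0)], 1.0)
        return s, lo, hi

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "surv": self.surv,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "at_risk": self.at_risk,
            }
        )


def km_estimate(
    time: np.ndarray, event: np.ndarray, ci_level: float = 0.95
) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Greenwood's formula gives Var[S(t)] = S(t)^2 * sum d_j / (n_j (n_j - d_j));
    the confidence interval is computed on the log(-log S) scale so the
    bounds stay within [0, 1]. Where S is 0 or 1 the interval degenerates
    to the point estimate.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise DataError("km_estimate: empty input")
    if np.any(time < 0):
        raise DataError("km_estimate: negative times")

    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order].astype(bool)
    n = time.size

    event_times = t_sorted[e_sorted]
    uniq, first_idx = np.unique(event_times, return_index=True)
    if uniq.size == 0:
        # all censored: S identically 1
        return SurvivalCurve(
            times=np.empty(0), surv=np.empty(0), variance=np.empty(0),
            ci_lower=np.empty(0), ci_upper=np.empty(0),
            at_risk=np.empty(0, dtype=int), n_events=0, n_subjects=n,
        )
    d = np.diff(np.append(first_idx, event_times.size))          # deaths per time
    n_at_risk = n - np.searchsorted(t_sorted, uniq, side="left")  # at risk just before

    frac = d / n_at_risk
    surv = np.cumprod(1.0 - frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        green = np.cumsum(d / (n_at_risk * (n_at_risk - d).clip(min=0)))
    green = np.where(n_at_risk == d, np.inf, green)   # S hits 0: variance undefined
    variance = np.where(surv > 0, surv**2 * np.where(np.isfinite(green), green, 0.0), 0.0)

    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    interior = (surv > 0) & (surv < 1) & np.isfinite(green)
    lo = surv.copy()
    hi = surv.copy()
    logs = np.log(surv[interior])
    se_loglog = np.sqrt(green[interior]) / np.abs(logs)
    lo[interior] = surv[interior] ** np.exp(z * se_loglog)
    hi[interior] = surv[interior] ** np.exp(-z * se_loglog)
    return SurvivalCurve(
        times=uniq, surv=surv, variance=variance,
        ci_lower=lo, ci_upper=hi, at_risk=n_at_risk.astype(int),
        n_events=int(d.sum()), n_subjects=n,
    )


def logrank_test(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> tuple[float, int, float]:
    """k-sample log-rank test; returns (chi-square, dof, p)."""
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if labels.size < 2:
        raise DataError("logrank_test: need at least two groups")
    res = multivariate_logrank_test(np.asarray(time, float), groups, np.asarray(event))
    return float(res.test_statistic), int(labels.size - 1), float(res.p_value)


def cox_hr(
    time: np.ndarray,
    event: np.ndarray,
    groups: np.ndarray,
    age: np.ndarray | None = None,
    sex_male: np.ndarray | None = None,
    adjusted: bool = False,
    reference: str = "fit",
    group_order: tuple[str, ...] = GROUP_ORDER,
) -> pd.DataFrame:
    """Hazard ratios per frailty group versus the fit reference.

    Returns one row per non-reference group with Wald 95% CIs. A group
    with zero observed events is flagged non-estimable (its dummy is
    dropped from the fit) instead of reporting a spurious number.
    """
    if adjusted and (age is None or sex_male is None):
        raise ConfigError("adjusted: age and sex_male covariates required")
    groups = np.asarray(groups)
    if reference not in groups:
        raise DataError(f"cox_hr: reference group {reference!r} absent")
    event = np.asarray(event)
    non_ref = [g for g in group_order if g != reference and (groups == g).any()]
    estimable = {
        g: bool(event[groups == g].sum() > 0) and bool(event[groups == reference].sum() > 0)
        for g in non_ref
    }

    df = pd.DataFrame({"time": np.asarray(time, float), "event": event})
    fitted = [g for g in non_ref if estimable[g]]
    for g in fitted:
        df[f"grp_{g}"] = (groups == g).astype(float)
    if adjusted:
        df["age"] = np.asarray(age, float)
        df["sex_male"] = np.asarray(sex_male, float)

    summary = None
    if fitted:
        # Efron ties (lifelines default). Strong group effects make the
        # default Newton step overshoot; retry with damped steps before
        # giving up — the partial-likelihood MLE itself is finite.
        last_exc = None
        for fit_options in (None, {"step_size": 0.25}, {"step_size": 0.1}):
            cph = CoxPHFitter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if fit_options is None:
                        cph.fit(df, duration_col="time", event_col="event")
                    else:
                        cph.fit(df, duration_col="time", event_col="event",
                                fit_options=fit_options)
                break
            except (ConvergenceError, np.linalg.LinAlgError) as exc:
                last_exc = exc
        else:
            raise DataError(f"cox_hr: fit failed to converge: {last_exc}")
        summary = cph.summary

    rows = []
    for g in non_ref:
        mask = groups == g
        if estimable[g]:
            s = summary.loc[f"grp_{g}"]
            rows.append(
                {
                    "group": g,
                    "hr": float(np.exp(s["coef"])),
                    "ci_low": float(np.exp(s["coef lower 95%"])),
                    "ci_high": float(np.exp(s["coef upper 95%"])),
                    "n_group": int(mask.sum()),
                    "n_events": int(event[mask].sum()),
                    "estimable": True,
                }
            )
        else:
            rows.append(
                {
                    "group": g, "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "n_group": int(mask.sum()), "n_events": int(event[mask].sum()),
                    "estimable": False,
                }
            )
    out = pd.DataFrame(rows)
    out.insert(0, "adjusted", adjusted)
    return out


def hazard_ratio_table(
    subjects: pd.DataFrame,
    groups: np.ndarray,
    specs: list[OutcomeSpec],
    age: np.ndarray | None = None,
    sex_male: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cox HR table across outcome x horizon x group x adjusted, fit = reference."""
    if age is None:
        age = subjects["age_at_baseline"].to_numpy(float)
    if sex_male is None:
        sex_male = (subjects["sex"] == "M").to_numpy(float)
    blocks = []
    for spec in specs:
        time, event = build_outcome(subjects, spec)
        for adjusted in (False, True):
            rows = cox_hr(time, event, groups, age=age, sex_male=sex_male,
                          adjusted=adjusted)
            rows.insert(0, "horizon_years", spec.horizon_years)
            rows.insert(0, "outcome", spec.outcome)
            blocks.append(rows)
    return pd.concat(blocks, ignore_index=True)


def concordance(time: np.ndarray, event: np.ndarray, risk: np.ndarray) -> float:
    """Harrell's C for a risk score (higher risk -> earlier event).

    Computed over pairs comparable under censoring; ties in risk count 1/2.
    """
    try:
        return float(
            _lifelines_concordance(np.asarray(time, float), -np.asarray(risk, float),
                                   np.asarray(event))
        )
    except ZeroDivisionError as exc:
        raise DataError("concordance: no comparable pairs") from exc
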