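"""Survival layer against hand computations and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from mlmfi import (
    DataError,
    OutcomeSpec,
    build_outcome,
    concordance,
    cox_hr,
    km_estimate,
    logrank_test,
)

# ------------------------------------------------------------ outcome spec


def test_censor_at_death_derived_from_outcome():
    assert not OutcomeSpec("all_cause_mortality", 8).censor_at_death
    assert OutcomeSpec("unplanned_hospitalization", 8).censor_at_death
    assert OutcomeSpec("icu_admission", 1).censor_at_death


def _subjects(**cols):
    n = max(len(v) for v in cols.values())
    base = {
        "subject_id": [f"s{i}" for i in range(n)],
        "followup_start": pd.Timestamp("2006-01-01"),
        "death_date": pd.NaT,
        "first_unplanned_hosp_date": pd.NaT,
        "first_icu_date": pd.NaT,
        "admin_censor_date": pd.Timestamp("2014-01-01"),
    }
    base.update(cols)
    df = pd.DataFrame(base)
    for c in ("followup_start", "death_date", "first_unplanned_hosp_date",
              "first_icu_date", "admin_censor_date"):
        df[c] = pd.to_datetime(df[c])
    return df


def test_death_within_horizon_is_event():
    # 913 days ~ 30 months
    df = _subjects(death_date=[pd.Timestamp("2006-01-01") + pd.Timedelta(days=913)])
    t, e = build_outcome(df, OutcomeSpec("all_cause_mortality", 8))
    assert e[0] == 1
    assert t[0] == pytest.approx(30.0, abs=0.02)


def test_death_censors_nonfatal_outcome():
    df = _subjects(death_date=[pd.Timestamp("2006-01-01") + pd.Timedelta(days=913)])
    t, e = build_outcome(df, OutcomeSpec("unplanned_hospitalization", 8))
    assert e[0] == 0
    assert t[0] == pytest.approx(30.0, abs=0.02)


def test_horizon_truncates_late_event():
    # death at ~70 months, 5-year horizon -> censored at 60 months
    df = _subjects(death_date=[pd.Timestamp("2006-01-01") + pd.Timedelta(days=2130)])
    t, e = build_outcome(df, OutcomeSpec("all_cause_mortality", 5))
    assert e[0] == 0
    assert t[0] == 60.0


def test_event_before_followup_start_rejected():
    df = _subjects(death_date=[pd.Timestamp("2005-06-01")])
    with pytest.raises(DataError):
        build_outcome(df, OutcomeSpec("all_cause_mortality", 8))


def test_event_counts_monotone_in_horizon(small_cohort):
    _, subjects, _, _ = small_cohort
    events = [
        build_outcome(subjects, OutcomeSpec("all_cause_mortality", h))[1].sum()
        for h in (1, 5, 8)
    ]
    assert events[0] <= events[1] <= events[2]


def test_sex_specific_events_partition_cohort(small_cohort):
    _, subjects, _, _ = small_cohort
    spec = OutcomeSpec("all_cause_mortality", 8)
    _, e_all = build_outcome(subjects, spec)
    _, e_m = build_outcome(subjects[subjects["sex"] == "M"], spec)
    _, e_f = build_outcome(subjects[subjects["sex"] == "F"], spec)
    assert e_m.sum() + e_f.sum() == e_all.sum()


# ------------------------------------------------------------ Kaplan-Meier


def brute_force_km(time, event):
    """Independent product-limit: loop over distinct event times."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(time[event])):
        n_at_risk = np.sum(time >= t)
        d = np.sum((time == t) & event)
        s *= 1 - d / n_at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def test_km_hand_example():
    """times (1..5), events (1,0,1,0,0): S = 4/5 then 4/5 * 2/3."""
    curve = km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 0, 0])
    assert curve.times.tolist() == [1, 3]
    assert curve.surv[0] == pytest.approx(0.8, abs=1e-15)
    assert curve.surv[1] == pytest.approx(0.8 * 2 / 3, abs=1e-15)
    assert curve.at_risk.tolist() == [5, 3]


def test_km_all_censored_is_flat_one():
    curve = km_estimate([3, 1, 4], [0, 0, 0])
    s, lo, hi = curve.evaluate([0, 2, 10])
    assert (s == 1).all() and (lo == 1).all() and (hi == 1).all()


def test_km_empty_input_rejected():
    with pytest.raises(DataError):
        km_estimate([], [])


def test_km_matches_brute_force_oracle():
    rng = np.random.default_rng(12)
    time = rng.exponential(40, 200)
    event = rng.random(200) < 0.6
    curve = km_estimate(time, event)
    t_o, s_o = brute_force_km(time, event)
    np.testing.assert_allclose(curve.times, t_o, atol=0)
    np.testing.assert_allclose(curve.surv, s_o, atol=1e-12)


def test_km_matches_lifelines_including_cis():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(5)
    time = rng.exponential(50, 200)
    event = rng.random(200) < 0.7
    curve = km_estimate(time, event)
    kmf = KaplanMeierFitter().fit(time, event)
    s = kmf.survival_function_.iloc[:, 0].loc[curve.times].to_numpy()
    lo = kmf.confidence_interval_.iloc[:, 0].loc[curve.times].to_numpy()
    hi = kmf.confidence_interval_.iloc[:, 1].loc[curve.times].to_numpy()
    np.testing.assert_allclose(curve.surv, s, atol=1e-10)
    np.testing.assert_allclose(curve.ci_lower, lo, atol=1e-10)
    np.testing.assert_allclose(curve.ci_upper, hi, atol=1e-10)


def test_km_monotone_and_bounded(small_cohort):
    _, subjects, _, _ = small_cohort
    t, e = build_outcome(subjects, OutcomeSpec("all_cause_mortality", 8))
    curve = km_estimate(t, e)
    assert (np.diff(curve.surv) <= 0).all()
    assert (curve.ci_lower <= curve.surv + 1e-12).all()
    assert (curve.surv <= curve.ci_upper + 1e-12).all()
    assert (np.diff(curve.at_risk) <= 0).all()


# ------------------------------------------------------------ log-rank


def test_logrank_identical_groups_null():
    time = np.tile([1.0, 2, 3, 4, 5], 2)
    event = np.tile([1, 0, 1, 1, 0], 2)
    groups = np.repeat(["a", "b"], 5)
    chi2, dof, p = logrank_test(time, event, groups)
    assert chi2 == pytest.approx(0.0, abs=1e-10)
    assert dof == 1
    assert p == pytest.approx(1.0, abs=1e-10)


def test_logrank_matches_hand_hypergeometric_sum():
    """Two-group example <=10 subjects, no ties across groups."""
    time = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
    event = np.array([1, 1, 1, 0, 1, 1, 0, 1])
    groups = np.array(list("aabbaabb"))
    # brute force: observed-expected and hypergeometric variance per event time
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at = time >= t
        n = at.sum()
        n1 = (at & (groups == "a")).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (groups == "a")).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    expected_chi2 = o_minus_e**2 / var
    chi2, dof, _ = logrank_test(time, event, groups)
    assert dof == 1
    assert chi2 == pytest.approx(expected_chi2, rel=1e-10)


def test_logrank_four_groups_dof():
    rng = np.random.default_rng(3)
    time = rng.exponential(10, 80)
    event = rng.random(80) < 0.8
    groups = np.repeat(["a", "b", "c", "d"], 20)
    _, dof, _ = logrank_test(time, event, groups)
    assert dof == 3


def test_logrank_single_group_rejected():
    with pytest.raises(DataError):
        logrank_test([1, 2], [1, 1], ["a", "a"])


# ------------------------------------------------------------ Cox


def partial_loglik_binary(beta, time, event, x):
    """Breslow partial log-likelihood for one binary covariate, no ties."""
    ll = 0.0
    for i in np.flatnonzero(event):
        at_risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def test_cox_matches_partial_likelihood_grid_search():
    time = np.array([3.0, 5, 7, 2, 8, 11, 4, 1])
    event = np.array([1, 1, 0, 1, 1, 0, 1, 1])
    x = np.array([1, 1, 1, 0, 1, 0, 0, 0])
    groups = np.where(x == 1, "severe", "fit")
    rows = cox_hr(time, event, groups, group_order=("fit", "severe"))
    res = minimize_scalar(
        lambda b: -partial_loglik_binary(b, time, event, x), bounds=(-5, 5),
        method="bounded", options={"xatol": 1e-10},
    )
    assert np.log(rows["hr"].iloc[0]) == pytest.approx(res.x, abs=1e-3)


def test_efron_equals_breslow_without_ties():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(7)
    n = 60
    x = rng.integers(0, 2, n)
    time = rng.exponential(10 / np.exp(0.7 * x))
    time += rng.random(n) * 1e-6  # enforce no ties
    event = rng.random(n) < 0.8
    df = pd.DataFrame({"t": time, "e": event.astype(int), "x": x})
    hr_e = np.exp(CoxPHFitter().fit(df, "t", "e").summary.loc["x", "coef"])
    hr_b = np.exp(
        CoxPHFitter(baseline_estimation_method="breslow")
        .fit(df, "t", "e").summary.loc["x", "coef"]
    )
    groups = np.where(x == 1, "severe", "fit")
    rows = cox_hr(time, event, groups, group_order=("fit", "severe"))
    assert rows["hr"].iloc[0] == pytest.approx(hr_e, rel=1e-6)
    assert hr_e == pytest.approx(hr_b, rel=1e-6)


def test_zero_event_group_flagged_not_estimated():
    time = np.array([5.0, 6, 7, 8, 1, 2, 3, 4])
    event = np.array([0, 0, 0, 0, 1, 1, 1, 0])
    groups = np.array(["severe"] * 4 + ["fit"] * 4)
    rows = cox_hr(time, event, groups, group_order=("fit", "severe"))
    assert not rows["estimable"].iloc[0]
    assert np.isnan(rows["hr"].iloc[0])


def test_cox_reference_must_be_present():
    with pytest.raises(DataError):
        cox_hr([1, 2], [1, 1], np.array(["mild", "mild"]))


# ------------------------------------------------------------ concordance


def brute_force_concordance(time, event, risk):
    num = den = 0.0
    n = len(time)
    for i, j in itertools.combinations(range(n), 2):
        # comparable iff the earlier time is an event; tied-time pairs with
        # both events are excluded, and an event tied with a censoring time
        # is treated as preceding it
        if time[i] == time[j]:
            if event[i] == event[j]:
                continue
            first, second = (i, j) if event[i] else (j, i)
        else:
            first, second = (i, j) if time[i] < time[j] else (j, i)
        if not event[first]:
            continue
        den += 1
        if risk[first] > risk[second]:
            num += 1
        elif risk[first] == risk[second]:
            num += 0.5
    return num / den


def test_constant_score_gives_half():
    assert concordance([1, 2, 3], [1, 1, 1], [5, 5, 5]) == 0.5


def test_perfect_ranking_gives_one():
    time = np.array([1.0, 2, 3, 4])
    risk = np.array([4.0, 3, 2, 1])
    assert concordance(time, np.ones(4), risk) == 1.0


def test_concordance_matches_pairwise_count():
    rng = np.random.default_rng(21)
    time = rng.exponential(10, 50).round(1)  # induce some ties
    event = rng.random(50) < 0.7
    risk = rng.random(50)
    assert concordance(time, event, risk) == pytest.approx(
        brute_force_concordance(time, event, risk), abs=1e-12
    )
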