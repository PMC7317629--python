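"""Synthetic administrative-claims cohort generator.

Emulates the structure the analysis assumes: an ascertainment (baseline)
year of outpatient/inpatient claims per subject, followed by an 8-year
follow-up window with death, first-unplanned-hospitalization and first-ICU
event dates, for a cohort of adults aged 65-100.

Generative model
----------------
* latent frailty  f_i = z_i + age_frailty_slope * (age_i - 82.5),
  z_i ~ N(0, 1);
* condition presence: logit P(condition c) = logit(base_c)
  + prevalence_frailty_slope * f_i, with per-condition baselines base_c
  spread uniformly around ``prevalence_base``;
* event times: independent exponential draws per outcome with rate
  h0_outcome * exp(lp_i), where the linear predictor
  lp_i = informative_log_hr * (# informative conditions present)
  + age_log_hr * (age_i - 75) + male_log_hr * 1{male}
  + frailty_log_hr * z_i;
* claims: each present condition emits a zero-truncated-Poisson number of
  outpatient claim rows (dates uniform in the baseline year) and, with a
  small probability, one inpatient claim row; absent conditions emit one
  or two "rule-out" outpatient rows with small probability, so the
  ascertainment rule sees both true and near-miss patterns.

Events falling after the follow-up window (or after an early
administrative-censoring time, drawn for a small fraction of subjects)
are recorded as administratively censored — their dates are absent from
the registry and ``admin_censor_date`` carries the truncation date.
Censoring-at-death for non-fatal outcomes is applied by the analysis
layer, not here: the registry keeps each latent first-event date that
falls inside the subject's observation window.

Determinism: everything flows from one root ``numpy.random.Generator``
seeded by ``config.seed``; substreams are drawn in a fixed, documented
order (ages, sex, latent frailty, prevalence baselines, condition
presence, informative-set choice, claim counts, event times, censoring),
so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError

BASELINE_START = pd.Timestamp("2005-01-01")
FOLLOWUP_START = pd.Timestamp("2006-01-01")
DAYS_PER_YEAR = 365.25

# age-band sampling weights: 65-69, 70-74, 75-79, 80-84, 85-100 — the
# age mix of a typical insured elderly cohort (younger bands dominate)
AGE_BANDS = ((65, 69), (70, 74), (75, 79), (80, 84), (85, 100))
AGE_BAND_WEIGHTS = (0.3306, 0.2752, 0.2179, 0.1153, 0.0610)


@dataclass(frozen=True)
class ClaimCountModel:
    """Claim-row counts given condition presence.

    Outpatient counts are zero-truncated Poisson with mean
    ``outpatient_mean`` (>= 3 on average so the ascertainment rule passes
    most true cases but misses some); inpatient rows are Bernoulli.
    Absent conditions emit 1-2 outpatient rows with probability
    ``spurious_outpatient_prob`` — never enough to satisfy the rule.
    """

    outpatient_mean: float = 4.0
    inpatient_prob: float = 0.15
    spurious_outpatient_prob: float = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 2000
    seed: int = 0
    n_conditions: int = 50
    n_informative: int = 5
    informative_log_hr: float = float(np.log(3.0))
    prevalence_base: float = 0.10
    prevalence_frailty_slope: float = 1.0
    age_range: tuple[int, int] = (65, 100)
    female_fraction: float = 0.502
    baseline_hazard_death: float = 0.04    # events per person-year at lp = 0
    baseline_hazard_hosp: float = 0.12
    baseline_hazard_icu: float = 0.05
    followup_years: float = 8.0
    claim_count_model: ClaimCountModel = field(default_factory=ClaimCountModel)
    admin_censor_prob: float = 0.05
    age_log_hr: float = 0.05               # per year of age above 75
    male_log_hr: float = 0.3
    frailty_log_hr: float = 0.3
    age_frailty_slope: float = 0.02        # latent-frailty shift per year of age

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects: must be positive")
        if self.n_conditions <= 0:
            raise ConfigError("n_conditions: must be positive")
        if not 0 <= self.n_informative <= self.n_conditions:
            raise ConfigError("n_informative: must be in [0, n_conditions]")
        if not 0.0 < self.prevalence_base < 1.0:
            raise ConfigError("prevalence_base: must be in (0, 1)")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction: must be in [0, 1]")
        if not 0.0 <= self.admin_censor_prob < 1.0:
            raise ConfigError("admin_censor_prob: must be in [0, 1)")
        for name in ("baseline_hazard_death", "baseline_hazard_hosp",
                     "baseline_hazard_icu"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be positive")
        if self.followup_years <= 0:
            raise ConfigError("followup_years: must be positive")
        lo, hi = self.age_range
        if not (0 < lo <= hi):
            raise ConfigError("age_range: must satisfy 0 < low <= high")
        ccm = self.claim_count_model
        if ccm.outpatient_mean <= 0:
            raise ConfigError("claim_count_model.outpatient_mean: must be positive")
        if not 0.0 <= ccm.inpatient_prob <= 1.0:
            raise ConfigError("claim_count_model.inpatient_prob: must be in [0, 1]")
        if not 0.0 <= ccm.spurious_outpatient_prob <= 1.0:
            raise ConfigError(
                "claim_count_model.spurious_outpatient_prob: must be in [0, 1]"
            )


@dataclass
class GroundTruth:
    """Simulation-internal truth used by parameter-recovery tests only."""

    latent_frailty: np.ndarray        # f_i (frailty incl. age shift)
    latent_z: np.ndarray              # the N(0,1) component
    informative_ids: list[str]
    true_log_hrs: dict[str, float]


def make_catalog(n_conditions: int) -> pd.DataFrame:
    """Synthetic condition catalog: one 3-digit ICD-9 family per condition."""
    families = [str(101 + 16 * j) for j in range(n_conditions)]
    return pd.DataFrame(
        {
            "condition_id": [f"C{j + 1:03d}" for j in range(n_conditions)],
            "icd9_prefixes": families,
            "label": [f"synthetic condition {j + 1}" for j in range(n_conditions)],
        }
    )


def _zero_truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Inverse-CDF sample of Poisson(mean) conditioned on > 0."""
    u = rng.uniform(np.exp(-mean), 1.0, size=size)
    # invert the Poisson CDF by accumulation; mean is small (a few claims)
    out = np.zeros(size, dtype=int)
    cdf = np.exp(-mean)
    term = np.exp(-mean)
    k = 0
    remaining = np.ones(size, dtype=bool)
    while remaining.any() and k < 1000:
        k += 1
        term *= mean / k
        cdf += term
        hit = remaining & (u <= cdf)
        out[hit] = k
        remaining &= ~hit
    out[remaining] = k
    return out


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate (registry, claims, ground truth) for one cohort.

    Returns the subject registry (one row per subject), the claims table
    (one row per claim-diagnosis) and the ground-truth ledger.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    p = config.n_conditions

    # --- demographics (substreams 1-2) ---
    lo, hi = config.age_range
    bands = [(max(a, lo), min(b, hi)) for a, b in AGE_BANDS if b >= lo and a <= hi]
    weights = np.array(AGE_BAND_WEIGHTS[: len(bands)])
    weights = weights / weights.sum()
    band_idx = rng.choice(len(bands), size=n, p=weights)
    band_lo = np.array([b[0] for b in bands])[band_idx]
    band_hi = np.array([b[1] for b in bands])[band_idx]
    ages = band_lo + (rng.random(n) * (band_hi - band_lo + 1)).astype(int)
    female = rng.random(n) < config.female_fraction

    # --- latent frailty (substream 3) ---
    z = rng.standard_normal(n)
    frailty = z + config.age_frailty_slope * (ages - 82.5)

    # --- condition presence (substreams 4-5) ---
    base = config.prevalence_base * rng.uniform(0.4, 1.6, size=p)
    base = np.clip(base, 0.005, 0.5)
    logit_base = np.log(base / (1.0 - base))
    logits = logit_base[None, :] + config.prevalence_frailty_slope * frailty[:, None]
    prob = 1.0 / (1.0 + np.exp(-logits))
    present = rng.random((n, p)) < prob

    catalog = make_catalog(p)
    cond_ids = catalog["condition_id"].to_numpy()

    # --- informative set (substream 6) ---
    informative_idx = np.sort(rng.choice(p, size=config.n_informative, replace=False))
    informative_ids = [cond_ids[j] for j in informative_idx]

    # --- claims (substreams 7-10) ---
    ccm = config.claim_count_model
    subj_ids = np.array([f"S{i + 1:06d}" for i in range(n)])
    si, ci = np.nonzero(present)
    n_pairs = si.size
    outp_counts = _zero_truncated_poisson(rng, ccm.outpatient_mean, n_pairs)
    inpatient = rng.random(n_pairs) < ccm.inpatient_prob
    # spurious 1-2 outpatient rows for absent conditions
    ai, aj = np.nonzero(~present)
    spurious = rng.random(ai.size) < ccm.spurious_outpatient_prob
    sp_counts = 1 + (rng.random(int(spurious.sum())) < 0.5).astype(int)

    rows_subj: list[np.ndarray] = []
    rows_cond: list[np.ndarray] = []
    rows_setting: list[np.ndarray] = []
    if n_pairs:
        rows_subj.append(np.repeat(si, outp_counts))
        rows_cond.append(np.repeat(ci, outp_counts))
        rows_setting.append(np.repeat(np.array(["OUTPATIENT"]), int(outp_counts.sum())))
        rows_subj.append(si[inpatient])
        rows_cond.append(ci[inpatient])
        rows_setting.append(np.repeat(np.array(["INPATIENT"]), int(inpatient.sum())))
    if spurious.any():
        rows_subj.append(np.repeat(ai[spurious], sp_counts))
        rows_cond.append(np.repeat(aj[spurious], sp_counts))
        rows_setting.append(np.repeat(np.array(["OUTPATIENT"]), int(sp_counts.sum())))
    if rows_subj:
        claim_subj = np.concatenate(rows_subj)
        claim_cond = np.concatenate(rows_cond)
        claim_setting = np.concatenate(rows_setting)
    else:
        claim_subj = np.empty(0, dtype=int)
        claim_cond = np.empty(0, dtype=int)
        claim_setting = np.empty(0, dtype=object)
    m = claim_subj.size
    day_offsets = rng.integers(0, 365, size=m)
    # half the claim rows carry a two-digit sub-code under the family
    sub = rng.random(m) < 0.5
    sub_digits = rng.integers(0, 100, size=m)
    fam = catalog["icd9_prefixes"].to_numpy()[claim_cond]
    codes = np.where(
        sub,
        np.char.add(np.char.add(fam.astype(str), "."),
                    np.char.zfill(sub_digits.astype(str), 2)),
        fam.astype(str),
    )
    claims = pd.DataFrame(
        {
            "subject_id": subj_ids[claim_subj],
            "service_date": BASELINE_START + pd.to_timedelta(day_offsets, unit="D"),
            "setting": claim_setting,
            "icd9": codes,
        }
    ).sort_values(["subject_id", "service_date", "setting", "icd9"], kind="stable")
    claims = claims.reset_index(drop=True)

    # --- event times (substream 11) ---
    n_informative_present = present[:, informative_idx].sum(axis=1)
    lp = (
        config.informative_log_hr * n_informative_present
        + config.age_log_hr * (ages - 75.0)
        + config.male_log_hr * (~female).astype(float)
        + config.frailty_log_hr * z
    )
    scale = np.exp(-lp)  # exponential scale = 1 / rate multiplier
    t_death = rng.exponential(scale / config.baseline_hazard_death)
    t_hosp = rng.exponential(scale / config.baseline_hazard_hosp)
    t_icu = rng.exponential(scale / config.baseline_hazard_icu)

    # --- administrative censoring (substream 12) ---
    early = rng.random(n) < config.admin_censor_prob
    censor_years = np.where(
        early, rng.uniform(0.0, config.followup_years, size=n), config.followup_years
    )

    def _event_date(t_years: np.ndarray) -> pd.Series:
        observed = t_years <= censor_years
        # unobserved events carry no date; clip before date arithmetic so
        # huge latent times cannot overflow the datetime range
        days = np.round(np.minimum(t_years, censor_years) * DAYS_PER_YEAR).astype(int)
        dates = FOLLOWUP_START + pd.to_timedelta(days, unit="D")
        return pd.Series(dates).where(observed, pd.NaT)

    subjects = pd.DataFrame(
        {
            "subject_id": subj_ids,
            "age_at_baseline": ages,
            "sex": np.where(female, "F", "M"),
            "followup_start": FOLLOWUP_START,
            "death_date": _event_date(t_death),
            "first_unplanned_hosp_date": _event_date(t_hosp),
            "first_icu_date": _event_date(t_icu),
            "admin_censor_date": FOLLOWUP_START
            + pd.to_timedelta(np.round(censor_years * DAYS_PER_YEAR).astype(int), unit="D"),
        }
    )
    truth = GroundTruth(
        latent_frailty=frailty,
        latent_z=z,
        informative_ids=informative_ids,
        true_log_hrs={cid: config.informative_log_hr for cid in informative_ids},
    )
    return subjects, claims, truth


def write_cohort(
    subjects: pd.DataFrame,
    claims: pd.DataFrame,
    path: str | Path,
    catalog: pd.DataFrame | None = None,
    truth: GroundTruth | None = None,
    fmt: str = "csv",
) -> dict[str, Path]:
    """Serialize registry/claims (and optionally catalog + ground truth).

    CSV by default (Parquet via ``fmt="parquet"``); date columns are
    written as ISO-8601 strings and round-trip losslessly through the
    ``claims_deficits`` readers.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if fmt not in ("csv", "parquet"):
        raise ConfigError(f"fmt: unknown value {fmt!r}")
    files: dict[str, Path] = {}

    def _write(df: pd.DataFrame, name: str, date_cols: tuple[str, ...] = ()) -> Path:
        out = df.copy()
        if fmt == "csv":
            for c in date_cols:
                out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
            f = path / f"{name}.csv"
            out.to_csv(f, index=False)
        else:
            f = path / f"{name}.parquet"
            out.to_parquet(f, index=False)
        return f

    files["registry"] = _write(
        subjects, "registry",
        ("followup_start", "death_date", "first_unplanned_hosp_date",
         "first_icu_date", "admin_censor_date"),
    )
    files["claims"] = _write(claims, "claims", ("service_date",))
    if catalog is not None:
        files["catalog"] = _write(catalog, "catalog")
    if truth is not None:
        gt = pd.DataFrame(
            {
                "latent_frailty": truth.latent_frailty,
                "latent_z": truth.latent_z,
            }
        )
        gt.insert(0, "subject_id", subjects["subject_id"].to_numpy())
        files["ground_truth_subjects"] = _write(gt, "ground_truth_subjects")
        inf = pd.DataFrame(
            {
                "condition_id": truth.informative_ids,
                "true_log_hr": [truth.true_log_hrs[c] for c in truth.informative_ids],
            }
        )
        files["ground_truth_conditions"] = _write(inf, "ground_truth_conditions")
    return files
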