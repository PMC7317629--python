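"""Claims ingestion, cohort filtering and binary deficit ascertainment.

The deficit ascertainment rule is the claims-validation convention used
throughout Taiwanese NHI research: a subject is considered to have a
condition in the baseline year only with at least 3 outpatient claim
records or at least 1 inpatient claim record whose diagnosis code falls
in the condition's ICD-9-CM code family.

ICD-9 normalization strips dots and upper-cases, so "250.01" and "25001"
both match the family prefix "250"; V- and E-codes are matched literally
by prefix. Numeric prefixes must name at least the 3-digit code family —
shorter prefixes are rejected at catalog load to rule out accidental
cross-family matches. Duplicate identical claim rows are collapsed on
(subject, date, setting, normalized code) before counting, so a
triple-keyed file artifact cannot fabricate a deficit; a corollary is
that three same-day outpatient rows with the same code count once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError, SchemaError

logger = logging.getLogger(__name__)

VALID_SETTINGS = frozenset({"OUTPATIENT", "INPATIENT"})
CLAIMS_COLUMNS = ("subject_id", "service_date", "setting", "icd9")
REGISTRY_COLUMNS = (
    "subject_id", "age_at_baseline", "sex", "followup_start", "death_date",
    "first_unplanned_hosp_date", "first_icu_date", "admin_censor_date",
)
REGISTRY_DATE_COLUMNS = (
    "followup_start", "death_date", "first_unplanned_hosp_date",
    "first_icu_date", "admin_censor_date",
)

MIN_OUTPATIENT_CLAIMS = 3
MIN_INPATIENT_CLAIMS = 1


def normalize_icd9(code: str) -> str:
    """Strip whitespace and dots, upper-case. "250.01" -> "25001"."""
    return str(code).strip().upper().replace(".", "")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_claims(path: str | Path) -> pd.DataFrame:
    """Read and validate a claims file (CSV or Parquet).

    Raises :class:`SchemaError` for missing columns or invalid settings,
    and :class:`DataError` listing 1-based data line numbers for rows
    whose service_date cannot be parsed (the run aborts if any).
    """
    df = _read_table(path)
    missing = [c for c in CLAIMS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"claims file {path}: missing columns {missing}")
    df = df.loc[:, list(CLAIMS_COLUMNS)].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["setting"] = df["setting"].astype(str).str.upper()
    bad_setting = ~df["setting"].isin(VALID_SETTINGS)
    if bad_setting.any():
        values = sorted(df.loc[bad_setting, "setting"].unique())
        raise SchemaError(
            f"claims file {path}: invalid setting value(s) {values}; "
            f"expected one of {sorted(VALID_SETTINGS)}"
        )
    parsed = pd.to_datetime(df["service_date"], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header line + 1-based
        raise DataError(
            f"claims file {path}: unparseable service_date on line(s) {lines[:20]}"
            + ("..." if len(lines) > 20 else "")
        )
    df["service_date"] = parsed
    df["icd9"] = df["icd9"].astype(str)
    return df


def read_registry(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject registry file (CSV or Parquet)."""
    df = _read_table(path)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"registry file {path}: missing columns {missing}")
    df = df.loc[:, list(REGISTRY_COLUMNS)].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        raise DataError(f"registry file {path}: duplicate subject_id values")
    df["age_at_baseline"] = pd.to_numeric(df["age_at_baseline"]).astype(int)
    sex = df["sex"].astype(str).str.upper()
    bad_sex = ~sex.isin(("M", "F"))
    if bad_sex.any():
        raise SchemaError(
            f"registry file {path}: invalid sex value(s) "
            f"{sorted(sex[bad_sex].unique())}"
        )
    df["sex"] = sex
    for col in REGISTRY_DATE_COLUMNS:
        raw = df[col].astype(str).replace("", pd.NA) if df[col].dtype == object else df[col]
        df[col] = pd.to_datetime(raw, errors="raise")
    start = df["followup_start"]
    for col in ("death_date", "first_unplanned_hosp_date", "first_icu_date"):
        early = df[col].notna() & (df[col] < start)
        if early.any():
            raise DataError(f"registry file {path}: {col} precedes followup_start")
    return df


@dataclass
class ConditionCatalog:
    """Mapping condition_id -> ICD-9-CM code-family prefixes."""

    condition_ids: list[str]
    prefixes: list[list[str]]   # normalized (dotless) prefixes per condition
    labels: list[str]

    def __post_init__(self):
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise SchemaError("catalog: duplicate condition_id values")
        for cid, prefs in zip(self.condition_ids, self.prefixes):
            if not prefs:
                raise SchemaError(f"catalog: condition {cid} has no prefixes")
            for pref in prefs:
                if pref[:1].isdigit() and len(pref) < 3:
                    raise SchemaError(
                        f"catalog: condition {cid}: numeric prefix {pref!r} shorter "
                        "than the 3-digit ICD-9 code family"
                    )

    def __len__(self) -> int:
        return len(self.condition_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConditionCatalog":
        missing = [c for c in ("condition_id", "icd9_prefixes", "label")
                   if c not in df.columns]
        if missing:
            raise SchemaError(f"catalog: missing columns {missing}")
        prefixes = [
            [normalize_icd9(p) for p in str(cell).split(";") if p.strip()]
            for cell in df["icd9_prefixes"]
        ]
        return cls(
            condition_ids=[str(c) for c in df["condition_id"]],
            prefixes=prefixes,
            labels=[str(x) for x in df["label"]],
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "ConditionCatalog":
        return cls.from_frame(pd.read_csv(path, dtype=str))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_id": self.condition_ids,
                "icd9_prefixes": [";".join(p) for p in self.prefixes],
                "label": self.labels,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def filter_cohort(
    subjects: pd.DataFrame, age_min: int = 65, age_max: int = 100
) -> pd.DataFrame:
    """Keep subjects with age_min <= age_at_baseline <= age_max (inclusive)."""
    if age_min > age_max:
        raise ConfigError("age_min: must not exceed age_max")
    keep = subjects["age_at_baseline"].between(age_min, age_max)
    out = subjects.loc[keep].reset_index(drop=True)
    logger.info("cohort filter [%d, %d]: retained %d of %d subjects",
                age_min, age_max, len(out), len(subjects))
    return out


@dataclass
class DeficitMatrix:
    """Binary subjects x conditions matrix from the ascertainment rule."""

    subject_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray            # int8, shape (n_subjects, n_conditions)
    window: tuple[pd.Timestamp, pd.Timestamp]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.subject_ids), len(self.condition_ids)):
            raise DataError("DeficitMatrix: shape mismatch with labels")
        if not np.isin(self.values, (0, 1)).all():
            raise DataError("DeficitMatrix: values must be 0/1")
        if self.window[1] < self.window[0]:
            raise DataError("DeficitMatrix: window end precedes start")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.condition_ids)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_wide_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_triplets_csv(self, path: str | Path) -> None:
        si, ci = np.nonzero(self.values)
        pd.DataFrame(
            {
                "subject_id": np.asarray(self.subject_ids)[si],
                "condition_id": np.asarray(self.condition_ids)[ci],
                "value": 1,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_wide_csv(
        cls, path: str | Path,
        window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    ) -> "DeficitMatrix":
        df = pd.read_csv(path, dtype={"subject_id": str})
        win = window or (pd.Timestamp.min, pd.Timestamp.max)
        return cls(
            subject_ids=df["subject_id"].tolist(),
            condition_ids=[c for c in df.columns if c != "subject_id"],
            values=df.drop(columns="subject_id").to_numpy(),
            window=win,
        )


def _match_conditions(codes: pd.Series, catalog: ConditionCatalog) -> pd.DataFrame:
    """Map unique normalized codes -> matching condition ids (prefix rule)."""
    uniq = pd.Index(codes.unique())
    norm = np.array([normalize_icd9(c) for c in uniq])
    rows = []
    for cid, prefs in zip(catalog.condition_ids, catalog.prefixes):
        hit = np.zeros(len(norm), dtype=bool)
        for pref in prefs:
            hit |= np.char.startswith(norm.astype(str), pref)
        for code in uniq[hit]:
            rows.append((code, cid))
    return pd.DataFrame(rows, columns=["icd9", "condition_id"])


def ascertain_deficits(
    claims: pd.DataFrame,
    catalog: ConditionCatalog,
    window: tuple[pd.Timestamp, pd.Timestamp],
    subject_ids: list[str] | None = None,
) -> DeficitMatrix:
    """Apply the >=3-outpatient / >=1-inpatient rule within the window.

    ``subject_ids`` fixes the row universe (normally the registry);
    claims for unknown subjects are warned about and dropped. Subjects
    with no qualifying claims keep an all-zero row.
    """
    if len(catalog) == 0:
        raise ConfigError("catalog: must be non-empty")
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if end < start:
        raise ConfigError("window: end precedes start")

    if subject_ids is None:
        subject_ids = sorted(claims["subject_id"].astype(str).unique())
    subject_ids = [str(s) for s in subject_ids]
    universe = set(subject_ids)
    unknown = set(claims["subject_id"].astype(str)) - universe
    if unknown:
        logger.warning(
            "ascertain_deficits: %d claim subject(s) absent from registry; "
            "their claims are ignored", len(unknown)
        )

    in_win = claims["service_date"].between(start, end)
    work = claims.loc[in_win & claims["subject_id"].astype(str).isin(universe)].copy()
    work["icd9_norm"] = work["icd9"].map(normalize_icd9)
    # dedup identical rows: a duplicated claim line must not add evidence
    work = work.drop_duplicates(
        subset=["subject_id", "service_date", "setting", "icd9_norm"]
    )

    n, p = len(subject_ids), len(catalog)
    values = np.zeros((n, p), dtype=np.int8)
    if len(work):
        mapping = _match_conditions(work["icd9"], catalog)
        merged = work.merge(mapping, on="icd9", how="inner")
        if len(merged):
            counts = (
                merged.groupby(["subject_id", "condition_id", "setting"])
                .size()
                .unstack("setting", fill_value=0)
            )
            outp = counts.get("OUTPATIENT", pd.Series(0, index=counts.index))
            inp = counts.get("INPATIENT", pd.Series(0, index=counts.index))
            hit = (outp >= MIN_OUTPATIENT_CLAIMS) | (inp >= MIN_INPATIENT_CLAIMS)
            srow = {s: i for i, s in enumerate(subject_ids)}
            ccol = {c: j for j, c in enumerate(catalog.condition_ids)}
            for (s, c) in hit.index[hit]:
                values[srow[s], ccol[c]] = 1
    return DeficitMatrix(
        subject_ids=subject_ids,
        condition_ids=list(catalog.condition_ids),
        values=values,
        window=(start, end),
    )
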