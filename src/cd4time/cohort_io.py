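"""Readers, writers, and validation for the three cohort tables.

A cohort is exchanged as three comma-separated UTF-8 files with
ISO-8601 (YYYY-MM-DD) dates:

``patients.csv``
    patient_id, sex, age_at_art, education, risk, site, art_start_date
``labs.csv``
    patient_id, date, kind, value   (kind is CD4 [cells/µL] or VL [copies/mL])
``events.csv``
    patient_id, date, category, subtype   (category is death, ADE or SNADE)

Validation is total: structurally broken files raise :class:`SchemaError`,
while rows that violate an invariant are dropped and reported as
row-level diagnostics, never as a crash.  Internally all dates are held
as ``datetime64[ns]``; downstream modules convert to integer days since
each patient's ART start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SEXES = ("male", "female")
EDUCATION_LEVELS = ("primary", "secondary", "university", "unknown")
RISK_GROUPS = ("MSM", "heterosexual", "other", "unknown")
LAB_KINDS = ("CD4", "VL")
EVENT_CATEGORIES = ("death", "ADE", "SNADE")

PATIENT_COLUMNS = ["patient_id", "sex", "age_at_art", "education", "risk", "site", "art_start_date"]
LAB_COLUMNS = ["patient_id", "date", "kind", "value"]
EVENT_COLUMNS = ["patient_id", "date", "category", "subtype"]

#: labs more than this many days before ART start are implausible
MAX_PRE_ART_LAB_DAYS = 5 * 365


class SchemaError(ValueError):
    """A file is structurally unusable (missing column, duplicate ids...)."""


@dataclass
class Diagnostic:
    """One rejected row: which table, which line (1-based, excluding header), why."""

    table: str
    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}:{self.line}: {self.message}"


@dataclass
class Cohort:
    """Validated patients / labs / events tables plus row diagnostics."""

    patients: pd.DataFrame
    labs: pd.DataFrame
    events: pd.DataFrame
    diagnostics: list[Diagnostic] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.diagnostics)


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s): {', '.join(missing)}")


def _parse_dates(df: pd.DataFrame, col: str, table: str, diags: list[Diagnostic]) -> pd.Series:
    parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    for idx in df.index[parsed.isna() & df[col].notna()]:
        diags.append(Diagnostic(table, int(idx) + 1, f"unparseable date {df.at[idx, col]!r}"))
    return parsed


def _validate_patients(raw: pd.DataFrame, diags: list[Diagnostic]) -> pd.DataFrame:
    _require_columns(raw, PATIENT_COLUMNS, "patients")
    raw = raw.reset_index(drop=True)
    dup = raw["patient_id"].duplicated(keep=False)
    if dup.any():
        ids = sorted(raw.loc[dup, "patient_id"].astype(str).unique())
        raise SchemaError(f"patients: duplicate patient_id(s): {', '.join(ids[:10])}")

    dates = _parse_dates(raw, "art_start_date", "patients", diags)
    keep = dates.notna()
    for col, levels in (("sex", SEXES), ("education", EDUCATION_LEVELS), ("risk", RISK_GROUPS)):
        bad = ~raw[col].isin(levels)
        for idx in raw.index[bad & keep]:
            diags.append(Diagnostic("patients", int(idx) + 1, f"invalid {col} {raw.at[idx, col]!r}"))
        keep &= ~bad
    age = pd.to_numeric(raw["age_at_art"], errors="coerce")
    bad_age = age.isna() | (age < 0)
    for idx in raw.index[bad_age & keep]:
        diags.append(Diagnostic("patients", int(idx) + 1, f"invalid age_at_art {raw.at[idx, 'age_at_art']!r}"))
    keep &= ~bad_age

    out = raw.loc[keep, PATIENT_COLUMNS].copy()
    out["art_start_date"] = dates[keep]
    out["age_at_art"] = age[keep].astype(float)
    out["patient_id"] = out["patient_id"].astype(str)
    out["site"] = out["site"].astype(str)
    return out.reset_index(drop=True)


def _validate_labs(raw: pd.DataFrame, patients: pd.DataFrame, diags: list[Diagnostic]) -> pd.DataFrame:
    _require_columns(raw, LAB_COLUMNS, "labs")
    raw = raw.reset_index(drop=True)
    dates = _parse_dates(raw, "date", "labs", diags)
    keep = dates.notna()

    bad_kind = ~raw["kind"].isin(LAB_KINDS)
    for idx in raw.index[bad_kind & keep]:
        diags.append(Diagnostic("labs", int(idx) + 1, f"invalid kind {raw.at[idx, 'kind']!r}"))
    keep &= ~bad_kind

    value = pd.to_numeric(raw["value"], errors="coerce")
    bad_value = value.isna() | (value < 0)
    for idx in raw.index[bad_value & keep]:
        diags.append(Diagnostic("labs", int(idx) + 1, f"invalid value {raw.at[idx, 'value']!r}"))
    keep &= ~bad_value

    known = raw["patient_id"].astype(str).isin(set(patients["patient_id"]))
    for idx in raw.index[~known & keep]:
        diags.append(Diagnostic("labs", int(idx) + 1, f"unknown patient_id {raw.at[idx, 'patient_id']!r}"))
    keep &= known

    out = raw.loc[keep, LAB_COLUMNS].copy()
    out["date"] = dates[keep]
    out["value"] = value[keep].astype(float)
    out["patient_id"] = out["patient_id"].astype(str)

    # plausibility window relative to each patient's ART start
    start = patients.set_index("patient_id")["art_start_date"]
    ref = out["patient_id"].map(start)
    early = out["date"] < ref - pd.Timedelta(days=MAX_PRE_ART_LAB_DAYS)
    for idx in out.index[early]:
        diags.append(Diagnostic("labs", int(idx) + 1, "date more than 5 years before ART start"))
    out = out.loc[~early]
    return out.reset_index(drop=True)


def _validate_events(raw: pd.DataFrame, patients: pd.DataFrame, diags: list[Diagnostic]) -> pd.DataFrame:
    _require_columns(raw, EVENT_COLUMNS, "events")
    raw = raw.reset_index(drop=True)
    dates = _parse_dates(raw, "date", "events", diags)
    keep = dates.notna()

    bad_cat = ~raw["category"].isin(EVENT_CATEGORIES)
    for idx in raw.index[bad_cat & keep]:
        diags.append(Diagnostic("events", int(idx) + 1, f"invalid category {raw.at[idx, 'category']!r}"))
    keep &= ~bad_cat

    known = raw["patient_id"].astype(str).isin(set(patients["patient_id"]))
    for idx in raw.index[~known & keep]:
        diags.append(Diagnostic("events", int(idx) + 1, f"unknown patient_id {raw.at[idx, 'patient_id']!r}"))
    keep &= known

    out = raw.loc[keep, EVENT_COLUMNS].copy()
    out["date"] = dates[keep]
    out["patient_id"] = out["patient_id"].astype(str)
    out["subtype"] = out["subtype"].fillna("").astype(str)

    # at most one death per patient, and no death before ART start
    start = patients.set_index("patient_id")["art_start_date"]
    is_death = out["category"] == "death"
    pre_art = is_death & (out["date"] < out["patient_id"].map(start))
    for idx in out.index[pre_art]:
        diags.append(Diagnostic("events", int(idx) + 1, "death before ART start"))
    out = out.loc[~pre_art]
    is_death = out["category"] == "death"
    dup_death = is_death & out.loc[is_death].duplicated(subset="patient_id", keep="first").reindex(out.index, fill_value=False)
    for idx in out.index[dup_death]:
        diags.append(Diagnostic("events", int(idx) + 1, "more than one death for patient"))
    out = out.loc[~dup_death]
    return out.reset_index(drop=True)


def read_cohort(patients_path: str | Path, labs_path: str | Path, events_path: str | Path) -> Cohort:
    """Read and validate the three cohort tables.

    Rows violating invariants are dropped and reported in
    ``Cohort.diagnostics``; structural problems raise :class:`SchemaError`.
    """
    diags: list[Diagnostic] = []
    patients_raw = pd.read_csv(patients_path, dtype={"patient_id": str})
    labs_raw = pd.read_csv(labs_path, dtype={"patient_id": str})
    events_raw = pd.read_csv(events_path, dtype={"patient_id": str})
    patients = _validate_patients(patients_raw, diags)
    labs = _validate_labs(labs_raw, patients, diags)
    events = _validate_events(events_raw, patients, diags)
    return Cohort(patients, labs, events, diags)


def _fmt_dates(df: pd.DataFrame, col: str) -> pd.DataFrame:
    out = df.copy()
    out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    return out


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write patients/labs/events as CSV with fixed column order and ISO dates.

    The writer is the inverse of :func:`read_cohort` on valid cohorts
    (lossless round trip) and idempotent at the byte level.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.csv",
        "labs": out / "labs.csv",
        "events": out / "events.csv",
    }
    _fmt_dates(cohort.patients[PATIENT_COLUMNS], "art_start_date").to_csv(paths["patients"], index=False)
    labs = _fmt_dates(cohort.labs[LAB_COLUMNS], "date")
    labs["value"] = labs["value"].map(lambda v: format(float(v), "g"))
    labs.to_csv(paths["labs"], index=False)
    _fmt_dates(cohort.events[EVENT_COLUMNS], "date").to_csv(paths["events"], index=False)
    return paths


def labs_by_patient(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Group labs by patient, sorted by date, as a plain dict for fast per-patient access."""
    return {pid: g.sort_values("date", kind="stable").reset_index(drop=True)
            for pid, g in cohort.labs.groupby("patient_id", sort=False)}
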