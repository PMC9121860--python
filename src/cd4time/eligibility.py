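"""Inclusion criteria and the follow-up window decision tree.

Study entry is the first documented viral suppression (VS): the earliest
viral load <200 copies/mL within 365 days of ART initiation.  Follow-up
under suppression then ends at the earliest applicable of:

* virologic failure — one VL >1000 copies/mL, or two consecutive
  VLs >200 copies/mL (failure dated at the second);
* death, when it occurs no more than 365 days after the last suppressed
  VL;
* the last suppressed VL, when the patient's final available VL is
  ≥200 copies/mL without meeting the failure definition;
* a measurement gap — ≥365 days with no VL or CD4 — censoring at the
  last measurement before the gap;
* loss to follow-up — last visit more than 365 days before cohort
  closure — censoring at the last visit;
* administrative censoring at the earlier of cohort closure and
  365 days after the last suppressed VL (suppression is only documented
  that far).

All times are integer days since the patient's ART start.  When two
rules fire on the same day the tie is broken deterministically with
death first (mortality is the primary outcome), then failure, then the
censoring reasons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cd4time.cohort_io import Cohort

VS_THRESHOLD = 200.0          # copies/mL, suppressed means strictly below
FAIL_SINGLE = 1000.0          # one VL strictly above -> failure
FAIL_CONSECUTIVE = 200.0      # two consecutive VLs strictly above -> failure
VS_DEADLINE_DAYS = 365        # first suppression must occur within 12 months of ART
BASELINE_WINDOW = (-90, 30)   # days around ART start for the baseline CD4
GAP_DAYS = 365                # lab-free gap that censors follow-up
DEATH_AFTER_VL_DAYS = 365     # deaths count only this soon after the last suppressed VL

END_REASONS = (
    "death",
    "virologic_failure",
    "final_vl_nonsuppressed",
    "gap_censor",
    "ltfu",
    "admin_censor",
)
_REASON_PRIORITY = {r: i for i, r in enumerate(END_REASONS)}


@dataclass
class FollowUpWindow:
    """Per-patient interval of documented suppression, [t_vs, end_day]."""

    patient_id: str
    t_vs: int                 # day of first viral suppression (since ART start)
    end_day: int
    end_reason: str
    baseline_cd4: float
    baseline_cd4_day: int
    baseline_group: str       # "lt200" | "ge200"

    def __post_init__(self) -> None:
        if self.end_day < self.t_vs:
            raise ValueError(f"{self.patient_id}: end_day {self.end_day} before t_vs {self.t_vs}")
        if self.end_reason not in END_REASONS:
            raise ValueError(f"unknown end_reason {self.end_reason!r}")

    @property
    def length(self) -> int:
        return self.end_day - self.t_vs


def dedupe_same_day(days: np.ndarray, values: np.ndarray, how: str) -> tuple[np.ndarray, np.ndarray]:
    """Collapse same-day repeat measurements: mean for CD4, max (worst) for VL."""
    if len(days) == 0:
        return days, values
    order = np.argsort(days, kind="stable")
    days, values = np.asarray(days)[order], np.asarray(values, dtype=float)[order]
    uniq, inv = np.unique(days, return_inverse=True)
    if len(uniq) == len(days):
        return days, values
    agg = np.zeros(len(uniq))
    if how == "mean":
        counts = np.bincount(inv)
        np.add.at(agg, inv, values)
        agg /= counts
    elif how == "max":
        agg[:] = -np.inf
        np.maximum.at(agg, inv, values)
    else:  # pragma: no cover
        raise ValueError(how)
    return uniq, agg


def find_baseline_cd4(cd4_days: np.ndarray, cd4_values: np.ndarray,
                      window: tuple[int, int] = BASELINE_WINDOW) -> tuple[float, int] | None:
    """CD4 at ART initiation: closest measurement within ``window`` days of ART start.

    Equidistant pre/post pair: the pre-ART value wins (it cannot be
    ART-affected).  Returns ``(value, day)`` or ``None`` if the window is
    empty.
    """
    cd4_days = np.asarray(cd4_days)
    mask = (cd4_days >= window[0]) & (cd4_days <= window[1])
    if not mask.any():
        return None
    days = cd4_days[mask]
    values = np.asarray(cd4_values, dtype=float)[mask]
    # sort by (|day|, day): ties on distance resolved toward the earlier day
    order = np.lexsort((days, np.abs(days)))
    return float(values[order[0]]), int(days[order[0]])


def find_first_vs(vl_days: np.ndarray, vl_values: np.ndarray,
                  deadline: int = VS_DEADLINE_DAYS) -> int | None:
    """Earliest VL <200 copies/mL no later than ``deadline`` days after ART start."""
    vl_days = np.asarray(vl_days)
    mask = (np.asarray(vl_values, dtype=float) < VS_THRESHOLD) & (vl_days <= deadline)
    if not mask.any():
        return None
    return int(vl_days[mask].min())


def detect_virologic_failure(vl_days: np.ndarray, vl_values: np.ndarray) -> int | None:
    """First day the failure definition holds on a date-ordered VL sequence.

    One VL >1000 copies/mL fails on its own day; two consecutive VLs
    >200 copies/mL fail on the second measurement's day ("consecutive"
    means adjacent in the measurement sequence, whatever the elapsed
    time).  Returns ``None`` if neither rule ever fires.
    """
    days = np.asarray(vl_days)
    values = np.asarray(vl_values, dtype=float)
    order = np.argsort(days, kind="stable")
    days, values = days[order], values[order]
    prev_high = False
    for d, v in zip(days, values):
        if v > FAIL_SINGLE:
            return int(d)
        if v > FAIL_CONSECUTIVE:
            if prev_high:
                return int(d)
            prev_high = True
        else:
            prev_high = False
    return None


def determine_followup_end(
    lab_days: np.ndarray,
    vl_days: np.ndarray,
    vl_values: np.ndarray,
    t_vs: int,
    closure: int,
    death_day: int | None = None,
    last_visit_day: int | None = None,
) -> tuple[int, str]:
    """Apply the follow-up decision tree; returns ``(end_day, end_reason)``.

    Parameters
    ----------
    lab_days : all lab measurement days (VL and CD4), any order.
    vl_days, vl_values : the VL series (all days).
    t_vs : day of first suppression.
    closure : cohort closure day for this patient.
    death_day : day of death, if any.
    last_visit_day : last contact (defaults to the latest lab/death day).
    """
    lab_days = np.unique(np.asarray(lab_days))
    vl_days = np.asarray(vl_days)
    vl_values = np.asarray(vl_values, dtype=float)
    order = np.argsort(vl_days, kind="stable")
    vl_days, vl_values = vl_days[order], vl_values[order]

    if death_day is not None and death_day > closure:
        death_day = None

    supp_mask = (vl_values < VS_THRESHOLD) & (vl_days >= t_vs) & (vl_days <= closure)
    if not supp_mask.any():
        raise ValueError("no suppressed VL at or after t_vs; t_vs is ill-defined")
    last_supp_vl = int(vl_days[supp_mask].max())

    candidates: list[tuple[int, str]] = []

    post_mask = (vl_days > t_vs) & (vl_days <= closure)
    fail = detect_virologic_failure(vl_days[post_mask], vl_values[post_mask])
    if fail is not None:
        candidates.append((fail, "virologic_failure"))

    if death_day is not None and death_day <= last_supp_vl + DEATH_AFTER_VL_DAYS:
        candidates.append((death_day, "death"))

    # the final-VL rule applies only when the failure definition is never met
    obs_vl = vl_days <= closure
    if fail is None and obs_vl.any() and vl_values[obs_vl][-1] >= VS_THRESHOLD:
        candidates.append((last_supp_vl, "final_vl_nonsuppressed"))

    on_study = np.sort(lab_days[(lab_days >= t_vs) & (lab_days <= closure)])
    gaps = np.diff(on_study)
    big = np.nonzero(gaps >= GAP_DAYS)[0]
    if big.size:
        candidates.append((int(on_study[big[0]]), "gap_censor"))

    if last_visit_day is None:
        last_visit_day = int(on_study.max()) if on_study.size else t_vs
        if death_day is not None:
            last_visit_day = max(last_visit_day, death_day)
    if closure - last_visit_day > 365:
        candidates.append((int(last_visit_day), "ltfu"))

    candidates.append((min(closure, last_supp_vl + DEATH_AFTER_VL_DAYS), "admin_censor"))

    end_day, end_reason = min(candidates, key=lambda c: (c[0], _REASON_PRIORITY[c[1]]))
    end_day = max(end_day, t_vs)  # a pre-entry candidate cannot shorten below entry
    return int(end_day), end_reason


# exclusion reason codes for the flow-chart accounting
EXCLUSION_REASONS = ("no_baseline_cd4", "no_suppression_12mo", "no_cd4_after_vs")


def build_followup_windows(cohort: Cohort, closure_date: str | pd.Timestamp) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply eligibility to a whole cohort.

    Returns ``(windows, exclusions)``: one row per included patient with
    the follow-up window and baseline CD4 classification, and one row
    per excluded patient with a reason code.  Day columns count from
    each patient's ART start.
    """
    closure_ts = pd.Timestamp(closure_date)
    windows: list[dict] = []
    exclusions: list[dict] = []

    labs = cohort.labs
    lab_groups = {pid: g for pid, g in labs.groupby("patient_id", sort=False)}
    death_dates = (
        cohort.events[cohort.events["category"] == "death"]
        .set_index("patient_id")["date"]
        .to_dict()
    )
    event_last = cohort.events.groupby("patient_id")["date"].max().to_dict()

    for row in cohort.patients.itertuples(index=False):
        pid = row.patient_id
        start = row.art_start_date
        closure = int((closure_ts - start).days)
        g = lab_groups.get(pid)
        if g is None:
            exclusions.append({"patient_id": pid, "reason": "no_baseline_cd4"})
            continue
        day = (g["date"] - start).dt.days.to_numpy()
        kind = g["kind"].to_numpy()
        value = g["value"].to_numpy(dtype=float)
        cd4_d, cd4_v = dedupe_same_day(day[kind == "CD4"], value[kind == "CD4"], "mean")
        vl_d, vl_v = dedupe_same_day(day[kind == "VL"], value[kind == "VL"], "max")

        baseline = find_baseline_cd4(cd4_d, cd4_v)
        if baseline is None:
            exclusions.append({"patient_id": pid, "reason": "no_baseline_cd4"})
            continue
        t_vs = find_first_vs(vl_d, vl_v)
        if t_vs is None:
            exclusions.append({"patient_id": pid, "reason": "no_suppression_12mo"})
            continue
        has_cd4_after = np.any((cd4_d >= t_vs) & (cd4_d <= t_vs + 365))
        if not has_cd4_after:
            exclusions.append({"patient_id": pid, "reason": "no_cd4_after_vs"})
            continue

        death_date = death_dates.get(pid)
        death_day = int((death_date - start).days) if death_date is not None else None
        last_visit = max(
            [int(day.max())] + ([int((event_last[pid] - start).days)] if pid in event_last else [])
        )
        end_day, reason = determine_followup_end(
            np.concatenate([cd4_d, vl_d]), vl_d, vl_v, t_vs, closure,
            death_day=death_day, last_visit_day=last_visit,
        )
        bval, bday = baseline
        windows.append({
            "patient_id": pid,
            "t_vs": t_vs,
            "end_day": end_day,
            "end_reason": reason,
            "baseline_cd4": bval,
            "baseline_cd4_day": bday,
            "baseline_group": "lt200" if bval < 200 else "ge200",
            "t_vs_date": (start + pd.Timedelta(days=t_vs)).strftime("%Y-%m-%d"),
            "end_date": (start + pd.Timedelta(days=end_day)).strftime("%Y-%m-%d"),
        })

    win_cols = ["patient_id", "t_vs", "end_day", "end_reason", "baseline_cd4",
                "baseline_cd4_day", "baseline_group", "t_vs_date", "end_date"]
    windows_df = pd.DataFrame(windows, columns=win_cols)
    exclusions_df = pd.DataFrame(exclusions, columns=["patient_id", "reason"])
    return windows_df, exclusions_df
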