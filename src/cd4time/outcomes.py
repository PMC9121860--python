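"""Outcome coding with cause-specific censoring.

Four outcomes are analysed: death; ADE or SNADE (AIDS-defining or
serious non-AIDS-defining event — non-AIDS cancer, cardiovascular,
liver or renal disease); any event (death, ADE or SNADE); and SNADE
alone.  For the event outcomes death is a competing risk handled by
censoring at death, so the models estimate cause-specific hazards.
Deaths qualify only when the follow-up window itself ends in death
(which enforces the ≤365-days-after-last-suppressed-VL rule).  Events
before first suppression are prevalent and excluded; only the first
event per outcome counts; an event exactly on the window end day is
counted.  Sites that do not report SNADE are removed from every model
whose outcome involves SNADE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cd4time.eligibility import FollowUpWindow

OUTCOMES = ("death", "ade_snade", "any_event", "snade_only")

_OUTCOME_CATEGORIES = {
    "ade_snade": ("ADE", "SNADE"),
    "snade_only": ("SNADE",),
    "any_event": ("ADE", "SNADE"),
}


class OutcomeCodingError(ValueError):
    pass


@dataclass
class OutcomeRecord:
    """First-event-or-censoring for one patient and one outcome.

    Times are days since ART start (same clock as the window).
    """

    patient_id: str
    outcome: str
    event_day: int | None      # day of the qualifying event, None if censored
    censor_day: int            # end of at-risk time for this outcome
    competing_death_censored: bool = False

    @property
    def time(self) -> int:
        """End of at-risk time: event day if the event occurred, else censoring day."""
        return self.event_day if self.event_day is not None else self.censor_day


def code_outcome(events: pd.DataFrame | None, window: FollowUpWindow, outcome: str) -> OutcomeRecord:
    """Code one outcome for one patient.

    ``events`` holds this patient's clinical events with columns
    ``day`` (since ART start) and ``category``; it may be None/empty.
    """
    if outcome not in OUTCOMES:
        raise OutcomeCodingError(f"unknown outcome {outcome!r}")
    t_vs, end = window.t_vs, window.end_day
    died_in_window = window.end_reason == "death"

    if outcome == "death":
        return OutcomeRecord(window.patient_id, outcome,
                             end if died_in_window else None, end)

    first_clin: int | None = None
    if events is not None and len(events):
        cats = _OUTCOME_CATEGORIES[outcome]
        sel = events[events["category"].isin(cats)]
        # prevalent (pre-suppression) events excluded; post-window ignored
        days = sel.loc[(sel["day"] > t_vs) & (sel["day"] <= end), "day"]
        if len(days):
            first_clin = int(days.min())

    if outcome == "any_event":
        cands = [d for d in (first_clin, end if died_in_window else None) if d is not None]
        ev = min(cands) if cands else None
        return OutcomeRecord(window.patient_id, outcome, ev, end)

    # ade_snade / snade_only: death censors (competing risk)
    return OutcomeRecord(window.patient_id, outcome, first_clin, end,
                         competing_death_censored=died_in_window and first_clin is None)


def site_filter(patients: pd.DataFrame, outcome: str, no_snade_sites: set[str] | frozenset[str]) -> pd.Series:
    """Boolean inclusion mask over ``patients`` rows for this outcome's risk set.

    Models whose outcome involves SNADE exclude sites that do not report
    serious non-AIDS events; the death-only model keeps every site.
    """
    if outcome not in OUTCOMES:
        raise OutcomeCodingError(f"unknown outcome {outcome!r}")
    if outcome == "death" or not no_snade_sites:
        return pd.Series(True, index=patients.index)
    return ~patients["site"].isin(no_snade_sites)


def code_outcomes_table(events: pd.DataFrame, windows: pd.DataFrame,
                        art_starts: pd.Series,
                        outcomes: tuple[str, ...] = OUTCOMES) -> pd.DataFrame:
    """Code all four outcomes for every windowed patient.

    ``events`` is the cohort events table (dates), ``windows`` the output
    of :func:`cd4time.eligibility.build_followup_windows`, ``art_starts``
    maps patient_id -> ART start date.  Returns a long table
    (patient_id, outcome, event, time) with time in days since t_vs.
    """
    ev = events.copy()
    ev["day"] = (ev["date"] - ev["patient_id"].map(art_starts)).dt.days
    ev_groups = {pid: g for pid, g in ev.groupby("patient_id", sort=False)}
    rows = []
    for w in windows.itertuples(index=False):
        window = FollowUpWindow(w.patient_id, int(w.t_vs), int(w.end_day), w.end_reason,
                                float(w.baseline_cd4), int(w.baseline_cd4_day), w.baseline_group)
        g = ev_groups.get(w.patient_id)
        for outcome in outcomes:
            rec = code_outcome(g, window, outcome)
            rows.append({
                "patient_id": rec.patient_id,
                "outcome": outcome,
                "event": int(rec.event_day is not None),
                "time": rec.time - window.t_vs,
                "event_day": rec.event_day,
                "censor_day": rec.censor_day,
            })
    return pd.DataFrame(rows, columns=["patient_id", "outcome", "event", "time",
                                       "event_day", "censor_day"])
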