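"""Cumulative percentage of suppressed time with CD4 <200 cells/µL.

The CD4 trajectory is a last-observation-carried-forward step function
anchored at the first suppression date ``t_vs``: each CD4 count is
assumed to hold until the next measurement, for at most 365 days.  The
exposure of interest, %t_CD4<200, is the fraction of elapsed follow-up
(0, t] spent strictly below 200 cells/µL, expressed in percent; it is 0
at t = 0 by convention (no elapsed time).

Follow-up is then expanded into counting-process person-periods: one
half-open row [start, stop) per inter-measurement interval, with the
exposure and the current CD4 evaluated at the row's *start* (no
look-ahead), and the event flag set on the row whose (start, stop]
contains the event date.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cd4time.eligibility import FollowUpWindow, dedupe_same_day

CD4_THRESHOLD = 200.0   # cells/µL; a value of exactly 200 counts as not-below
CARRY_LIMIT = 365       # days a CD4 count may be carried forward
SEED_LOOKBACK = 365     # days before t_vs a CD4 may seed the trajectory


class ExposureError(ValueError):
    """Trajectory cannot be built (no qualifying CD4)."""


@dataclass
class CD4StepFunction:
    """Piecewise-constant CD4 trajectory on days since ``t_vs``.

    ``breakpoints[0] == 0`` (the seed at t_vs); the value on
    [breakpoints[i], breakpoints[i+1]) is ``values[i]``; the function is
    defined up to ``end`` days.
    """

    breakpoints: np.ndarray   # int days since t_vs, strictly increasing, first == 0
    values: np.ndarray        # cells/µL
    end: int                  # days of defined follow-up

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.breakpoints.size == 0 or self.breakpoints[0] != 0:
            raise ExposureError("step function must start at t_vs (day 0)")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ExposureError("breakpoints must be strictly increasing")
        if len(self.breakpoints) != len(self.values):
            raise ExposureError("breakpoints and values length mismatch")

    def value_at(self, t: float) -> float:
        """CD4 in force at time t (left-continuous carry-forward)."""
        i = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return float(self.values[max(i, 0)])


def build_step_function(cd4_days: np.ndarray, cd4_values: np.ndarray,
                        t_vs: int, window: FollowUpWindow | None = None,
                        end_day: int | None = None) -> CD4StepFunction:
    """LOCF trajectory over the follow-up window.

    The seed at t_vs is the most recent CD4 measured no more than 365
    days before t_vs (a measurement on t_vs itself counts); if none
    precedes, the first on-study CD4 value is carried back to t_vs.  The
    trajectory is truncated at the window end, and also wherever a CD4
    would have to be carried for more than 365 days.

    ``cd4_days`` are days since ART start; the returned function is on
    days since t_vs.
    """
    if end_day is None:
        if window is None:
            raise ValueError("need a window or an explicit end_day")
        end_day = window.end_day
    end_rel = int(end_day) - int(t_vs)   # follow-up length on the t_vs clock
    cd4_days, cd4_values = dedupe_same_day(np.asarray(cd4_days), np.asarray(cd4_values, dtype=float), "mean")

    mask = (cd4_days >= t_vs - SEED_LOOKBACK) & (cd4_days <= end_day)
    days = cd4_days[mask] - t_vs
    vals = cd4_values[mask]
    if days.size == 0:
        raise ExposureError("no CD4 measurement within the carry window")

    pre = days <= 0
    if pre.any():
        seed_val = vals[pre][-1]          # most recent at or before t_vs
        days, vals = days[~pre], vals[~pre]
    else:
        seed_val = vals[0]                # carry the first on-study value back
    bp = np.concatenate([[0], days]).astype(np.int64)
    vv = np.concatenate([[seed_val], vals])

    # carry-forward limit: truncate where any piece would exceed 365 days
    edges = np.concatenate([bp, [end_rel]])
    lengths = np.diff(edges)
    too_long = np.nonzero(lengths > CARRY_LIMIT)[0]
    end = end_rel
    if too_long.size:
        k = int(too_long[0])
        end = int(bp[k]) + CARRY_LIMIT
        keep = bp <= bp[k]
        bp, vv = bp[keep], vv[keep]
    else:
        keep = bp < end_rel if end_rel > 0 else bp <= 0
        bp, vv = bp[keep], vv[keep]
    return CD4StepFunction(bp, vv, max(end, 0))


def pct_time_below(f: CD4StepFunction, t: float, threshold: float = CD4_THRESHOLD) -> float:
    """%t_CD4<threshold over (0, t]: 100 × time below / t, and 0 at t = 0."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0:
        return 0.0
    if t > f.end:
        raise ValueError(f"t={t} beyond defined follow-up ({f.end} days)")
    edges = np.concatenate([f.breakpoints, [f.end]]).astype(float)
    lo = np.minimum(edges[:-1], t)
    hi = np.minimum(edges[1:], t)
    below = (f.values < threshold).astype(float)
    time_below = float(np.sum((hi - lo) * below))
    return 100.0 * time_below / t


def pct_time_below_many(f: CD4StepFunction, ts: np.ndarray, threshold: float = CD4_THRESHOLD) -> np.ndarray:
    """Vectorized :func:`pct_time_below` for an increasing array of times."""
    ts = np.asarray(ts, dtype=float)
    edges = np.concatenate([f.breakpoints, [f.end]]).astype(float)
    below = (f.values < threshold).astype(float)
    seg = np.diff(edges) * below
    cum = np.concatenate([[0.0], np.cumsum(seg)])          # time below up to each edge
    idx = np.searchsorted(edges, ts, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    tb = cum[idx] + (ts - edges[idx]) * below[idx]
    out = np.zeros_like(ts)
    nz = ts > 0
    out[nz] = 100.0 * tb[nz] / ts[nz]
    return out


PERSON_PERIOD_COLUMNS = [
    "patient_id", "start", "stop", "event", "pct_below", "current_cd4",
]


def build_person_periods(
    f: CD4StepFunction,
    end_time: int,
    event_time: int | None,
    patient_id: str = "",
    covariates: dict | None = None,
) -> pd.DataFrame:
    """Counting-process rows for one patient and one outcome.

    Rows partition (0, T] where T = ``event_time`` if the outcome
    occurred (event flagged on the last row) else ``end_time``; each row
    starts at a CD4 breakpoint (or t_vs) with ``pct_below`` and
    ``current_cd4`` evaluated at its start.  Events are attributed to
    the row whose (start, stop] contains them, so an event exactly on a
    breakpoint day belongs to the earlier row.  An event after
    ``end_time`` is ignored (censored).
    """
    arrays = person_period_arrays(f, end_time, event_time)
    if arrays is None:
        return pd.DataFrame(columns=PERSON_PERIOD_COLUMNS)
    starts, stops, event, pct, cd4 = arrays
    df = pd.DataFrame({
        "patient_id": patient_id,
        "start": starts,
        "stop": stops,
        "event": event,
        "pct_below": pct,
        "current_cd4": cd4,
    })
    if covariates:
        for k, v in covariates.items():
            df[k] = v
    return df


def person_period_arrays(f: CD4StepFunction, end_time: int, event_time: int | None):
    """Array core of :func:`build_person_periods`; ``None`` when no follow-up."""
    if event_time is not None and event_time > end_time:
        event_time = None
    T = int(event_time if event_time is not None else end_time)
    T = min(T, f.end)
    if T <= 0:
        return None
    starts = f.breakpoints[f.breakpoints < T]
    stops = np.concatenate([starts[1:], [T]])
    pct = pct_time_below_many(f, starts.astype(float))
    cd4 = f.values[: len(starts)]
    event = np.zeros(len(starts), dtype=int)
    if event_time is not None and event_time == T:
        event[-1] = 1
    return starts.astype(int), stops.astype(int), event, pct, cd4
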