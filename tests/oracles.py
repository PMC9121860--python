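"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results with different algorithms (daily
grids, explicit scans, direct formula evaluation) and share no code with
the package internals they verify.
"""

from __future__ import annotations

import numpy as np


def daily_grid_pct_below(breakpoints, values, end, t, threshold=200.0) -> float:
    """%time below threshold over (0, t] summed day by day."""
    if t == 0:
        return 0.0
    bp = np.asarray(breakpoints)
    vals = np.asarray(values, dtype=float)
    below_days = 0
    for d in range(1, int(t) + 1):
        # value in force on the interval (d-1, d): last breakpoint <= d-1
        i = int(np.searchsorted(bp, d - 1, side="right")) - 1
        if vals[max(i, 0)] < threshold:
            below_days += 1
    return 100.0 * below_days / t


def brute_force_log_partial_likelihood(beta, X, start, stop, event) -> float:
    """Cox log partial likelihood by direct risk-set enumeration (no ties)."""
    X = np.asarray(X, dtype=float)
    lp = X @ np.asarray(beta, dtype=float)
    ll = 0.0
    for i in np.nonzero(np.asarray(event, dtype=bool))[0]:
        t = stop[i]
        at_risk = (start < t) & (t <= stop)
        ll += lp[i] - np.log(np.exp(lp[at_risk]).sum())
    return float(ll)


_PRIORITY = {"death": 0, "virologic_failure": 1, "final_vl_nonsuppressed": 2,
             "gap_censor": 3, "ltfu": 4, "admin_censor": 5}


def brute_force_followup_end(cd4_days, vl_days, vl_values, t_vs, closure,
                             death_day=None):
    """Day-by-day re-derivation of the follow-up decision tree.

    Returns (end_day, reason).  Assumes distinct measurement days and a
    suppressed VL at t_vs (the fixtures guarantee both).
    """
    vl_days = list(vl_days)
    vl_values = list(vl_values)
    order = np.argsort(vl_days)
    vl_days = [int(vl_days[i]) for i in order]
    vl_values = [float(vl_values[i]) for i in order]
    lab_days = sorted(set(int(d) for d in cd4_days) | set(vl_days))
    on_study = [d for d in lab_days if t_vs <= d <= closure]
    if death_day is not None and death_day > closure:
        death_day = None

    candidates = []

    # virologic failure: explicit index scan over post-entry VLs
    post = [(d, v) for d, v in zip(vl_days, vl_values) if t_vs < d <= closure]
    fail = None
    for i, (d, v) in enumerate(post):
        if v > 1000:
            fail = d
            break
        if v > 200 and i > 0 and post[i - 1][1] > 200:
            fail = d
            break
    if fail is not None:
        candidates.append((fail, "virologic_failure"))

    supp = [d for d, v in zip(vl_days, vl_values) if v < 200 and t_vs <= d <= closure]
    last_supp = max(supp)

    if death_day is not None and death_day <= last_supp + 365:
        candidates.append((death_day, "death"))

    observed = [(d, v) for d, v in zip(vl_days, vl_values) if d <= closure]
    if fail is None and observed and observed[-1][1] >= 200:
        candidates.append((last_supp, "final_vl_nonsuppressed"))

    # gap: walk every day, counting days since the previous measurement
    since = 0
    prev = t_vs
    for d in range(t_vs + 1, closure + 1):
        since += 1
        if d in on_study:
            if since >= 365:
                candidates.append((prev, "gap_censor"))
                break
            since = 0
            prev = d

    last_visit = max(on_study) if on_study else t_vs
    if death_day is not None:
        last_visit = max(last_visit, death_day)
    if closure - last_visit > 365:
        candidates.append((last_visit, "ltfu"))

    candidates.append((min(closure, last_supp + 365), "admin_censor"))

    end, reason = min(candidates, key=lambda c: (c[0], _PRIORITY[c[1]]))
    return max(end, t_vs), reason


def brute_force_failure_scan(vl_days, vl_values):
    """Failure day by explicit enumeration over every index pair rule."""
    order = np.argsort(vl_days)
    days = np.asarray(vl_days)[order]
    vals = np.asarray(vl_values, dtype=float)[order]
    for i in range(len(days)):
        if vals[i] > 1000:
            return int(days[i])
        if i >= 1 and vals[i] > 200 and vals[i - 1] > 200:
            return int(days[i])
    return None
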