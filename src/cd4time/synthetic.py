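"""Synthetic longitudinal HIV cohort with known ground truth.

Generates patients, labs, and clinical events with the statistical
structure the analysis assumes: roughly half of patients start ART with
CD4 <200 cells/µL (group-conditional baseline distributions with
medians near 74 and 328 cells/µL), first viral suppression at a median
of ≈3.4 months after ART start, CD4 measured at a median interval of
≈156 days, exponential-recovery CD4 trajectories with multiplicative
lognormal measurement noise, independent exponential virologic-failure
and loss-to-follow-up processes, and event times drawn from a
proportional-hazards model whose log-hazard is linear in the *true*
running percentage of suppressed time spent below 200 cells/µL (so
measurement sparsity is a realistic source of estimation error, not of
simulation bias).

Continuous distributions with printed median/IQR are sampled by a
quantile-anchored lognormal: log-value is piecewise-linear in the
normal score through the three anchor quantiles, with the end segments
extrapolated into the tails.  This reproduces the target quartiles
exactly.

Each patient has an independent random stream derived from
``(seed, patient_index)``, so enlarging a cohort extends it without
reshuffling existing patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri

from cd4time.cohort_io import Cohort

DAYS_PER_MONTH = 30.4375

_Z75 = float(ndtri(0.75))


def sample_quantile_anchored(rng: np.random.Generator, n: int,
                             q25: float, q50: float, q75: float,
                             lo: float | None = None, hi: float | None = None) -> np.ndarray:
    """Sample positives whose 25/50/75% quantiles match the anchors.

    Log-value is linear in the normal score z between anchors and
    extends the outer segments' slopes into the tails (lognormal-like).
    Optional bounds are enforced by rejection, which perturbs the
    quantiles only as much as the truncated mass.
    """
    if not (0 < q25 <= q50 <= q75):
        raise ValueError("anchors must be positive and ordered")
    lq = np.log([q25, q50, q75])
    s_lo = (lq[1] - lq[0]) / _Z75     # slope below the median
    s_hi = (lq[2] - lq[1]) / _Z75

    out = np.empty(n)
    need = np.ones(n, dtype=bool)
    while need.any():
        z = ndtri(rng.random(int(need.sum())))
        logv = np.where(z < 0, lq[1] + s_lo * z, lq[1] + s_hi * z)
        v = np.exp(logv)
        ok = np.ones(len(v), dtype=bool)
        if lo is not None:
            ok &= v >= lo
        if hi is not None:
            ok &= v <= hi
        idx = np.nonzero(need)[0]
        out[idx[ok]] = v[ok]
        need[idx[ok]] = False
    return out


def simulate_event_time(times: np.ndarray, x: np.ndarray, baseline_rate: float,
                        beta: float, rng: np.random.Generator) -> float | None:
    """Exact draw from an inhomogeneous exponential with piecewise-constant hazard.

    The hazard on [times[k], times[k+1]) is ``baseline_rate · exp(beta · x[k])``;
    the horizon is ``times[-1]``.  The cumulative hazard is piecewise
    linear, so a unit-exponential draw is inverted segment-wise without
    any thinning-rejection bias.  Returns the event time, or ``None`` if
    no event occurs before the horizon.
    """
    if baseline_rate < 0:
        raise ValueError("baseline_rate must be non-negative")
    times = np.asarray(times, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(times) != len(x) + 1:
        raise ValueError("need len(times) == len(x) + 1")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rates = baseline_rate * np.exp(beta * x)
    increments = rates * np.diff(times)
    cum = np.concatenate([[0.0], np.cumsum(increments)])
    e = rng.exponential()
    if e >= cum[-1]:
        return None
    k = int(np.searchsorted(cum, e, side="right")) - 1
    return float(times[k] + (e - cum[k]) / rates[k])


@dataclass
class SimConfig:
    """Generator parameters; the defaults are the emulated study conditions."""

    n_patients: int = 1000
    seed: int = 0

    # baseline immunology
    p_baseline_low: float = 0.51
    baseline_cd4_low_q: tuple[float, float, float] = (31.0, 74.0, 131.0)   # cells/µL
    baseline_cd4_high_q: tuple[float, float, float] = (261.0, 328.0, 445.0)
    p_missing_baseline: float = 0.02

    # time to first suppression (days): median 3.43 months, IQR 2.6-5.4
    t_vs_days_q: tuple[float, float, float] = (79.1, 104.4, 164.4)

    # inter-visit gap for CD4/VL measurement (days)
    visit_gap_q: tuple[float, float, float] = (101.0, 156.0, 196.0)
    visit_gap_min: float = 14.0
    visit_gap_max: float | None = None   # cap the gap tail (None = lognormal-like tail)

    # CD4 recovery: cd4(t) = cd4_0 + gain·(1 − exp(−t/τ)), lognormal gain
    gain_median_low: float = 200.0    # cells/µL asymptotic gain, baseline <200 group
    gain_median_high: float = 250.0
    gain_sigma: float = 0.5           # lognormal sd of gain
    tau_days: float = 200.0           # recovery time constant
    cd4_noise_sigma: float = 0.2      # lognormal measurement noise on CD4

    # demographics
    p_male: float = 0.78
    age_q: tuple[float, float, float] = (27.6, 33.9, 42.3)
    education_probs: dict = field(default_factory=lambda: {
        "primary": 0.10, "secondary": 0.48, "university": 0.33, "unknown": 0.09})
    risk_probs: dict = field(default_factory=lambda: {
        "MSM": 0.50, "heterosexual": 0.42, "other": 0.01, "unknown": 0.07})
    site_probs: dict = field(default_factory=lambda: {
        "Argentina": 0.06, "Brazil": 0.30, "Chile": 0.14,
        "Honduras": 0.03, "Mexico": 0.15, "Peru": 0.32})
    no_snade_sites: tuple[str, ...] = ("Honduras",)

    # calendar frame
    art_year_range: tuple[int, int] = (2000, 2017)
    closure_date: str = "2019-12-31"

    # outcome processes (per-day baseline hazards; log-hazard slopes).
    # Baselines are calibrated on a pilot cohort so crude incidences land
    # near 5.8 deaths and 19 ADE/SNADE per 1000 person-years.
    baseline_hazard: dict = field(default_factory=lambda: {
        "death": 1.02e-5, "ade": 2.81e-5, "snade": 1.76e-5})
    beta_exposure: dict = field(default_factory=lambda: {
        "death": math.log(1.27) / 15.0,
        "ade": math.log(1.13) / 15.0,
        "snade": math.log(0.96) / 15.0})
    beta_cd4: dict = field(default_factory=lambda: {"death": 0.0, "ade": 0.0, "snade": 0.0})
    failure_rate: float = 2.4e-4      # per day after suppression
    ltfu_rate: float = 2.4e-4
    exposure_grid_days: float = 30.0  # step for the piecewise-constant true hazard path

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if not 0.0 <= self.p_baseline_low <= 1.0:
            raise ValueError("p_baseline_low must be a probability")
        for name in ("failure_rate", "ltfu_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(r < 0 for r in self.baseline_hazard.values()):
            raise ValueError("baseline hazards must be non-negative")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


TRUTH_COLUMNS = ["patient_id", "group_true", "cd4_0", "gain", "tau", "t_vs_day",
                 "days_below_after_vs", "death_day", "ade_day", "snade_day",
                 "failure_day", "ltfu_day", "closure_day"]


def _true_pct_path(edges_rel: np.ndarray, days_below: float) -> np.ndarray:
    """%t below threshold at the left edge of each segment (0 at t=0)."""
    t = edges_rel[:-1].astype(float)
    out = np.zeros(len(t))
    pos = t > 0
    out[pos] = 100.0 * np.minimum(days_below, t[pos]) / t[pos]
    return out


def generate_cohort(config: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Draw a full synthetic cohort; returns ``(cohort, truth)``.

    ``truth`` holds each patient's latent parameters (true baseline
    group, recovery curve, time spent below 200 cells/µL after
    suppression on the true trajectory, and the latent event/censoring
    days, all in days since ART start) for parameter-recovery tests.
    """
    cfg = config
    closure_ts = pd.Timestamp(cfg.closure_date)

    pat_rows, lab_rows, event_rows, truth_rows = [], [], [], []

    edu_levels = list(cfg.education_probs)
    edu_p = np.array(list(cfg.education_probs.values()), dtype=float)
    edu_p /= edu_p.sum()
    risk_levels = list(cfg.risk_probs)
    risk_p = np.array(list(cfg.risk_probs.values()), dtype=float)
    risk_p /= risk_p.sum()
    site_levels = list(cfg.site_probs)
    site_p = np.array(list(cfg.site_probs.values()), dtype=float)
    site_p /= site_p.sum()

    for i in range(cfg.n_patients):
        rng = np.random.default_rng([cfg.seed, i])
        pid = f"P{i:06d}"

        sex = "male" if rng.random() < cfg.p_male else "female"
        age = float(sample_quantile_anchored(rng, 1, *cfg.age_q, lo=18.0)[0])
        education = edu_levels[rng.choice(len(edu_levels), p=edu_p)]
        risk = risk_levels[rng.choice(len(risk_levels), p=risk_p)]
        site = site_levels[rng.choice(len(site_levels), p=site_p)]
        year = int(rng.integers(cfg.art_year_range[0], cfg.art_year_range[1] + 1))
        art_start = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=int(rng.integers(0, 365)))
        closure = int((closure_ts - art_start).days)

        low = rng.random() < cfg.p_baseline_low
        if low:
            cd4_0 = float(np.round(sample_quantile_anchored(
                rng, 1, *cfg.baseline_cd4_low_q, lo=1.0, hi=199.0)[0]))
            gain_med = cfg.gain_median_low
        else:
            cd4_0 = float(np.round(sample_quantile_anchored(
                rng, 1, *cfg.baseline_cd4_high_q, lo=200.0, hi=2000.0)[0]))
            gain_med = cfg.gain_median_high
        gain = float(gain_med * np.exp(cfg.gain_sigma * rng.standard_normal()))
        baseline_day = -int(rng.integers(0, 31))
        missing_baseline = rng.random() < cfg.p_missing_baseline

        t_vs = int(np.ceil(sample_quantile_anchored(rng, 1, *cfg.t_vs_days_q, lo=7.0)[0]))

        # latent censoring processes, all measured from t_vs
        failure_rel = rng.exponential(1.0 / cfg.failure_rate) if cfg.failure_rate > 0 else np.inf
        ltfu_rel = rng.exponential(1.0 / cfg.ltfu_rate) if cfg.ltfu_rate > 0 else np.inf

        # true time spent below 200 after t_vs on the mean recovery curve
        tau = cfg.tau_days
        if cd4_0 >= 200.0:
            t200 = 0.0
        elif cd4_0 + gain <= 200.0:
            t200 = np.inf
        else:
            t200 = -tau * math.log(1.0 - (200.0 - cd4_0) / gain)
        days_below = max(0.0, t200 - t_vs)

        horizon_rel = max(closure - t_vs, 1)
        edges = np.arange(0.0, float(horizon_rel), cfg.exposure_grid_days)
        edges = np.append(edges, float(horizon_rel))
        pct_path = _true_pct_path(edges, days_below)
        cd4_path = cd4_0 + gain * (1.0 - np.exp(-(edges[:-1] + t_vs) / tau))

        latent: dict[str, float] = {}
        for proc in ("death", "ade", "snade"):
            lin = cfg.beta_exposure[proc] * pct_path + cfg.beta_cd4[proc] * cd4_path
            t = simulate_event_time(edges, lin, cfg.baseline_hazard[proc], 1.0, rng)
            latent[proc] = np.inf if t is None else t

        death_rel, ade_rel, snade_rel = latent["death"], latent["ade"], latent["snade"]
        obs_end_rel = min(death_rel, ltfu_rel, float(horizon_rel))
        lab_end_rel = min(obs_end_rel, failure_rel)

        # visit schedule from t_vs; CD4 + VL at every visit (gaps drawn in batches)
        visit_rel = np.array([0.0])
        while visit_rel[-1] < lab_end_rel:
            m = max(4, int((lab_end_rel - visit_rel[-1]) / cfg.visit_gap_q[1] * 1.5) + 2)
            gaps = sample_quantile_anchored(rng, m, *cfg.visit_gap_q,
                                            lo=cfg.visit_gap_min, hi=cfg.visit_gap_max)
            visit_rel = np.concatenate([visit_rel, visit_rel[-1] + np.cumsum(gaps)])
        visit_rel = visit_rel[visit_rel <= lab_end_rel]
        visit_days = t_vs + np.floor(visit_rel).astype(int)

        pat_rows.append({
            "patient_id": pid, "sex": sex, "age_at_art": round(age, 1),
            "education": education, "risk": risk, "site": site,
            "art_start_date": art_start,
        })

        if not missing_baseline:
            lab_rows.append((pid, art_start + pd.Timedelta(days=baseline_day), "CD4", cd4_0))
        lab_rows.append((pid, art_start, "VL", float(np.round(10 ** rng.uniform(4.0, 5.7)))))

        noise = np.exp(cfg.cd4_noise_sigma * rng.standard_normal(len(visit_days)))
        for j, d in enumerate(visit_days):
            true_cd4 = cd4_0 + gain * (1.0 - math.exp(-d / tau))
            cd4_meas = max(1.0, float(np.round(true_cd4 * noise[j])))
            lab_rows.append((pid, art_start + pd.Timedelta(days=int(d)), "CD4", cd4_meas))
            lab_rows.append((pid, art_start + pd.Timedelta(days=int(d)), "VL",
                             float(np.round(10 ** rng.uniform(1.0, 2.2)))))
        if failure_rel <= obs_end_rel:
            fday = t_vs + int(np.ceil(failure_rel))
            lab_rows.append((pid, art_start + pd.Timedelta(days=fday), "VL", 50000.0))

        death_day = ade_day = snade_day = None
        if death_rel <= min(ltfu_rel, float(horizon_rel)):
            death_day = t_vs + int(np.ceil(death_rel))
            event_rows.append((pid, art_start + pd.Timedelta(days=death_day), "death", ""))
        if ade_rel <= min(death_rel, ltfu_rel, float(horizon_rel)):
            ade_day = t_vs + int(np.ceil(ade_rel))
            event_rows.append((pid, art_start + pd.Timedelta(days=ade_day), "ADE", "opportunistic"))
        if snade_rel <= min(death_rel, ltfu_rel, float(horizon_rel)):
            snade_day = t_vs + int(np.ceil(snade_rel))
            if site not in cfg.no_snade_sites:   # non-reporting sites record no SNADE
                event_rows.append((pid, art_start + pd.Timedelta(days=snade_day), "SNADE", "cardiovascular"))

        truth_rows.append({
            "patient_id": pid, "group_true": "lt200" if low else "ge200",
            "cd4_0": cd4_0, "gain": gain, "tau": tau, "t_vs_day": t_vs,
            "days_below_after_vs": days_below,
            "death_day": death_day if death_day is not None else np.nan,
            "ade_day": ade_day if ade_day is not None else np.nan,
            "snade_day": snade_day if snade_day is not None else np.nan,
            "failure_day": t_vs + failure_rel if np.isfinite(failure_rel) else np.nan,
            "ltfu_day": t_vs + ltfu_rel if np.isfinite(ltfu_rel) else np.nan,
            "closure_day": closure,
        })

    patients = pd.DataFrame(pat_rows, columns=["patient_id", "sex", "age_at_art", "education",
                                               "risk", "site", "art_start_date"])
    labs = pd.DataFrame(lab_rows, columns=["patient_id", "date", "kind", "value"])
    events = pd.DataFrame(event_rows, columns=["patient_id", "date", "category", "subtype"])
    if len(patients):
        patients["art_start_date"] = pd.to_datetime(patients["art_start_date"])
    if len(labs):
        labs["date"] = pd.to_datetime(labs["date"])
    if len(events):
        events["date"] = pd.to_datetime(events["date"])
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    cohort = Cohort(patients, labs, events)
    return cohort, truth
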