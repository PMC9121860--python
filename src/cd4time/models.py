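"""Time-varying Cox models, contrasts, survival prediction, fractional logit.

Three Cox specifications are fit per outcome on the counting-process
person-period table, differing only in the time-varying predictor(s):
the cumulative percentage of suppressed time with CD4 <200 cells/µL
(``pct_only``), the time-updated CD4 count (``cd4_only``), or both
(``both``).  All models adjust for sex, age (years), probable HIV
acquisition risk, education, baseline CD4 group, and calendar year of
ART initiation, and are stratified by site.  Ties are handled with the
Efron approximation (lifelines' default); confidence intervals are Wald
on the log-hazard scale.

Because both predictors enter per unit (per percentage point, per
cell), published-style contrasts such as "50% vs 0%" or "350 vs 200
cells" are exponentiated linear contrasts exp(β·δ) — the log-linear
structure behind the reported hazard-ratio grids.

The proportional-hazards diagnostic is a Schoenfeld-residual score test
(rank time transform).  It is computed in-package because the data are
left-truncated (each row enters at its period start), a layout for
which lifelines does not provide residuals; it is reported, never used
to alter a model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

import statsmodels.api as sm

PREDICTOR_SETS = {
    "pct_only": ["pct_below"],
    "cd4_only": ["current_cd4"],
    "both": ["pct_below", "current_cd4"],
}

DEFAULT_ADJUSTMENT = ["sex", "age", "risk", "education", "baseline_group", "art_year"]

#: reference level and modelled levels for each categorical covariate
CATEGORICAL_LEVELS = {
    "sex": ("female", ["male"]),
    "risk": ("heterosexual", ["MSM", "other", "unknown"]),
    "education": ("primary", ["secondary", "university", "unknown"]),
    "baseline_group": ("ge200", ["lt200"]),
    "site": ("Brazil", ["Argentina", "Chile", "Honduras", "Mexico", "Peru"]),
}


class NoEventsError(ValueError):
    """The risk set contains no events; a Cox model cannot be fit."""


def encode_covariates(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Fixed-reference dummy encoding; numeric columns pass through.

    Unseen categorical levels beyond the declared ones raise, so fits
    and predictions always share one design convention.
    """
    out = {}
    for col in columns:
        if col in CATEGORICAL_LEVELS:
            ref, levels = CATEGORICAL_LEVELS[col]
            vals = df[col].astype(str)
            unknown = set(vals.unique()) - set(levels) - {ref}
            if unknown:
                raise ValueError(f"unexpected {col} level(s): {sorted(unknown)}")
            for lev in levels:
                out[f"{col}_{lev}"] = (vals == lev).astype(float)
        else:
            out[col] = pd.to_numeric(df[col]).astype(float)
    return pd.DataFrame(out, index=df.index)


@dataclass
class CoxFit:
    """A fitted time-varying Cox model plus what prediction needs."""

    outcome: str
    predictor_set: str
    params: pd.Series                 # per-unit log-hazards
    cov: pd.DataFrame                 # covariance of params
    aic: float
    log_likelihood: float
    n_events: int
    n_rows: int
    ph_pvalues: pd.Series             # Schoenfeld-residual test per covariate
    strata_col: str | None
    design_columns: list[str]
    dropped_columns: list[str]
    _data: pd.DataFrame = field(repr=False)   # encoded rows used for the fit
    patient_ids: frozenset = field(default_factory=frozenset, repr=False)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)


def fit_cox(person_periods: pd.DataFrame, predictor_set: str,
            adjustment: list[str] | None = None, strata: str | None = "site",
            outcome: str = "") -> CoxFit:
    """Fit one Cox specification on counting-process rows.

    ``person_periods`` needs columns start, stop, event, the predictors
    of the chosen set, the adjustment covariates, and the strata column.
    Covariate values are those at each row's start.  Dummy columns with
    no variation are dropped (and recorded) rather than left singular.
    """
    if predictor_set not in PREDICTOR_SETS:
        raise ValueError(f"unknown predictor_set {predictor_set!r}")
    if adjustment is None:
        adjustment = DEFAULT_ADJUSTMENT
    n_events = int(person_periods["event"].sum())
    if n_events == 0:
        raise NoEventsError(f"no events for outcome {outcome!r}")

    columns = PREDICTOR_SETS[predictor_set] + list(adjustment)
    X = encode_covariates(person_periods, columns)
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=dropped)

    data = X.copy()
    data["start"] = person_periods["start"].to_numpy(dtype=float)
    data["stop"] = person_periods["stop"].to_numpy(dtype=float)
    data["event"] = person_periods["event"].to_numpy(dtype=int)
    if strata is not None:
        data[strata] = person_periods[strata].astype(str).to_numpy()

    cph = CoxPHFitter()
    cph.fit(data, duration_col="stop", event_col="event", entry_col="start",
            strata=strata, show_progress=False)

    fit = CoxFit(
        outcome=outcome,
        predictor_set=predictor_set,
        params=cph.params_.copy(),
        cov=cph.variance_matrix_.copy(),
        aic=float(cph.AIC_partial_),
        log_likelihood=float(cph.log_likelihood_),
        n_events=n_events,
        n_rows=len(data),
        ph_pvalues=pd.Series(dtype=float),
        strata_col=strata,
        design_columns=list(X.columns),
        dropped_columns=dropped,
        _data=data,
        patient_ids=frozenset(person_periods["patient_id"].unique())
        if "patient_id" in person_periods else frozenset(),
    )
    fit.ph_pvalues = schoenfeld_ph_test(fit)
    return fit


@dataclass
class ContrastResult:
    """Exponentiated linear contrast: hazard ratio with a 95% Wald CI."""

    label: str
    hr: float
    ci_low: float
    ci_high: float


def hr_contrast(fit: CoxFit, variable: str, delta: float, label: str | None = None) -> ContrastResult:
    """Hazard ratio for a ``delta``-unit increase of one per-unit covariate."""
    if variable not in fit.params.index:
        raise KeyError(f"{variable!r} not in fitted model ({list(fit.params.index)})")
    beta = float(fit.params[variable])
    se = float(np.sqrt(fit.cov.loc[variable, variable]))
    hr = float(np.exp(beta * delta))
    z = stats.norm.ppf(0.975)
    lo = float(np.exp((beta - z * se) * delta))
    hi = float(np.exp((beta + z * se) * delta))
    if delta < 0:
        lo, hi = hi, lo
    return ContrastResult(label or f"+{delta:g} {variable}", hr, lo, hi)


def compare_aic(fits: list[CoxFit]) -> pd.DataFrame:
    """Rank specifications of one outcome by AIC (lower is better).

    Fits must share the outcome and the risk set — same rows, events,
    and patients — otherwise partial likelihoods are not comparable.
    """
    if len({f.outcome for f in fits}) != 1:
        raise ValueError("AIC comparison across different outcomes")
    first = fits[0]
    for f in fits[1:]:
        if (f.n_rows, f.n_events, f.patient_ids) != (first.n_rows, first.n_events, first.patient_ids):
            raise ValueError("AIC comparison across different risk sets")
    out = pd.DataFrame({
        "predictor_set": [f.predictor_set for f in fits],
        "aic": [f.aic for f in fits],
        "log_likelihood": [f.log_likelihood for f in fits],
        "k": [len(f.params) for f in fits],
    }).sort_values("aic", kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _risk_sets(fit: CoxFit):
    """Yield (stratum, X, start, stop, event) arrays per stratum."""
    data = fit._data
    if fit.strata_col is None:
        groups = [("", data)]
    else:
        groups = list(data.groupby(fit.strata_col, sort=True))
    for name, g in groups:
        X = g[fit.design_columns].to_numpy(dtype=float)
        yield (name, X, g["start"].to_numpy(), g["stop"].to_numpy(),
               g["event"].to_numpy(dtype=bool))


def breslow_baseline(fit: CoxFit) -> dict[str, pd.DataFrame]:
    """Breslow baseline cumulative hazard Λ₀(t) per stratum, at covariates 0."""
    beta = fit.params.to_numpy()
    out = {}
    for name, X, start, stop, event in _risk_sets(fit):
        lp = X @ beta
        elp = np.exp(lp)
        times = np.unique(stop[event])
        dj = np.array([np.sum(event & (stop == t)) for t in times], dtype=float)
        denom = np.array([elp[(start < t) & (t <= stop)].sum() for t in times])
        cumhaz = np.cumsum(dj / denom)
        out[str(name)] = pd.DataFrame({"time": times, "cumhaz": cumhaz})
    return out


@dataclass
class SurvivalCurve:
    """Predicted survival for a fixed hypothetical covariate profile."""

    label: str
    stratum: str
    times: np.ndarray
    survival: np.ndarray


def predict_survival(fit: CoxFit, profile: dict, stratum: str | None = None,
                     label: str = "") -> SurvivalCurve:
    """S(t) = exp(−Λ₀(t)·exp(xβ)) for a profile held constant over time.

    ``profile`` gives raw covariate values (e.g. ``{"pct_below": 50,
    "sex": "male", ...}``); every fitted covariate must be derivable
    from it, otherwise the missing one is named in the error.
    """
    raw_needed = set()
    for col in fit.design_columns:
        base = next((c for c in CATEGORICAL_LEVELS if col.startswith(f"{c}_")), col)
        raw_needed.add(base)
    missing = sorted(c for c in raw_needed if c not in profile)
    if missing:
        raise KeyError(f"profile missing covariate(s): {', '.join(missing)}")

    row = pd.DataFrame([profile])
    raw_cols = sorted(raw_needed)
    x = encode_covariates(row, raw_cols).reindex(columns=fit.design_columns, fill_value=0.0)
    lp = float((x.to_numpy() @ fit.params.to_numpy())[0])

    baselines = breslow_baseline(fit)
    if stratum is None:
        if len(baselines) != 1:
            raise ValueError(f"stratified fit: choose a stratum among {sorted(baselines)}")
        stratum = next(iter(baselines))
    base = baselines[str(stratum)]
    times = np.concatenate([[0.0], base["time"].to_numpy()])
    surv = np.concatenate([[1.0], np.exp(-base["cumhaz"].to_numpy() * np.exp(lp))])
    # every emitted curve honours the survival-function contract
    assert surv[0] == 1.0 and np.all(np.diff(surv) <= 0) and np.all((surv >= 0) & (surv <= 1))
    return SurvivalCurve(label or str(profile), str(stratum), times, surv)


def schoenfeld_ph_test(fit: CoxFit) -> pd.Series:
    """Schoenfeld-residual proportional-hazards score test (rank transform).

    For each event, the residual is the event's covariate vector minus
    the risk-set mean weighted by exp(xβ); residuals are scaled by
    d·Var(β̂) and correlated with the rank of the event time.  Per
    covariate, the statistic is compared to χ²₁.  Ties use the
    Breslow-style risk-set mean.
    """
    beta = fit.params.to_numpy()
    p = len(beta)
    resids, times = [], []
    for _, X, start, stop, event in _risk_sets(fit):
        elp = np.exp(X @ beta)
        for t in np.unique(stop[event]):
            at_risk = (start < t) & (t <= stop)
            w = elp[at_risk]
            xbar = (X[at_risk] * w[:, None]).sum(axis=0) / w.sum()
            for i in np.nonzero(event & (stop == t))[0]:
                resids.append(X[i] - xbar)
                times.append(t)
    resids = np.asarray(resids)
    times = np.asarray(times, dtype=float)
    d = len(times)
    if d < 3:
        return pd.Series(np.nan, index=fit.params.index)
    scaled = d * (fit.cov.to_numpy() @ resids.T).T        # d·V·s per event
    g = stats.rankdata(times)
    gc = g - g.mean()
    se2 = np.diag(fit.cov.to_numpy())
    T = (gc @ scaled) ** 2 / (d * se2 * np.sum(gc ** 2))
    return pd.Series(stats.chi2.sf(T, 1), index=fit.params.index)


# ---------------------------------------------------------------------------
# fractional logit

@dataclass
class FractionalLogitFit:
    """Quasi-binomial logistic fit on a proportion outcome, robust SEs."""

    params: pd.Series
    cov: pd.DataFrame
    n: int

    def odds_ratio(self, variable: str, delta: float = 1.0) -> tuple[float, float, float]:
        """OR (with 95% CI) for a ``delta``-unit increase of one covariate."""
        beta = float(self.params[variable])
        se = float(np.sqrt(self.cov.loc[variable, variable]))
        z = stats.norm.ppf(0.975)
        lo, hi = np.exp((beta - z * se) * delta), np.exp((beta + z * se) * delta)
        if delta < 0:
            lo, hi = hi, lo
        return float(np.exp(beta * delta)), float(lo), float(hi)


def fit_fractional_logit(df: pd.DataFrame, outcome_col: str,
                         covariates: list[str]) -> FractionalLogitFit:
    """Logistic quasi-likelihood fit of a fractional (0–1) outcome.

    The binomial log-likelihood is a valid quasi-likelihood for
    proportions; robust (HC1) standard errors make inference valid
    without the binomial variance assumption.  With a binary 0/1
    outcome this reduces to ordinary logistic regression.
    """
    y = pd.to_numeric(df[outcome_col]).to_numpy(dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fractional outcome must lie in [0, 1]")
    X = encode_covariates(df, covariates)
    X = X.loc[:, X.nunique() > 1]
    X = sm.add_constant(X, has_constant="add")
    import warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*non-integer.*")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC1")
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("fractional logit did not converge (separation?)")
    return FractionalLogitFit(params=res.params, cov=pd.DataFrame(
        res.cov_params(), index=res.params.index, columns=res.params.index), n=len(y))


# ---------------------------------------------------------------------------
# log-linear contrast algebra on published-style grids

def recover_per_unit_coefficient(deltas: list[float], hrs: list[float]) -> float:
    """Per-unit log-hazard from contrasts (δ, HR) sharing one coefficient.

    Least squares of log HR on δ through the origin — exact when the
    grid is internally log-linear, and the natural reconciliation when
    printed values carry rounding error.
    """
    d = np.asarray(deltas, dtype=float)
    lh = np.log(np.asarray(hrs, dtype=float))
    return float(np.sum(d * lh) / np.sum(d * d))


def predict_contrast(beta_per_unit: float, delta: float) -> float:
    """HR implied by a per-unit coefficient at a ``delta``-unit increase."""
    return float(np.exp(beta_per_unit * delta))
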