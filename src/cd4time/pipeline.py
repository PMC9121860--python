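"""End-to-end orchestration: simulate → build → fit → report.

Stages are plain functions over in-memory tables; ``run_pipeline`` wires
them together, logs Figure-1-style flow counts (included plus every
exclusion category equals the input), and writes a deterministic report
bundle: cohort tables, follow-up windows and exclusions, per-outcome
person-period tables, fitted-model summaries with hazard-ratio contrast
grids and AIC triplets, survival-curve data for hypothetical exposure
profiles, and a plain-text summary.  Every run writes its resolved
configuration next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from lifelines.exceptions import ConvergenceError

from cd4time import eligibility, exposure, models, outcomes as outcomes_mod
from cd4time.cohort_io import Cohort, write_cohort
from cd4time.synthetic import SimConfig, generate_cohort

log = logging.getLogger("cd4time")

DAYS_PER_YEAR = 365.25


@dataclass
class RunConfig:
    """Resolved configuration for a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    closure_date: str = "2019-12-31"
    outcomes: tuple[str, ...] = outcomes_mod.OUTCOMES
    predictor_sets: tuple[str, ...] = ("pct_only", "cd4_only", "both")
    pct_deltas: tuple[float, ...] = (15.0, 50.0, 90.0)
    cd4_deltas: tuple[float, ...] = (150.0, 300.0)
    cd4_ref: float = 200.0
    adjustment: tuple[str, ...] = tuple(models.DEFAULT_ADJUSTMENT)
    no_snade_sites: tuple[str, ...] = ("Honduras",)
    curve_profile: dict = field(default_factory=lambda: {
        "sex": "male", "risk": "MSM", "age": 40.0, "education": "secondary",
        "baseline_group": "lt200", "art_year": 2012.0, "current_cd4": 350.0})
    curve_stratum: str = "Brazil"
    curve_pcts: tuple[float, ...] = (0.0, 50.0, 90.0)

    def __post_init__(self) -> None:
        unknown = set(self.outcomes) - set(outcomes_mod.OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcome(s): {sorted(unknown)}")
        if any(d < 0 for d in tuple(self.pct_deltas) + tuple(self.cd4_deltas)):
            raise ValueError("contrast deltas must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def build_person_period_tables(cohort: Cohort, windows: pd.DataFrame,
                               config: RunConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Expand every windowed patient into per-outcome counting-process tables.

    Also returns a per-patient summary with the final exposure fraction
    (for the fractional-logit model) and total suppressed follow-up.
    """
    art_starts = cohort.patients.set_index("patient_id")["art_start_date"]
    pat_info = cohort.patients.set_index("patient_id").to_dict("index")
    outcome_table = outcomes_mod.code_outcomes_table(
        cohort.events, windows, art_starts, outcomes=config.outcomes)
    oc = {(r.patient_id, r.outcome): r for r in outcome_table.itertuples(index=False)}

    labs = cohort.labs[cohort.labs["kind"] == "CD4"]
    cd4_groups = {pid: ((g["date"] - art_starts[pid]).dt.days.to_numpy(),
                        g["value"].to_numpy(dtype=float))
                  for pid, g in labs.groupby("patient_id", sort=False)}

    chunks: dict[str, list] = {o: [] for o in config.outcomes}
    patient_rows = []
    sites = windows["patient_id"].map(lambda p: pat_info[p]["site"])
    included = {o: outcomes_mod.site_filter(
        windows.assign(site=sites), o, set(config.no_snade_sites)).to_numpy()
        for o in config.outcomes}

    for pos, w in enumerate(windows.itertuples(index=False)):
        pid = w.patient_id
        info = pat_info[pid]
        days, vals = cd4_groups[pid]
        f = exposure.build_step_function(days, vals, int(w.t_vs), end_day=int(w.end_day))
        followed = min(f.end, int(w.end_day) - int(w.t_vs))
        final_pct = exposure.pct_time_below(f, followed) if followed > 0 else 0.0
        covs = {
            "sex": info["sex"], "age": float(info["age_at_art"]), "risk": info["risk"],
            "education": info["education"], "site": info["site"],
            "art_year": float(info["art_start_date"].year),
            "baseline_group": w.baseline_group,
        }
        patient_rows.append({
            "patient_id": pid, **covs,
            "t_vs": int(w.t_vs), "followup_days": followed,
            "final_pct_below": final_pct,
            "vs_year": float((info["art_start_date"] + pd.Timedelta(days=int(w.t_vs))).year),
        })
        for o in config.outcomes:
            if not included[o][pos]:
                continue
            rec = oc[(pid, o)]
            event_time = (rec.event_day - w.t_vs) if rec.event else None
            arrays = exposure.person_period_arrays(f, followed, event_time)
            if arrays is not None:
                chunks[o].append((pid, covs, arrays))

    pp_tables = {}
    for o, ch in chunks.items():
        if not ch:
            pp_tables[o] = pd.DataFrame(columns=exposure.PERSON_PERIOD_COLUMNS)
            continue
        sizes = [len(a[2][0]) for a in ch]
        cols = {
            "patient_id": np.repeat([a[0] for a in ch], sizes),
            "start": np.concatenate([a[2][0] for a in ch]),
            "stop": np.concatenate([a[2][1] for a in ch]),
            "event": np.concatenate([a[2][2] for a in ch]),
            "pct_below": np.concatenate([a[2][3] for a in ch]),
            "current_cd4": np.concatenate([a[2][4] for a in ch]),
        }
        for key in ("sex", "age", "risk", "education", "site", "art_year", "baseline_group"):
            cols[key] = np.repeat([a[1][key] for a in ch], sizes)
        pp_tables[o] = pd.DataFrame(cols)
    return pp_tables, pd.DataFrame(patient_rows)


def crude_incidence(pp: pd.DataFrame) -> dict:
    """Events, person-years, and crude rate per 1000 person-years."""
    person_days = float((pp["stop"] - pp["start"]).sum())
    events = int(pp["event"].sum())
    py = person_days / DAYS_PER_YEAR
    return {"events": events, "person_years": py,
            "rate_per_1000py": 1000.0 * events / py if py > 0 else float("nan")}


def _contrast_grid(fit: models.CoxFit, config: RunConfig) -> dict:
    grid = {}
    if "pct_below" in fit.params.index:
        grid["pct_below"] = {
            f"{d:g}% vs 0%": dataclasses.asdict(
                models.hr_contrast(fit, "pct_below", d, label=f"{d:g}% vs 0%"))
            for d in config.pct_deltas}
    if "current_cd4" in fit.params.index:
        grid["current_cd4"] = {
            f"{config.cd4_ref + d:g} vs {config.cd4_ref:g}": dataclasses.asdict(
                models.hr_contrast(fit, "current_cd4", d,
                                   label=f"{config.cd4_ref + d:g} vs {config.cd4_ref:g}"))
            for d in config.cd4_deltas}
    return grid


def fit_all_models(pp_tables: dict[str, pd.DataFrame], config: RunConfig
                   ) -> tuple[dict, dict[str, dict[str, models.CoxFit]], list[models.SurvivalCurve]]:
    """Fit every (outcome, predictor set), contrasts, AIC ranking, curves."""
    results: dict = {}
    fits: dict[str, dict[str, models.CoxFit]] = {}
    curves: list[models.SurvivalCurve] = []
    for o in config.outcomes:
        pp = pp_tables[o]
        entry: dict = {"n_patients": int(pp["patient_id"].nunique()) if len(pp) else 0,
                       **crude_incidence(pp)}
        fits[o] = {}
        per_set = {}
        for ps in config.predictor_sets:
            try:
                fit = models.fit_cox(pp, ps, adjustment=list(config.adjustment),
                                     strata="site", outcome=o)
            except models.NoEventsError:
                per_set[ps] = {"error": "no events"}
                continue
            except ConvergenceError as exc:
                log.warning("fit %s/%s did not converge: %s", o, ps, exc)
                per_set[ps] = {"error": "did not converge"}
                continue
            fits[o][ps] = fit
            per_set[ps] = {
                "coefficients": fit.params.round(10).to_dict(),
                "se": fit.se.round(10).to_dict(),
                "aic": fit.aic,
                "n_events": fit.n_events,
                "ph_pvalues": fit.ph_pvalues.round(8).to_dict(),
                "contrasts": _contrast_grid(fit, config),
            }
        entry["models"] = per_set
        if len(fits[o]) == len(config.predictor_sets):
            entry["aic_ranking"] = models.compare_aic(list(fits[o].values())).to_dict("records")
        results[o] = entry

        if "pct_only" in fits[o]:
            for pct in config.curve_pcts:
                profile = dict(config.curve_profile)
                profile["pct_below"] = float(pct)
                try:
                    curves.append(models.predict_survival(
                        fits[o]["pct_only"], profile, stratum=config.curve_stratum,
                        label=f"{o}:pct={pct:g}"))
                except (KeyError, ValueError) as exc:  # e.g. stratum absent in tiny cohorts
                    log.warning("survival curve skipped for %s pct=%s: %s", o, pct, exc)
    return results, fits, curves


def descriptives(patient_table: pd.DataFrame) -> dict:
    """Cohort description by baseline CD4 group (counts, medians, IQRs)."""
    def med_iqr(s: pd.Series) -> dict:
        if len(s) == 0:
            return {"median": float("nan"), "q1": float("nan"), "q3": float("nan")}
        return {"median": float(s.median()), "q1": float(s.quantile(0.25)),
                "q3": float(s.quantile(0.75))}

    out = {}
    for name, g in [("all", patient_table)] + list(patient_table.groupby("baseline_group")):
        out[str(name)] = {
            "n": int(len(g)),
            "pct_male": 100.0 * float((g["sex"] == "male").mean()) if len(g) else float("nan"),
            "age": med_iqr(g["age"]),
            "followup_months": med_iqr(g["followup_days"] / 30.4375),
            "final_pct_below": med_iqr(g["final_pct_below"]),
        }
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 cohort: Cohort | None = None) -> dict:
    """Execute all stages and write the report bundle; returns results dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        cohort, truth = generate_cohort(config.sim)
        truth.to_csv(out / "truth.csv", index=False)
    write_cohort(cohort, out)

    windows, exclusions = eligibility.build_followup_windows(cohort, config.closure_date)
    windows.to_csv(out / "windows.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    flow = {"input_patients": int(len(cohort.patients)),
            "included": int(len(windows)),
            **{r: int((exclusions["reason"] == r).sum()) for r in eligibility.EXCLUSION_REASONS}}
    assert flow["included"] + sum(flow[r] for r in eligibility.EXCLUSION_REASONS) == flow["input_patients"]
    for pid, reason in exclusions.itertuples(index=False):
        log.info("excluded %s: %s", pid, reason)

    pp_tables, patient_table = build_person_period_tables(cohort, windows, config)
    for o, pp in pp_tables.items():
        pp.to_csv(out / f"person_periods_{o}.csv", index=False)
    patient_table.to_csv(out / "patient_summary.csv", index=False)

    results, fits, curves = fit_all_models(pp_tables, config)

    frac = None
    model_patients = patient_table[patient_table["followup_days"] > 0]
    if len(model_patients) > 50:
        try:
            frac = models.fit_fractional_logit(
                model_patients.assign(final_frac=model_patients["final_pct_below"] / 100.0),
                "final_frac",
                ["sex", "age", "risk", "education", "site", "baseline_group", "art_year", "vs_year"])
        except (RuntimeError, ValueError) as exc:
            log.warning("fractional logit skipped: %s", exc)

    bundle = {
        "flow": flow,
        "descriptives": descriptives(patient_table),
        "outcomes": results,
    }
    if frac is not None:
        bundle["fractional_logit"] = {
            "coefficients": frac.params.round(10).to_dict(),
            "se": pd.Series(np.sqrt(np.diag(frac.cov)), index=frac.params.index).round(10).to_dict(),
            "or_male": frac.odds_ratio("sex_male")[0] if "sex_male" in frac.params else None,
            "or_age_per_decade": frac.odds_ratio("age", 10.0)[0] if "age" in frac.params else None,
            "or_baseline_lt200": frac.odds_ratio("baseline_group_lt200")[0]
            if "baseline_group_lt200" in frac.params else None,
        }

    curve_rows = [
        {"label": c.label, "stratum": c.stratum, "time": float(t), "survival": float(s)}
        for c in curves for t, s in zip(c.times, c.survival)
    ]
    pd.DataFrame(curve_rows, columns=["label", "stratum", "time", "survival"]).to_csv(
        out / "curves.csv", index=False)

    (out / "results.json").write_text(json.dumps(bundle, indent=2, sort_keys=True,
                                                 default=float) + "\n")
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    (out / "summary.txt").write_text(_summary_text(bundle))
    return bundle


def _summary_text(bundle: dict) -> str:
    lines = ["cd4time pipeline summary", "=" * 24, ""]
    flow = bundle["flow"]
    lines.append(f"patients in: {flow['input_patients']}, included: {flow['included']}")
    for k, v in flow.items():
        if k not in ("input_patients", "included"):
            lines.append(f"  excluded ({k}): {v}")
    lines.append("")
    for o, r in bundle["outcomes"].items():
        lines.append(f"outcome {o}: {r['events']} events over {r['person_years']:.1f} PY "
                     f"({r['rate_per_1000py']:.2f} /1000 PY)")
        m = r["models"].get("pct_only", {})
        for lbl, c in m.get("contrasts", {}).get("pct_below", {}).items():
            lines.append(f"    HR {lbl}: {c['hr']:.2f} ({c['ci_low']:.2f}-{c['ci_high']:.2f})")
    return "\n".join(lines) + "\n"
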