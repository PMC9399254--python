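"""End-to-end orchestration: tables in, estimate tables out.

The run mirrors a pharmacoepidemiological protocol: clean prescriptions
(analgesia-formulation exclusions), censor at modality switch, apply
age/registration eligibility, reconstruct treatment episodes, split
follow-up into risk windows, ascertain non-fatal overdoses from coded
admissions, estimate stabilised IPWs from baseline covariates, and fit
unadjusted / adjusted / weighted rate models plus first-event Cox models,
finishing with E-values for the headline contrasts.  Every input patient
lands in the audit log exactly once, as included or excluded-with-reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from oatrisk.ascertain import (
    CodeList,
    classify_admissions,
    classify_deaths,
    default_code_list,
)
from oatrisk.episodes import (
    build_episodes,
    build_follow_up,
    censor_at_switch,
    clean_prescriptions,
    episode_summaries,
)
from oatrisk.evalue import e_value
from oatrisk.models import (
    crude_rate_ratio,
    fit_cox_first_event,
    fit_negbin,
    fit_poisson,
    overdispersion_test,
)
from oatrisk.persontime import (
    aggregate,
    apply_censor_variant,
    attribute_events,
    first_event_view,
    split_follow_up,
)
from oatrisk.weighting import fit_propensity, stabilised_ipw, standardised_differences

EPOCH = pd.Timestamp("1970-01-01")
BASE_COVARIATES = ("age_band", "gender", "imd_quintile", "region")
SCHEMA_PATIENT_COLS = {
    "patient_id", "birth_date", "gender", "region", "imd_quintile",
    "regist_start", "regist_end",
}


@dataclass
class RunConfig:
    """All knobs of a pipeline run; serialised alongside outputs."""

    supply_days: int = 14
    max_gap_days: int = 14
    overlap_mode: str = "extend"
    window_days: int = 28
    censor_variant: str = "none"
    censor_years: float | None = None
    study_end: str = "2017-12-31"
    matching: str = "prefix"
    any_position: bool = True
    covariates: tuple | None = None  # None = schema covariates + extra flags
    model_family: str = "auto"  # poisson | negbin | auto (LRT-decided)
    dispersion_level: float = 0.05
    fit_models: bool = True
    fit_cox: bool = True
    code_list_path: str | None = None

    def validate(self) -> None:
        if self.supply_days < 1 or self.max_gap_days < 1 or self.window_days < 1:
            raise ValueError("supply_days, max_gap_days, window_days must be >= 1")
        if self.overlap_mode not in ("extend", "stack"):
            raise ValueError("overlap_mode must be 'extend' or 'stack'")
        if self.model_family not in ("poisson", "negbin", "auto"):
            raise ValueError("model_family must be poisson|negbin|auto")


@dataclass
class RunResult:
    config: RunConfig
    follow_up: pd.DataFrame
    episodes: pd.DataFrame
    intervals: pd.DataFrame
    aggregates: dict
    balance: pd.DataFrame
    weights: pd.Series
    rate_tables: pd.DataFrame
    hazard_tables: pd.DataFrame
    evalues: pd.DataFrame
    audit: pd.DataFrame
    dispersion: dict
    episode_summary: pd.DataFrame = field(default=None)


def _days(series) -> pd.Series:
    return (pd.to_datetime(series) - EPOCH).dt.days


def ingest_tables(patients, prescriptions, admissions, deaths):
    """Add integer day columns (days since 1970-01-01) for all dates."""
    pa = patients.copy()
    for col, out in (("birth_date", "birth_day"), ("regist_start", "regist_start_day"),
                     ("regist_end", "regist_end_day")):
        pa[out] = _days(pa[col])
    rx = prescriptions.copy()
    rx["issue_day"] = _days(rx["issue_date"])
    adm = admissions.copy()
    if len(adm):
        adm["admission_day"] = _days(adm["admission_date"])
    else:
        adm["admission_day"] = pd.Series(dtype=int)
    de = deaths.copy()
    if len(de):
        de["death_day"] = _days(de["death_date"])
    else:
        de["death_day"] = pd.Series(dtype=int)
    return pa, rx, adm, de


def _age_band(age: int) -> str:
    if age <= 24:
        return "18-24"
    if age <= 34:
        return "25-34"
    if age <= 44:
        return "35-44"
    return "45-64"


def baseline_covariates(patients: pd.DataFrame, follow_up: pd.DataFrame,
                        names: tuple | None = None) -> pd.DataFrame:
    """Per-patient baseline covariate frame aligned to the follow-up table.

    Default set: age band at index, gender, IMD quintile, region, plus any
    extra binary flag columns present on the patients table (comorbidity /
    co-prescription history).
    """
    extra = [c for c in patients.columns
             if c not in SCHEMA_PATIENT_COLS and not c.endswith("_day")]
    merged = follow_up.merge(patients, on="patient_id", how="left")
    cov = pd.DataFrame(index=follow_up.index)
    cov["age_band"] = merged["age_at_index"].map(_age_band)
    cov["gender"] = merged["gender"]
    cov["imd_quintile"] = merged["imd_quintile"].astype(str)
    cov["region"] = merged["region"]
    for c in extra:
        cov[c] = merged[c].astype(int).astype(str)
    if names is not None:
        cov = cov[list(names)]
    return cov


def _factor_refs(covariates: pd.DataFrame) -> dict:
    """Most frequent level of each covariate as its reference."""
    return {c: str(covariates[c].mode().iloc[0]) for c in covariates.columns}


def run_pipeline(patients, prescriptions, admissions, deaths,
                 config: RunConfig | None = None,
                 code_list: CodeList | None = None) -> RunResult:
    """Execute the full analysis on the four input tables."""
    config = config or RunConfig()
    config.validate()
    if code_list is None:
        code_list = (CodeList.from_csv(config.code_list_path)
                     if config.code_list_path else default_code_list())
    pa, rx, adm, de = ingest_tables(patients, prescriptions, admissions, deaths)
    study_end_day = int(_days(pd.Series([config.study_end])).iloc[0])
    audit_rows = []

    # 1. formulation exclusions, then modality assignment / switch censoring
    n0 = len(rx)
    rx = clean_prescriptions(rx, code_list)
    stream, switches, ties = censor_at_switch(rx)
    for pid in ties["patient_id"]:
        audit_rows.append((pid, "excluded", "both modalities on index date"))
    no_rx = set(pa["patient_id"]) - set(stream["patient_id"]) - set(ties["patient_id"])
    for pid in sorted(no_rx):
        audit_rows.append((pid, "excluded", "no eligible prescriptions"))

    # 2. eligibility and observation window
    follow_up, exclusions = build_follow_up(
        pa, stream, switches, study_end_day, deaths=de
    )
    for row in exclusions.itertuples(index=False):
        audit_rows.append((row.patient_id, "excluded", row.reason))

    stream = stream[stream["patient_id"].isin(follow_up["patient_id"])]
    episodes = build_episodes(
        stream, config.supply_days, config.max_gap_days, config.overlap_mode
    )
    follow_up = apply_censor_variant(
        follow_up, episodes, config.censor_variant, config.censor_years
    )
    for pid in follow_up["patient_id"]:
        audit_rows.append((pid, "included", ""))
    audit = pd.DataFrame(audit_rows, columns=["patient_id", "status", "reason"])

    # 3. risk-window person-time and outcome attribution
    intervals = split_follow_up(episodes, follow_up, config.window_days)
    nonfatal = classify_admissions(adm, code_list, config.matching, config.any_position)
    nonfatal = nonfatal.merge(adm[["admission_id", "admission_day"]].drop_duplicates(),
                              left_on="source_id", right_on="admission_id")
    events = nonfatal.merge(
        follow_up[["patient_id", "index_day"]], on="patient_id", how="inner"
    )
    events["day"] = events["admission_day"] - events["index_day"]
    intervals, attributed = attribute_events(
        intervals, events[["patient_id", "day", "source_id"]]
    )
    fatal = classify_deaths(de, code_list, config.matching)

    aggregates = {
        "window": aggregate(intervals, ["window"]),
        "window_drug": aggregate(intervals, ["window", "drug"]),
        "drug": aggregate(intervals, ["drug"]),
        "status": aggregate(
            intervals.assign(status=np.where(
                intervals["window"].str.startswith("in"), "in", "out")),
            ["status"],
        ),
    }

    # 4. weighting and balance
    covariates = baseline_covariates(pa, follow_up, config.covariates)
    prop = fit_propensity(covariates, follow_up["drug"])
    weights = stabilised_ipw(prop.scores, follow_up["drug"])
    balance = standardised_differences(covariates, follow_up["drug"]).merge(
        standardised_differences(covariates, follow_up["drug"], weights),
        on="indicator", suffixes=("_unweighted", "_weighted"),
    )
    wtab = pd.DataFrame({"patient_id": follow_up["patient_id"],
                         "weight": weights.to_numpy()})

    rate_tables = hazard_tables = pd.DataFrame()
    dispersion = {}
    evalues = pd.DataFrame()
    if config.fit_models:
        rate_tables, dispersion = _fit_rate_models(
            intervals, covariates, follow_up, wtab, config
        )
        if config.fit_cox:
            hazard_tables = _fit_hazard_models(
                intervals, attributed, covariates, follow_up, wtab
            )
        evalues = _evalue_table(rate_tables)

    return RunResult(
        config=config,
        follow_up=follow_up,
        episodes=episodes,
        intervals=intervals,
        aggregates=aggregates,
        balance=balance,
        weights=weights,
        rate_tables=rate_tables,
        hazard_tables=hazard_tables,
        evalues=evalues,
        audit=audit,
        dispersion=dispersion,
        episode_summary=episode_summaries(episodes, follow_up),
    )


def _records(intervals, covariates, follow_up, wtab):
    rec = intervals.copy()
    rec["person_years"] = (rec["end"] - rec["start"]) / 365.25
    rec = rec[rec["person_years"] > 0]
    cov = covariates.copy()
    cov["patient_id"] = follow_up["patient_id"].to_numpy()
    rec = rec.merge(cov, on="patient_id").merge(wtab, on="patient_id")
    rec["status"] = np.where(rec["window"].str.startswith("in"), "in", "out")
    return rec


def _fit_family(records, factors, family, weights=None, cluster="patient_id"):
    fit_fn = fit_negbin if family == "negbin" else fit_poisson
    return fit_fn(records, factors, weights=weights, cluster=cluster)


def _fit_rate_models(intervals, covariates, follow_up, wtab, config):
    """Unadjusted, adjusted and weighted rate ratios.

    uRR: single-factor Poisson fits — with a saturated categorical
    exposure the MLE reproduces the crude stratum rate ratios exactly, so
    the crude column is genuinely crude.  aRR/wRR: joint exposure model
    (risk window x modality, both time-varying at the interval level),
    plus baseline covariates for aRR and stabilised weights for wRR,
    under the LRT-decided count family.  All CIs are cluster-robust by
    patient.
    """
    rec = _records(intervals, covariates, follow_up, wtab)
    cov_refs = _factor_refs(covariates)
    joint = {"window": "in_gt4", "drug": "methadone"}
    status_joint = {"status": "in", "drug": "methadone"}
    family = config.model_family
    disp = {}
    if family == "auto":
        disp = overdispersion_test(rec, joint, level=config.dispersion_level)
        family = disp["family"]

    rows = []

    def collect(name, prefix, flavour, fit):
        for term in fit.params.index:
            if term.startswith(prefix):
                est = fit.rate_ratio(term, flavour)
                rows.append((name, term, flavour, est.rr, est.ci_low,
                             est.ci_high, fit.kind))

    for name, exposure in (
        ("status", {"status": "in"}),
        ("window", {"window": "in_gt4"}),
        ("drug", {"drug": "methadone"}),
    ):
        collect(name, name, "uRR", fit_poisson(rec, exposure, cluster="patient_id"))

    a_joint = _fit_family(rec, {**joint, **cov_refs}, family)
    w_joint = _fit_family(rec, joint, family, weights="weight")
    collect("window", "window", "aRR", a_joint)
    collect("window", "window", "wRR", w_joint)
    collect("drug", "drug", "aRR", a_joint)
    collect("drug", "drug", "wRR", w_joint)

    a_status = _fit_family(rec, {**status_joint, **cov_refs}, family)
    w_status = _fit_family(rec, status_joint, family, weights="weight")
    collect("status", "status", "aRR", a_status)
    collect("status", "status", "wRR", w_status)

    tables = pd.DataFrame(
        rows, columns=["contrast", "term", "flavour", "rr", "ci_low", "ci_high", "model"]
    )
    return tables, disp


def _fit_hazard_models(intervals, attributed, covariates, follow_up, wtab):
    first = first_event_view(intervals, attributed)
    rec = _records(first.drop(columns=["events"]), covariates, follow_up, wtab)
    cov_refs = _factor_refs(covariates)
    joint = {"window": "in_gt4", "drug": "methadone"}
    rows = []

    def collect(name, prefix, flavour, fit):
        for term in fit.params.index:
            if term.startswith(prefix):
                est = fit.hazard_ratio(term, flavour)
                rows.append((name, term, flavour, est.rr, est.ci_low, est.ci_high))

    for name, exposure in (
        ("window", {"window": "in_gt4"}),
        ("drug", {"drug": "methadone"}),
    ):
        collect(name, name, "uHR", fit_cox_first_event(rec, exposure))
    a_joint = fit_cox_first_event(rec, {**joint, **cov_refs})
    w_joint = fit_cox_first_event(rec, joint, weights="weight")
    for name in ("window", "drug"):
        collect(name, name, "aHR", a_joint)
        collect(name, name, "wHR", w_joint)
    return pd.DataFrame(
        rows, columns=["contrast", "term", "flavour", "hr", "ci_low", "ci_high"]
    )


def _evalue_table(rate_tables: pd.DataFrame) -> pd.DataFrame:
    rows = []
    sel = rate_tables[rate_tables["flavour"] == "wRR"]
    for row in sel.itertuples(index=False):
        res = e_value(row.rr, row.ci_low, row.ci_high)
        rows.append((row.contrast, row.term, row.rr, res.e_value, res.e_value_ci))
    return pd.DataFrame(
        rows, columns=["contrast", "term", "wrr", "e_value", "e_value_ci"]
    )


def crude_window_table(result: RunResult) -> pd.DataFrame:
    """Crude rate-ratio table by risk window (reference: in >4 weeks)."""
    agg = result.aggregates["window"].set_index("window")
    ref = agg.loc["in_gt4"]
    rows = []
    for w in agg.index:
        est = crude_rate_ratio(
            agg.loc[w, "events"], agg.loc[w, "person_years"],
            ref["events"], ref["person_years"], label=w,
        )
        rows.append((w, agg.loc[w, "person_years"], int(agg.loc[w, "events"]),
                     agg.loc[w, "rate_per_100py"], est.rr, est.ci_low, est.ci_high))
    return pd.DataFrame(
        rows, columns=["window", "person_years", "events", "rate_per_100py",
                       "rr", "ci_low", "ci_high"]
    )


SENSITIVITY_VARIANTS = {
    "base": {},
    "supply_7d": {"supply_days": 7},
    "gap_7d": {"max_gap_days": 7},
    "censor_1y_post_treatment": {"censor_variant": "one_year_post_treatment"},
}


def run_sensitivity_suite(patients, prescriptions, admissions, deaths,
                          config: RunConfig | None = None,
                          variants: dict | None = None) -> dict:
    """Crude window rate-ratio tables under each sensitivity variant.

    Variants re-run the exposure construction with a 7-day assumed supply,
    a 7-day discontinuation gap, or censoring one year after the last
    episode; the check of interest is whether the direction of each
    window's rate ratio survives the re-definition.
    """
    from dataclasses import replace

    base = config or RunConfig(fit_models=False)
    out = {}
    for name, overrides in (variants or SENSITIVITY_VARIANTS).items():
        cfg = replace(base, fit_models=False, **overrides)
        res = run_pipeline(patients, prescriptions, admissions, deaths, cfg)
        out[name] = crude_window_table(res)
    return out


def write_report(result: RunResult, outdir) -> None:
    """Write the report bundle as delimited tables plus a JSON summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.balance.to_csv(out / "balance_asd.csv", index=False)
    result.rate_tables.to_csv(out / "rate_ratios.csv", index=False)
    result.hazard_tables.to_csv(out / "hazard_ratios.csv", index=False)
    result.evalues.to_csv(out / "evalues.csv", index=False)
    result.audit.to_csv(out / "audit_log.csv", index=False)
    crude_window_table(result).to_csv(out / "crude_window_rates.csv", index=False)
    for key, df in result.aggregates.items():
        df.to_csv(out / f"aggregate_{key}.csv", index=False)
    if result.episode_summary is not None:
        result.episode_summary.to_csv(out / "episode_summary.csv", index=False)
    with open(out / "run_config.json", "w") as fh:
        json.dump(asdict(result.config), fh, indent=2, default=str)
    summary = {
        "n_patients": int(result.audit[result.audit["status"] == "included"]
                          ["patient_id"].nunique()),
        "n_excluded": int(result.audit[result.audit["status"] == "excluded"]
                          ["patient_id"].nunique()),
        "total_person_years": float(
            (result.intervals["end"] - result.intervals["start"]).sum() / 365.25
        ),
        "total_events": int(result.intervals["events"].sum()),
        "dispersion": {
            k: (bool(v) if isinstance(v, (bool, np.bool_))
                else float(v) if isinstance(v, (int, float, np.floating))
                else v)
            for k, v in result.dispersion.items()
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
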