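"""Synthetic OAT cohort generator with analytically known ground truth.

Emulates the statistical structure of a primary-care opioid-agonist-
treatment cohort linked to hospital admissions and mortality records:

* prescription cascades with within-episode refill gaps, overlapping
  scripts, supply discontinuations and modality switches;
* confounding by indication — baseline covariates that raise the overdose
  hazard also push assignment towards methadone;
* piecewise-constant overdose hazards that are elevated in the first four
  weeks after treatment initiation and after treatment cessation, with a
  protective buprenorphine-vs-methadone effect;
* death (fatal poisoning and other causes) censoring follow-up, plus
  non-outcome "noise" admissions so code-list filtering is exercised.

Events are drawn from a Poisson process whose rate on each person-time
segment is

    baseline_hazard * window_rr[w] * modality_rr^{bup} * exp(sum g_j x_j)

and the realised segment ledger (interval, window, modality, hazard) is
returned as ground truth, so expected event counts per stratum are exact
analytic quantities rather than Monte-Carlo estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

DAYS_PER_YEAR = 365.25
WINDOWS = ("in_1_4", "in_gt4", "out_1_4", "out_gt4")
METHADONE = "methadone"
BUPRENORPHINE = "buprenorphine"

# toy product vocabulary; the *-PATCH / *-LINCTUS / sub-2mg codes are
# analgesia formulations that the cleaning step must remove
OAT_PRODUCTS = {
    METHADONE: ("MTD-ORAL-1MG", "MTD-ORAL-5MG"),
    BUPRENORPHINE: ("BUP-SL-2MG", "BUP-SL-8MG"),
}
ANALGESIA_PRODUCTS = (
    (BUPRENORPHINE, "BUP-PATCH-5"),
    (METHADONE, "MTD-LINCTUS"),
    (BUPRENORPHINE, "BUP-SL-04MG"),
)
NONFATAL_CODES = ("T40.1", "T40.2", "T40.3", "T43.0")
FATAL_CODES = ("X42", "X44", "Y12")
NOISE_ADMISSION_CODES = ("J18.9", "S72.0", "K35.8", "F10.1", "I20.9")
OTHER_DEATH_CODE = "I21.9"

REGIONS = ("North", "South", "East", "West", "London")
REGION_WEIGHTS = (0.25, 0.3, 0.1, 0.15, 0.2)
IMD_WEIGHTS = (0.06, 0.09, 0.14, 0.25, 0.46)


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration field is invalid."""


@dataclass(frozen=True)
class ConfounderSpec:
    """A baseline binary covariate acting on assignment and outcome.

    ``log_odds_bup`` shifts the log-odds of receiving buprenorphine
    (negative values push high-risk patients towards methadone, the
    confounding-by-indication direction); ``log_rate`` shifts the log
    overdose rate.
    """

    name: str
    prevalence: float
    log_odds_bup: float
    log_rate: float


@dataclass(frozen=True)
class EpisodeSpec:
    """Distributional shape of the simulated prescription cascade.

    Scripts per episode are geometric with mean ``mean_scripts_per_episode``,
    except that a fraction ``long_episode_prob`` of episodes come from a
    long-retention regime (geometric with mean ``mean_scripts_long``) so
    that, as in real OAT cohorts, most episodes are short while most
    in-treatment person-time sits in long episodes.  Consecutive issue
    dates within an episode are separated by a uniform integer gap on
    [script_gap_min, script_gap_max] days (gaps below the 14-day supply
    create overlapping scripts, gaps above it are bridged refill delays);
    out-of-treatment gaps are 14 + Exponential days so an episode break is
    always a genuine supply discontinuation.
    """

    mean_scripts_per_episode: float = 2.5
    mean_scripts_long: float = 25.0
    long_episode_prob: float = 0.15
    script_gap_min: int = 7
    script_gap_max: int = 27
    out_gap_mean_days: float = 250.0
    switch_probability: float = 0.15
    switch_hazard: float = 0.25  # per-episode prob of switching, given a switcher


def _default_confounders() -> tuple[ConfounderSpec, ...]:
    return (
        ConfounderSpec("overdose_history", 0.20, -0.8, 0.7),
        ConfounderSpec("benzodiazepine", 0.23, -0.4, 0.4),
        ConfounderSpec("severe_mental_illness", 0.12, -0.5, 0.5),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    baseline_hazard is the overdose event rate (events per person-year) in
    the reference stratum: methadone, in treatment for more than four
    weeks, all covariates at zero.  window_rr must contain exactly the four
    risk-window labels with the in-treatment >4-week stratum as reference.
    """

    n_patients: int = 5000
    seed: int = 0
    baseline_hazard: float = 0.08
    window_rr: dict = field(
        default_factory=lambda: {
            "in_1_4": 5.5,
            "in_gt4": 1.0,
            "out_1_4": 13.0,
            "out_gt4": 1.4,
        }
    )
    modality_rr: float = 0.4
    confounders: tuple = field(default_factory=_default_confounders)
    episode_spec: EpisodeSpec = field(default_factory=EpisodeSpec)
    follow_up_years: float = 10.0
    assignment_intercept: float = -0.70
    entry_window_days: int = 3653
    study_days: int = 7305
    epoch: str = "1998-01-01"
    noise_admission_rate: float = 0.30
    fatal_fraction: float = 0.015
    other_death_rate: float = 0.004
    analgesia_script_prob: float = 0.03

    def validate(self) -> None:
        if not self.n_patients >= 1:
            raise ConfigError("n_patients must be >= 1")
        if not self.baseline_hazard > 0:
            raise ConfigError("baseline_hazard must be > 0")
        if not self.modality_rr > 0:
            raise ConfigError("modality_rr must be > 0")
        if set(self.window_rr) != set(WINDOWS):
            raise ConfigError(
                f"window_rr must have exactly the labels {set(WINDOWS)}"
            )
        if any(v <= 0 for v in self.window_rr.values()):
            raise ConfigError("window_rr values must be > 0")
        if self.window_rr["in_gt4"] != 1.0:
            raise ConfigError("window_rr['in_gt4'] is the reference and must be 1")
        if not self.follow_up_years > 0:
            raise ConfigError("follow_up_years must be > 0")
        for c in self.confounders:
            if not 0 <= c.prevalence <= 1:
                raise ConfigError(f"confounders[{c.name}].prevalence must be in [0,1]")
        es = self.episode_spec
        if es.mean_scripts_per_episode < 1:
            raise ConfigError("episode_spec.mean_scripts_per_episode must be >= 1")
        if not 0 <= es.switch_probability <= 1:
            raise ConfigError("episode_spec.switch_probability must be in [0,1]")


@dataclass
class GroundTruth:
    """Realised latent state of a simulated cohort.

    ``ledger`` holds one row per person-time segment (patient_id, start,
    end in days since index, window, drug, hazard in events/person-year);
    ``patients`` holds per-patient latent values (assignment probability,
    initial modality, switch day, observation end, covariate flags).
    Together these suffice to recompute expected event counts per stratum
    analytically.
    """

    config: SimulationConfig
    ledger: pd.DataFrame
    patients: pd.DataFrame

    def ledger_before_switch(self) -> pd.DataFrame:
        """Segments up to each patient's modality switch (the part of the
        timeline the analysis pipeline retains after switch censoring)."""
        led = self.ledger.merge(
            self.patients[["patient_id", "switch_day"]], on="patient_id"
        )
        led = led[led["switch_day"].isna() | (led["start"] < led["switch_day"])].copy()
        cap = led["switch_day"].fillna(np.inf)
        led["end"] = np.minimum(led["end"], cap).astype(int)
        return led.drop(columns="switch_day")

    def to_json(self, path) -> None:
        payload = {
            "config": _config_to_dict(self.config),
            "ledger": self.ledger.to_dict(orient="list"),
            "patients": self.patients.where(pd.notna(self.patients), None).to_dict(
                orient="list"
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["confounders"] = [asdict(c) for c in config.confounders]
    return d


def _simulate_death(rng, segs, hazards, fatal_fraction, other_rate):
    """First arrival of the combined death process over the segment ledger.

    Returns (death_day, is_overdose_death) or (None, False).  Hazards are
    per-year; segments are (start, end) day intervals.
    """
    for (start, end), h in zip(segs, hazards):
        rate = h * fatal_fraction + other_rate
        if rate <= 0:
            continue
        t_years = rng.exponential(1.0 / rate)
        t_days = t_years * DAYS_PER_YEAR
        if start + t_days < end:
            day = int(start + t_days)
            if day >= end:  # int truncation landed on the boundary
                day = end - 1
            p_od = h * fatal_fraction / rate
            return day, bool(rng.random() < p_od)
    return None, False


def generate_cohort(config: SimulationConfig):
    """Simulate a cohort; returns (patients, prescriptions, admissions,
    deaths, GroundTruth).

    Tables are plain DataFrames with ISO-8601 calendar dates, in the
    pipeline's input schema.  The same config (including seed) produces
    byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    epoch = pd.Timestamp(config.epoch)
    es = config.episode_spec
    conf = list(config.confounders)

    patient_rows, rx_rows, adm_rows, death_rows = [], [], [], []
    ledger_rows, truth_rows = [], []
    admission_seq = 0

    for pid in range(1, config.n_patients + 1):
        patient_id = f"P{pid:06d}"

        # ---- baseline covariates and confounded modality assignment
        x = {c.name: int(rng.random() < c.prevalence) for c in conf}
        lin = config.assignment_intercept + sum(
            c.log_odds_bup * x[c.name] for c in conf
        )
        p_bup = float(expit(lin))
        drug = BUPRENORPHINE if rng.random() < p_bup else METHADONE
        cov_mult = float(np.exp(sum(c.log_rate * x[c.name] for c in conf)))

        age = float(np.clip(rng.normal(34.0, 8.0), 18.2, 64.0))
        gender = "M" if rng.random() < 0.70 else "F"
        region = REGIONS[rng.choice(len(REGIONS), p=REGION_WEIGHTS)]
        imd = int(rng.choice(5, p=IMD_WEIGHTS)) + 1

        entry = int(rng.integers(0, config.entry_window_days))
        fu_days = rng.uniform(1.0, config.follow_up_years) * DAYS_PER_YEAR
        obs_end = int(min(fu_days, config.study_days - entry))
        obs_end = max(obs_end, 30)

        # ---- prescription cascade
        will_switch = rng.random() < es.switch_probability
        switched = False
        switch_day = None
        episodes = []  # (start, end, drug, issue_days)
        t = 0
        while t < obs_end:
            if episodes and will_switch and not switched:
                if rng.random() < es.switch_hazard:
                    drug = BUPRENORPHINE if drug == METHADONE else METHADONE
                    switched = True
                    switch_day = t
            mean_k = (
                es.mean_scripts_long
                if rng.random() < es.long_episode_prob
                else es.mean_scripts_per_episode
            )
            k = int(rng.geometric(1.0 / mean_k))
            issues = [t]
            for _ in range(k - 1):
                nxt = issues[-1] + int(
                    rng.integers(es.script_gap_min, es.script_gap_max + 1)
                )
                if nxt >= obs_end:
                    break
                issues.append(nxt)
            end = min(issues[-1] + 14, obs_end)
            episodes.append((issues[0], end, drug, issues))
            t = issues[-1] + 14 + 14 + int(rng.exponential(es.out_gap_mean_days))

        # ---- risk-window ledger (days since index, half-open intervals)
        segs, seg_meta = [], []
        for i, (s, e, d, _) in enumerate(episodes):
            nxt = episodes[i + 1][0] if i + 1 < len(episodes) else obs_end
            cut = min(s + 28, e)
            segs.append((s, cut))
            seg_meta.append(("in_1_4", d))
            if e > cut:
                segs.append((cut, e))
                seg_meta.append(("in_gt4", d))
            if nxt > e:
                ocut = min(e + 28, nxt)
                segs.append((e, ocut))
                seg_meta.append(("out_1_4", d))
                if nxt > ocut:
                    segs.append((ocut, nxt))
                    seg_meta.append(("out_gt4", d))

        hazards = [
            config.baseline_hazard
            * config.window_rr[w]
            * (config.modality_rr if d == BUPRENORPHINE else 1.0)
            * cov_mult
            for (w, d) in seg_meta
        ]

        # ---- death censoring (fatal poisoning or other cause)
        death_day, od_death = _simulate_death(
            rng, segs, hazards, config.fatal_fraction, config.other_death_rate
        )
        if death_day is not None:
            obs_end = death_day
            kept = []
            for (s, e), meta, h in zip(segs, seg_meta, hazards):
                if s >= obs_end:
                    continue
                kept.append(((s, min(e, obs_end)), meta, h))
            segs = [k[0] for k in kept]
            seg_meta = [k[1] for k in kept]
            hazards = [k[2] for k in kept]
            cause = (
                str(rng.choice(FATAL_CODES)) if od_death else OTHER_DEATH_CODE
            )
            death_rows.append((patient_id, entry + death_day, cause))
            if switch_day is not None and switch_day >= obs_end:
                switch_day = None

        for (s, e), (w, d), h in zip(segs, seg_meta, hazards):
            if e > s:
                ledger_rows.append((patient_id, s, e, w, d, h))

        # ---- non-fatal overdose events (Poisson on each segment)
        for (s, e), h in zip(segs, hazards):
            if e <= s:
                continue
            n = rng.poisson(h * (e - s) / DAYS_PER_YEAR)
            for day in sorted(rng.integers(s, e, n).tolist()):
                admission_seq += 1
                adm_id = f"A{admission_seq:07d}"
                code = str(rng.choice(NONFATAL_CODES))
                adm_rows.append((adm_id, patient_id, entry + day, code, 1))
                if rng.random() < 0.4:
                    extra = str(rng.choice(NOISE_ADMISSION_CODES))
                    adm_rows.append((adm_id, patient_id, entry + day, extra, 2))

        # ---- non-outcome admissions (ascertainment noise)
        n_noise = rng.poisson(config.noise_admission_rate * obs_end / DAYS_PER_YEAR)
        for day in sorted(rng.integers(0, obs_end, n_noise).tolist()):
            admission_seq += 1
            adm_id = f"A{admission_seq:07d}"
            code = str(rng.choice(NOISE_ADMISSION_CODES))
            adm_rows.append((adm_id, patient_id, entry + day, code, 1))

        # ---- prescriptions table
        for s, e, d, issues in episodes:
            for day in issues:
                if day >= obs_end and day > 0:
                    continue
                product = str(rng.choice(OAT_PRODUCTS[d]))
                rx_rows.append((patient_id, entry + day, d, product))
        if rng.random() < config.analgesia_script_prob and obs_end > 1:
            d, product = ANALGESIA_PRODUCTS[
                int(rng.choice(len(ANALGESIA_PRODUCTS)))
            ]
            day = int(rng.integers(0, obs_end))
            rx_rows.append((patient_id, entry + day, d, product))

        regist_start = entry - 30 - int(rng.exponential(200.0))
        patient_rows.append(
            (
                patient_id,
                entry - int(age * DAYS_PER_YEAR),
                gender,
                region,
                imd,
                regist_start,
                entry + obs_end,
                *[x[c.name] for c in conf],
            )
        )
        truth_rows.append(
            (
                patient_id,
                episodes[0][2],
                p_bup,
                switch_day,
                obs_end,
                entry,
                cov_mult,
                *[x[c.name] for c in conf],
            )
        )

    conf_names = [c.name for c in conf]
    patients = pd.DataFrame(
        patient_rows,
        columns=[
            "patient_id",
            "birth_date",
            "gender",
            "region",
            "imd_quintile",
            "regist_start",
            "regist_end",
            *conf_names,
        ],
    )
    for col in ("birth_date", "regist_start", "regist_end"):
        patients[col] = epoch + pd.to_timedelta(patients[col], unit="D")

    prescriptions = pd.DataFrame(
        rx_rows, columns=["patient_id", "issue_date", "drug", "product_code"]
    )
    prescriptions["issue_date"] = epoch + pd.to_timedelta(
        prescriptions["issue_date"], unit="D"
    )
    prescriptions = prescriptions.sort_values(
        ["patient_id", "issue_date"], kind="stable"
    ).reset_index(drop=True)

    admissions = pd.DataFrame(
        adm_rows,
        columns=["admission_id", "patient_id", "admission_date", "diag_code", "position"],
    )
    admissions["admission_date"] = epoch + pd.to_timedelta(
        admissions["admission_date"], unit="D"
    )

    deaths = pd.DataFrame(death_rows, columns=["patient_id", "death_date", "cause_code"])
    if len(deaths):
        deaths["death_date"] = epoch + pd.to_timedelta(deaths["death_date"], unit="D")
    else:
        deaths["death_date"] = pd.to_datetime(deaths["death_date"])

    ledger = pd.DataFrame(
        ledger_rows, columns=["patient_id", "start", "end", "window", "drug", "hazard"]
    )
    truth_patients = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id",
            "initial_drug",
            "p_bup",
            "switch_day",
            "obs_end",
            "entry_day",
            "cov_mult",
            *conf_names,
        ],
    )
    truth = GroundTruth(config=config, ledger=ledger, patients=truth_patients)
    return patients, prescriptions, admissions, deaths, truth


def expected_counts(
    ground_truth: GroundTruth, by=("window", "drug"), before_switch: bool = False
) -> pd.DataFrame:
    """Analytic expected event counts per stratum from the ground-truth ledger.

    Expectation on each segment is hazard x person-time; summing over a
    stratum gives the exact mean of the simulated Poisson counts, for use
    as a simulation oracle.
    """
    led = (
        ground_truth.ledger_before_switch()
        if before_switch
        else ground_truth.ledger
    )
    led = led.assign(person_years=(led["end"] - led["start"]) / DAYS_PER_YEAR)
    led = led.assign(expected_events=led["hazard"] * led["person_years"])
    out = (
        led.groupby(list(by), as_index=False)[["person_years", "expected_events"]]
        .sum()
        .sort_values(list(by), kind="stable")
        .reset_index(drop=True)
    )
    return out
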