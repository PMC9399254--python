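"""Treatment-episode reconstruction from prescription records.

Opioid-agonist-treatment scripts are instalment prescriptions with a
maximum supply of 14 days, so exposure has to be reconstructed: each
prescription covers ``[issue, issue + supply_days)``; the next script
continues the episode if the gap between the running expiry date and its
issue date is below ``max_gap_days``, extends the expiry if it overlaps
the current supply, and otherwise opens an out-of-treatment period.
Patients who receive both methadone and buprenorphine are censored at
the switch so each analysed patient carries a single modality.

All dates in this module are integer day numbers (days since an arbitrary
epoch); intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from oatrisk.ascertain import CodeList

log = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44
DURATION_BANDS = (
    ("up to 1 month", 0.0, 1.0),
    ("1-3 months", 1.0, 3.0),
    ("3-6 months", 3.0, 6.0),
    ("6-12 months", 6.0, 12.0),
    ("> 12 months", 12.0, np.inf),
)


def clean_prescriptions(
    prescriptions: pd.DataFrame, exclusion_list: CodeList, matching: str = "exact"
) -> pd.DataFrame:
    """Drop analgesia-formulation scripts (patches, linctus, sub-2mg
    sublingual tablets) whose product code is in the exclusion list.

    Matching is exact on product codes by default.  An empty exclusion
    list returns the input unchanged; removals are logged.
    """
    if prescriptions.empty or not len(exclusion_list.codes("analgesia_exclusion")):
        return prescriptions.copy()
    hit = exclusion_list.matches(
        prescriptions["product_code"], "analgesia_exclusion", matching
    )
    removed = int(hit.sum())
    if removed:
        log.info("clean_prescriptions: removed %d analgesia-formulation scripts", removed)
    out = prescriptions.loc[~hit.to_numpy()].reset_index(drop=True)
    if out.empty:
        log.warning("clean_prescriptions: no prescriptions left after exclusions")
    return out


def censor_at_switch(prescriptions: pd.DataFrame):
    """Restrict each patient to their first-observed modality.

    Returns ``(stream, switches, excluded)``:

    * ``stream`` — prescriptions of the first-observed drug strictly before
      the first script of the other drug;
    * ``switches`` — per patient: modality and switch day (NaN if never
      switched), for truncating follow-up;
    * ``excluded`` — patients whose first methadone and first buprenorphine
      scripts share a date (modality unassignable; audit reason ``tie``).

    Expects a numeric ``issue_day`` column.
    """
    if prescriptions.empty:
        empty_sw = pd.DataFrame(columns=["patient_id", "drug", "switch_day"])
        return prescriptions.copy(), empty_sw, pd.DataFrame(columns=["patient_id", "reason"])

    first = (
        prescriptions.groupby(["patient_id", "drug"])["issue_day"]
        .min()
        .unstack("drug")
    )
    for d in ("methadone", "buprenorphine"):
        if d not in first.columns:
            first[d] = np.nan
    tie = first["methadone"] == first["buprenorphine"]
    excluded = pd.DataFrame(
        {"patient_id": first.index[tie.fillna(False)], "reason": "tie"}
    )

    ok = first[~tie.fillna(False)]
    modality = ok.idxmin(axis=1, skipna=True)
    # the other drug's first issue, if any, is the switch date
    other = np.where(modality == "methadone", "buprenorphine", "methadone")
    switch_day = np.array(
        [ok.at[pid, o] for pid, o in zip(ok.index, other)], dtype=float
    )
    switches = pd.DataFrame(
        {"patient_id": ok.index, "drug": modality.to_numpy(), "switch_day": switch_day}
    ).reset_index(drop=True)

    merged = prescriptions.merge(switches, on=["patient_id", "drug"], how="inner")
    keep = merged["switch_day"].isna() | (merged["issue_day"] < merged["switch_day"])
    stream = merged.loc[keep, list(prescriptions.columns)].reset_index(drop=True)
    return stream, switches, excluded


def build_episodes(
    prescriptions: pd.DataFrame,
    supply_days: int = 14,
    max_gap_days: int = 14,
    overlap_mode: str = "extend",
) -> pd.DataFrame:
    """Collapse a single-drug prescription stream into maximal episodes.

    Each script covers ``[issue, issue + supply_days)``.  A script issued
    while the current supply is still running ("overlapping and
    duplicated") extends the expiry: in ``extend`` mode to its own
    ``issue + supply_days``, in ``stack`` mode by a further full supply on
    top of the running expiry (instalment interpretation).  A script
    issued after expiry continues the episode iff the gap is strictly
    below ``max_gap_days``; a gap of ``max_gap_days`` or more closes the
    episode at the running expiry.

    Returns (patient_id, drug, start, end, n_rx); exact duplicate rows are
    collapsed first, unsorted input is sorted with a warning.
    """
    if overlap_mode not in ("extend", "stack"):
        raise ValueError(f"overlap_mode must be 'extend' or 'stack', got {overlap_mode!r}")
    cols = ["patient_id", "drug", "start", "end", "n_rx"]
    if prescriptions.empty:
        return pd.DataFrame(columns=cols)
    rx = prescriptions.drop_duplicates(["patient_id", "drug", "issue_day"])
    if not rx.groupby("patient_id")["issue_day"].is_monotonic_increasing.all():
        log.warning("build_episodes: input not sorted per patient; sorting internally")
    rx = rx.sort_values(["patient_id", "issue_day"], kind="stable")

    rows = []
    for (pid, drug), grp in rx.groupby(["patient_id", "drug"], sort=False):
        issues = grp["issue_day"].to_numpy()
        start = issues[0]
        expiry = issues[0] + supply_days
        n = 1
        for t in issues[1:]:
            if t < expiry:  # overlapping / duplicated script
                if overlap_mode == "extend":
                    expiry = max(expiry, t + supply_days)
                else:
                    expiry = expiry + supply_days
                n += 1
            elif t - expiry < max_gap_days:  # refill delay bridged in-episode
                expiry = t + supply_days
                n += 1
            else:  # supply discontinuation
                rows.append((pid, drug, start, expiry, n))
                start, expiry, n = t, t + supply_days, 1
        rows.append((pid, drug, start, expiry, n))
    return pd.DataFrame(rows, columns=cols)


def build_follow_up(
    patients: pd.DataFrame,
    stream: pd.DataFrame,
    switches: pd.DataFrame,
    study_end_day: int,
    deaths: pd.DataFrame | None = None,
    min_registration_days: int = 30,
    age_range: tuple[int, int] = (18, 64),
):
    """Index date, modality and observation end per eligible patient.

    The index date is the first eligible prescription; observation ends at
    the earliest of registration end, death, the global study end and the
    modality switch.  Patients outside the 18-64 age range at index or
    with under one month of prior registration are excluded with a reason.

    ``patients`` needs numeric ``birth_day``, ``regist_start_day``,
    ``regist_end_day`` columns; ``deaths`` (optional) a ``death_day``.
    Returns ``(follow_up, exclusions)``.
    """
    idx = stream.groupby("patient_id")["issue_day"].min().rename("index_day")
    fu = patients.merge(idx, on="patient_id", how="inner").merge(
        switches[["patient_id", "drug", "switch_day"]], on="patient_id", how="left"
    )
    if deaths is not None and len(deaths):
        death = deaths.groupby("patient_id")["death_day"].min().reset_index()
        fu = fu.merge(death, on="patient_id", how="left")
    else:
        fu["death_day"] = np.nan

    age = (fu["index_day"] - fu["birth_day"]) / 365.25
    lo, hi = age_range
    age_ok = (np.floor(age) >= lo) & (np.floor(age) <= hi)
    reg_ok = fu["index_day"] - fu["regist_start_day"] >= min_registration_days

    ends = np.column_stack(
        [
            fu["regist_end_day"].to_numpy(dtype=float),
            fu["death_day"].fillna(np.inf).to_numpy(dtype=float),
            np.full(len(fu), float(study_end_day)),
            fu["switch_day"].fillna(np.inf).to_numpy(dtype=float),
        ]
    )
    fu["obs_end_day"] = ends.min(axis=1).astype(int)
    has_time = fu["obs_end_day"] > fu["index_day"]

    reasons = np.select(
        [~age_ok, ~reg_ok, ~has_time],
        ["age outside 18-64 at index", "under 1 month registration before index",
         "no follow-up time"],
        default="",
    )
    exclusions = pd.DataFrame(
        {"patient_id": fu.loc[reasons != "", "patient_id"], "reason": reasons[reasons != ""]}
    ).reset_index(drop=True)
    keep = reasons == ""
    fu = fu.loc[keep, ["patient_id", "drug", "index_day", "obs_end_day",
                       "switch_day", "death_day", "birth_day"]].reset_index(drop=True)
    fu["age_at_index"] = np.floor(
        (fu["index_day"] - fu["birth_day"]) / 365.25
    ).astype(int)
    return fu, exclusions


def episode_summaries(episodes: pd.DataFrame, follow_up: pd.DataFrame) -> pd.DataFrame:
    """Per-modality episode summary: counts, median/IQR days in and out of
    treatment, and the distribution of episode durations over bands
    (month = 30.44 days)."""
    if episodes.empty:
        return pd.DataFrame(
            columns=["drug", "n_episodes", "median_days_in", "iqr_days_in",
                     "median_days_out", "iqr_days_out",
                     *[b for b, _, _ in DURATION_BANDS]]
        )
    ep = episodes.merge(
        follow_up[["patient_id", "index_day", "obs_end_day"]], on="patient_id"
    )
    ep["days"] = ep["end"].clip(upper=ep["obs_end_day"]) - ep["start"]
    ep = ep[ep["days"] > 0]
    rows = []
    for drug, grp in ep.groupby("drug", sort=True):
        days = grp["days"]
        in_days = grp.groupby("patient_id")["days"].sum()
        total = grp.groupby("patient_id").apply(
            lambda g: g["obs_end_day"].iloc[0] - g["index_day"].iloc[0],
            include_groups=False,
        )
        out_days = (total - in_days).clip(lower=0)
        months = days / DAYS_PER_MONTH
        band_counts = {
            label: int(((months > lo if lo > 0 else months >= 0) & (months <= hi)).sum())
            if np.isfinite(hi)
            else int((months > lo).sum())
            for label, lo, hi in DURATION_BANDS
        }
        rows.append(
            {
                "drug": drug,
                "n_episodes": len(grp),
                "median_days_in": float(days.median()),
                "iqr_days_in": (float(days.quantile(0.25)), float(days.quantile(0.75))),
                "median_days_out": float(out_days.median()),
                "iqr_days_out": (
                    float(out_days.quantile(0.25)),
                    float(out_days.quantile(0.75)),
                ),
                **band_counts,
            }
        )
    return pd.DataFrame(rows)
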