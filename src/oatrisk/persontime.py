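"""Risk-window person-time: splitting, event attribution, aggregation.

Follow-up is split into four risk windows keyed to treatment transitions:
the first four weeks of each episode (``in_1_4``), the remainder of the
episode (``in_gt4``, the reference stratum), the first four weeks after
each cessation (``out_1_4``) and the remaining out-of-treatment time
(``out_gt4``).  Windows restart at every episode transition.  "Four
weeks" is 28 days with half-open intervals: days 0-27 of a window are
weeks 1-4, day 28 starts the >4-weeks stratum.

All intervals are half-open ``[start, end)`` in days since the index
date; person-years use 365.25 days/year.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25
AGE_BANDS = ((18, 24, "18-24"), (25, 34, "25-34"), (35, 44, "35-44"), (45, 64, "45-64"))

log = logging.getLogger(__name__)


class InvariantError(ValueError):
    """Raised when inputs violate a tiling/ordering invariant."""


def split_follow_up(
    episodes: pd.DataFrame,
    follow_up: pd.DataFrame,
    window_days: int = 28,
    restart_per_episode: bool = True,
) -> pd.DataFrame:
    """Split each patient's follow-up into labelled risk intervals.

    ``episodes`` carries absolute-day ``start``/``end`` columns per
    patient; ``follow_up`` carries ``index_day``, ``obs_end_day`` and the
    modality ``drug``.  Output intervals are relative to the index date
    and tile ``[0, obs_end - index)`` exactly.  With
    ``restart_per_episode=False`` only the first initiation and first
    cessation open 1-4-week windows (later transitions go straight to the
    >4-week strata).
    """
    out_rows = []
    ep_by_pid = dict(tuple(episodes.groupby("patient_id", sort=False)))
    for row in follow_up.itertuples(index=False):
        pid, index, obs_end, drug = (
            row.patient_id,
            row.index_day,
            row.obs_end_day,
            row.drug,
        )
        total = obs_end - index
        grp = ep_by_pid.get(pid)
        if grp is None:
            out_rows.append((pid, drug, 0, total, "out_gt4"))
            continue
        eps = grp.sort_values("start", kind="stable")
        starts = eps["start"].to_numpy() - index
        ends = eps["end"].to_numpy() - index
        if np.any(starts[1:] < ends[:-1]):
            raise InvariantError(f"overlapping episodes for patient {pid}")
        # clip to follow-up
        starts = np.clip(starts, 0, total)
        ends = np.clip(ends, 0, total)
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]

        def emit(s, e, label):
            if e > s:
                out_rows.append((pid, drug, int(s), int(e), label))

        if len(starts) == 0:
            emit(0, total, "out_gt4")
            continue
        if starts[0] > 0:
            emit(0, starts[0], "out_gt4")
        for i, (s, e) in enumerate(zip(starts, ends)):
            nxt = starts[i + 1] if i + 1 < len(starts) else total
            fresh = restart_per_episode or i == 0
            cut = min(s + window_days, e) if fresh else s
            emit(s, cut, "in_1_4")
            emit(cut, e, "in_gt4")
            if nxt > e:
                ocut = min(e + window_days, nxt) if fresh else e
                emit(e, ocut, "out_1_4")
                emit(ocut, nxt, "out_gt4")
    return pd.DataFrame(
        out_rows, columns=["patient_id", "drug", "start", "end", "window"]
    )


def attribute_events(intervals: pd.DataFrame, events: pd.DataFrame):
    """Assign each event to the unique interval containing its day.

    ``events`` needs ``patient_id`` and a relative ``day`` column.  Events
    outside every interval (e.g. after the censor date) are dropped with a
    warning.  Returns ``(intervals_with_counts, attributed_events)`` where
    the second frame carries the window label and interval row index of
    each retained event.
    """
    iv = intervals.reset_index(drop=True).copy()
    iv["interval_id"] = iv.index
    if events.empty:
        iv["events"] = 0
        attributed = pd.DataFrame(columns=[*events.columns, "interval_id", "window"])
        return iv, attributed
    merged = events.merge(
        iv[["patient_id", "start", "end", "window", "interval_id"]],
        on="patient_id",
        how="left",
    )
    inside = (merged["day"] >= merged["start"]) & (merged["day"] < merged["end"])
    attributed = merged.loc[inside].drop(columns=["start", "end"]).reset_index(drop=True)
    n_dropped = len(events) - len(attributed)
    if n_dropped:
        log.warning("attribute_events: dropped %d events outside follow-up", n_dropped)
    counts = attributed.groupby("interval_id").size()
    iv["events"] = iv["interval_id"].map(counts).fillna(0).astype(int)
    return iv, attributed


def first_event_view(intervals: pd.DataFrame, attributed: pd.DataFrame) -> pd.DataFrame:
    """Truncate each patient at their first event for incidence analyses.

    Follow-up ends at the end of the event day (the event day itself
    contributes person-time, avoiding zero-length risk sets); the
    containing interval gets ``event = 1``.  Patients without events keep
    their full follow-up with ``event = 0`` everywhere.
    """
    iv = intervals.copy()
    if "interval_id" not in iv.columns:
        iv["interval_id"] = iv.index
    if attributed.empty:
        iv["event"] = 0
        return iv.assign(events=iv.get("events", 0))
    first = attributed.sort_values("day", kind="stable").groupby("patient_id").first()
    iv = iv.merge(
        first[["day", "interval_id"]].rename(
            columns={"day": "first_day", "interval_id": "first_interval"}
        ),
        on="patient_id",
        how="left",
    )
    cap = (iv["first_day"] + 1).fillna(np.inf)
    iv["end"] = np.minimum(iv["end"], cap).astype(int)
    iv = iv[iv["end"] > iv["start"]].copy()
    iv["event"] = (iv["interval_id"] == iv["first_interval"]).astype(int)
    iv["events"] = iv["event"]
    return iv.drop(columns=["first_day", "first_interval"]).reset_index(drop=True)


def aggregate(intervals: pd.DataFrame, by=("window",)) -> pd.DataFrame:
    """Person-years, event counts and rates per stratum.

    Rates are events per 100 person-years; strata with zero person-time
    are not reported.
    """
    iv = intervals.copy()
    if "events" not in iv.columns:
        iv["events"] = 0
    iv["person_years"] = (iv["end"] - iv["start"]) / DAYS_PER_YEAR
    agg = (
        iv.groupby(list(by), as_index=False)[["person_years", "events"]]
        .sum()
        .query("person_years > 0")
        .reset_index(drop=True)
    )
    agg["rate_per_100py"] = 100.0 * agg["events"] / agg["person_years"]
    return agg


def apply_censor_variant(
    follow_up: pd.DataFrame,
    episodes: pd.DataFrame | None = None,
    variant: str = "none",
    years: float | None = None,
) -> pd.DataFrame:
    """Shorten (never lengthen) observation ends for sensitivity analyses.

    * ``none`` — identity.
    * ``one_year_post_treatment`` — censor 365 days after the end of the
      last treatment episode (needs ``episodes``).
    * ``max_followup_years`` — censor ``years`` after the index date.
    """
    fu = follow_up.copy()
    if variant == "none":
        return fu
    if variant == "one_year_post_treatment":
        if episodes is None:
            raise ValueError("one_year_post_treatment needs the episode table")
        last_end = episodes.groupby("patient_id")["end"].max()
        cap = fu["patient_id"].map(last_end) + 365
        fu["obs_end_day"] = np.minimum(
            fu["obs_end_day"], cap.fillna(fu["obs_end_day"])
        ).astype(int)
    elif variant == "max_followup_years":
        if years is None:
            raise ValueError("max_followup_years needs years=")
        cap = fu["index_day"] + int(round(years * DAYS_PER_YEAR))
        fu["obs_end_day"] = np.minimum(fu["obs_end_day"], cap).astype(int)
    else:
        raise ValueError(f"unknown censor variant: {variant!r}")
    fu["obs_end_day"] = np.maximum(fu["obs_end_day"], fu["index_day"])
    return fu


def _age_band(age: float) -> str:
    for lo, hi, label in AGE_BANDS:
        if lo <= age <= hi:
            return label
    return AGE_BANDS[-1][2] if age > 64 else AGE_BANDS[0][2]


def add_age_bands(intervals: pd.DataFrame, follow_up: pd.DataFrame) -> pd.DataFrame:
    """Split intervals at age-band transitions and label them.

    Age is time-varying: an interval spanning a 25th, 35th or 45th
    birthday is split at that day.  ``follow_up`` must carry ``birth_day``
    and ``index_day`` (absolute days).
    """
    info = follow_up.set_index("patient_id")[["birth_day", "index_day"]]
    rows = []
    for row in intervals.itertuples(index=False):
        birth, index = info.loc[row.patient_id]
        offset = index - birth  # age in days at relative day 0
        cuts = [
            int(np.ceil(lo * DAYS_PER_YEAR)) - offset
            for lo, _, _ in AGE_BANDS[1:]
        ]
        points = sorted({row.start, row.end, *[c for c in cuts if row.start < c < row.end]})
        for s, e in zip(points[:-1], points[1:]):
            age = (s + offset) / DAYS_PER_YEAR
            d = row._asdict()
            d.update(start=s, end=e, age_band=_age_band(age))
            rows.append(d)
    return pd.DataFrame(rows)
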