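"""Code-list-based ascertainment of overdose outcomes and history.

Hospital admissions, death registrations and primary-care history records
are classified against configurable code lists (ICD-10 for secondary-care
and mortality coding, Read/SNOMED for primary care, product codes for
formulation exclusions).  ICD-10 matching is prefix-based by default, so a
list entry ``T40`` captures ``T40.1``; codes are normalised by upper-casing
and stripping the dot before comparison.

The toy lists shipped with the package are synthetic stand-ins with the
same shape as real ascertainment lists; any production run supplies its
own CSV (columns code, system, category).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

VALID_SYSTEMS = {"ICD10", "READ", "SNOMED", "PRODUCT"}


class InputError(ValueError):
    """Raised for malformed ascertainment inputs (e.g. unknown coding system)."""


def _normalise(code) -> str:
    return str(code).strip().upper().replace(".", "")


@dataclass(frozen=True)
class CodeList:
    """A set of (code, system, category) entries.

    Codes are stored normalised; entries must be unique within
    (system, category).
    """

    entries: pd.DataFrame  # columns: code, system, category

    def __post_init__(self):
        df = self.entries.copy()
        missing = {"code", "system", "category"} - set(df.columns)
        if missing:
            raise InputError(f"code list missing columns: {sorted(missing)}")
        bad = set(df["system"]) - VALID_SYSTEMS
        if bad:
            raise InputError(f"unknown coding system(s): {sorted(bad)}")
        df["code"] = df["code"].map(_normalise)
        if df.duplicated(["system", "category", "code"]).any():
            raise InputError("duplicate codes within (system, category)")
        object.__setattr__(self, "entries", df.reset_index(drop=True))

    @classmethod
    def from_csv(cls, path) -> "CodeList":
        return cls(pd.read_csv(path, dtype=str))

    def codes(self, category: str, system: str | None = None) -> tuple[str, ...]:
        df = self.entries
        sel = df["category"] == category
        if system is not None:
            sel &= df["system"] == system
        return tuple(df.loc[sel, "code"])

    def matches(self, codes, category: str, matching: str = "prefix") -> pd.Series:
        """Boolean mask: does each code match any list entry of ``category``?"""
        targets = self.codes(category)
        normalised = pd.Series(codes, dtype=object).map(_normalise)
        if matching == "exact":
            return normalised.isin(set(targets))
        if matching == "prefix":
            if not targets:
                return pd.Series(False, index=normalised.index)
            return normalised.str.startswith(tuple(targets))
        raise InputError(f"unknown matching mode: {matching!r}")


def default_code_list() -> CodeList:
    """The synthetic toy code list shipped with the package."""
    with resources.files("oatrisk.data").joinpath("default_codes.csv").open() as fh:
        return CodeList(pd.read_csv(fh, dtype=str))


def classify_admissions(
    admissions: pd.DataFrame,
    code_list: CodeList,
    matching: str = "prefix",
    any_position: bool = True,
) -> pd.DataFrame:
    """Non-fatal overdose events from coded hospital admissions.

    One event per admission record that carries at least one matching
    diagnosis code (in any position by default, primary position only if
    ``any_position`` is False); multiple matching codes on one admission
    still yield a single event, dated at the admission date.

    Returns a DataFrame (patient_id, date, kind='nonfatal', source_id).
    """
    if admissions.empty:
        return pd.DataFrame(columns=["patient_id", "date", "kind", "source_id"])
    adm = admissions if any_position else admissions[admissions["position"] == 1]
    hit = code_list.matches(adm["diag_code"], "nonfatal_overdose", matching)
    matched = adm.loc[hit.to_numpy(), ["admission_id", "patient_id", "admission_date"]]
    events = matched.drop_duplicates("admission_id")
    return (
        events.rename(columns={"admission_date": "date", "admission_id": "source_id"})
        .assign(kind="nonfatal")[["patient_id", "date", "kind", "source_id"]]
        .sort_values(["patient_id", "date"], kind="stable")
        .reset_index(drop=True)
    )


def classify_deaths(
    deaths: pd.DataFrame, code_list: CodeList, matching: str = "prefix"
) -> pd.DataFrame:
    """Fatal drug-poisoning events from death registrations.

    A death whose cause code matches the fatal-overdose list yields one
    event dated at the death date.  Deaths after any downstream mortality
    censor date are still classified here; censoring is a person-time
    concern.
    """
    if deaths.empty:
        return pd.DataFrame(columns=["patient_id", "date", "kind", "source_id"])
    hit = code_list.matches(deaths["cause_code"], "fatal_overdose", matching)
    matched = deaths.loc[hit.to_numpy()].drop_duplicates("patient_id")
    out = matched.rename(columns={"death_date": "date"}).assign(kind="fatal")
    out["source_id"] = out["patient_id"]
    return (
        out[["patient_id", "date", "kind", "source_id"]]
        .sort_values("patient_id", kind="stable")
        .reset_index(drop=True)
    )


def flag_history(
    events: pd.DataFrame,
    index_date,
    lookback_years: float | None = None,
) -> bool:
    """True iff at least one event falls strictly before the index date,
    within the lookback window (``None`` = all time).

    ``events`` needs a ``date`` column; an event on the index date itself
    does not count (strictly-before rule).
    """
    if events.empty:
        return False
    dates = pd.to_datetime(events["date"])
    index_date = pd.Timestamp(index_date)
    before = dates < index_date
    if lookback_years is not None:
        horizon = index_date - pd.Timedelta(days=lookback_years * 365.25)
        before &= dates >= horizon
    return bool(before.any())
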