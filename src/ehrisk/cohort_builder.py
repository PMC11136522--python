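"""Case definition, inclusion criteria and pre-index censoring.

Labels each patient in a flat extract as a case (carries at least one
suicide-attempt ICD-9 code from the wildcard families E95*, 965*, 967*,
969*, 881*) or a noncase, applies the inclusion rules (>= 3 visits,
>= 30 days between first and last visit, records after age 10 and before
age 90), and censors each case's record strictly before its index date
(the date of the first case-defining code).  Cases left with no events
before the index date are excluded and tallied in the exclusion ledger.

A "visit" is proxied by a distinct calendar date carrying at least one
event: the flat extract has no encounter table, so date-level grouping is
the only visit notion available.  Inclusion is evaluated on the full,
uncensored record; censoring and the no-pre-index-data exclusion happen
afterwards as a separate step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

DEFAULT_CASE_PATTERNS: tuple[str, ...] = ("E95*", "965*", "967*", "969*", "881*")

#: Machine-readable exclusion reasons, in evaluation order.
REASON_MIN_VISITS = "min_visits"
REASON_MIN_SPAN = "min_span"
REASON_AGE_WINDOW = "age_window"
REASON_NO_PRE_INDEX = "no_pre_index_data"


@dataclass(frozen=True)
class CaseDefinition:
    """Wildcard ICD-9 patterns defining the outcome, restricted to DX events."""

    code_patterns: tuple[str, ...] = DEFAULT_CASE_PATTERNS

    def __post_init__(self) -> None:
        if not self.code_patterns:
            raise ValueError("case definition needs at least one code pattern")
        for pat in self.code_patterns:
            stem = pat[:-1] if pat.endswith("*") else pat
            if not stem:
                raise ValueError(f"invalid case-code pattern: {pat!r}")


@dataclass(frozen=True)
class InclusionRules:
    min_visits: int = 3
    min_span_days: int = 30
    min_age_years: float = 10.0
    max_age_years: float = 90.0

    def __post_init__(self) -> None:
        if self.min_visits < 1:
            raise ValueError("min_visits must be >= 1")
        if self.min_span_days < 0:
            raise ValueError("min_span_days must be >= 0")
        if not self.min_age_years < self.max_age_years:
            raise ValueError("min_age_years must be below max_age_years")


@dataclass
class CohortPatient:
    """One labeled patient with a chronologically ordered, censored record."""

    patient_id: str
    label: str  # "case" | "noncase"
    index_date: pd.Timestamp | None
    birth_date: pd.Timestamp
    sex: str
    race_ethnicity: str
    events: pd.DataFrame  # columns: patient_id, date, domain, code, value_flag


def match_case_code(code: str, definition: CaseDefinition | None = None) -> bool:
    """True iff ``code`` matches the case definition.

    A pattern ending in ``*`` matches any code starting with its stem
    (the bare stem itself included); other patterns match exactly.
    """
    if definition is None:
        definition = CaseDefinition()
    if not code:
        raise ValueError("code must be non-empty")
    for pat in definition.code_patterns:
        if pat.endswith("*"):
            if code.startswith(pat[:-1]):
                return True
        elif code == pat:
            return True
    return False


def _match_series(codes: pd.Series, definition: CaseDefinition) -> np.ndarray:
    mask = np.zeros(len(codes), dtype=bool)
    s = codes.astype(str)
    for pat in definition.code_patterns:
        if pat.endswith("*"):
            mask |= s.str.startswith(pat[:-1]).to_numpy()
        else:
            mask |= (s == pat).to_numpy()
    return mask


def find_index_date(events: pd.DataFrame,
                    definition: CaseDefinition | None = None) -> pd.Timestamp | None:
    """Earliest date of any case-defining DX event, or None."""
    if definition is None:
        definition = CaseDefinition()
    dx = events[events["domain"] == "DX"]
    if dx.empty:
        return None
    hits = dx[_match_series(dx["code"], definition)]
    if hits.empty:
        return None
    return hits["date"].min()


@dataclass(frozen=True)
class InclusionDecision:
    keep: bool
    reason: str | None = None


def apply_inclusion(events: pd.DataFrame, birth_date: pd.Timestamp,
                    rules: InclusionRules | None = None) -> InclusionDecision:
    """Keep/drop decision for one patient's full (uncensored) record.

    Visits are distinct event dates.  The age rule requires at least one
    event after ``min_age_years`` and at least one before ``max_age_years``.
    """
    if rules is None:
        rules = InclusionRules()
    if birth_date is None or pd.isna(birth_date):
        raise ValueError("birth_date is required for inclusion rules")
    dates = pd.to_datetime(events["date"]).drop_duplicates().sort_values()
    if len(dates) < rules.min_visits:
        return InclusionDecision(False, REASON_MIN_VISITS)
    if (dates.iloc[-1] - dates.iloc[0]).days < rules.min_span_days:
        return InclusionDecision(False, REASON_MIN_SPAN)
    age_last = (dates.iloc[-1] - birth_date).days / DAYS_PER_YEAR
    age_first = (dates.iloc[0] - birth_date).days / DAYS_PER_YEAR
    if not (age_last > rules.min_age_years and age_first < rules.max_age_years):
        return InclusionDecision(False, REASON_AGE_WINDOW)
    return InclusionDecision(True, None)


class Cohort:
    """A labeled, censored cohort backed by two tables.

    ``members`` holds one row per patient (patient_id, label, index_date,
    demographics); ``events`` holds the censored event stream, sorted by
    (patient_id, date) with stable within-date order.  Iterating yields
    :class:`CohortPatient` objects.
    """

    def __init__(self, members: pd.DataFrame, events: pd.DataFrame):
        self.members = members.reset_index(drop=True)
        self.events = events.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_cases(self) -> int:
        return int((self.members["label"] == "case").sum())

    @property
    def n_noncases(self) -> int:
        return int((self.members["label"] == "noncase").sum())

    def __iter__(self) -> Iterator[CohortPatient]:
        groups = dict(tuple(self.events.groupby("patient_id", sort=False)))
        empty = self.events.iloc[0:0]
        for row in self.members.itertuples(index=False):
            ev = groups.get(row.patient_id, empty)
            yield CohortPatient(
                patient_id=row.patient_id,
                label=row.label,
                index_date=None if pd.isna(row.index_date) else row.index_date,
                birth_date=row.birth_date,
                sex=row.sex,
                race_ethnicity=row.race_ethnicity,
                events=ev.reset_index(drop=True),
            )

    def subset(self, patient_ids: Sequence[str]) -> "Cohort":
        wanted = set(patient_ids)
        m = self.members[self.members["patient_id"].isin(wanted)]
        e = self.events[self.events["patient_id"].isin(wanted)]
        return Cohort(m, e)


def build_cohort(patients: pd.DataFrame, events: pd.DataFrame,
                 definition: CaseDefinition | None = None,
                 rules: InclusionRules | None = None) -> tuple[Cohort, dict]:
    """Apply case labeling, inclusion rules and pre-index censoring.

    Returns the cohort plus an exclusion ledger whose counts conserve the
    input: every patient is either a cohort member or tallied under
    exactly one exclusion reason.
    """
    definition = definition or CaseDefinition()
    rules = rules or InclusionRules()

    patients = patients.copy()
    patients["birth_date"] = pd.to_datetime(patients["birth_date"])
    events = events.copy()
    events["date"] = pd.to_datetime(events["date"])
    if "value_flag" in events:
        events["value_flag"] = events["value_flag"].fillna("")

    known = set(patients["patient_id"])
    unknown = sorted(set(events["patient_id"]) - known)
    if unknown:
        shown = ", ".join(map(str, unknown[:20]))
        raise ValueError(
            f"{len(unknown)} event patient id(s) missing from patient table: {shown}"
        )

    # Index dates from case-defining DX events.
    dx = events[events["domain"] == "DX"]
    hits = dx[_match_series(dx["code"], definition)]
    index_dates = hits.groupby("patient_id")["date"].min()

    # Per-patient record stats on the full record.
    stats = events.groupby("patient_id").agg(
        n_dates=("date", "nunique"), dmin=("date", "min"), dmax=("date", "max"))
    info = patients.set_index("patient_id").join(stats, how="left")
    info["n_dates"] = info["n_dates"].fillna(0).astype(int)
    span_days = (info["dmax"] - info["dmin"]).dt.days
    age_last = (info["dmax"] - info["birth_date"]).dt.days / DAYS_PER_YEAR
    age_first = (info["dmin"] - info["birth_date"]).dt.days / DAYS_PER_YEAR

    fail_visits = info["n_dates"] < rules.min_visits
    fail_span = ~fail_visits & (span_days < rules.min_span_days)
    fail_age = ~fail_visits & ~fail_span & ~(
        (age_last > rules.min_age_years) & (age_first < rules.max_age_years))
    included = ~(fail_visits | fail_span | fail_age)

    info["index_date"] = index_dates.reindex(info.index)
    info["label"] = np.where(info["index_date"].notna(), "case", "noncase")

    inc = info[included]
    # Censor case events strictly before the index date.
    ev = events[events["patient_id"].isin(inc.index)]
    ev_index = inc["index_date"].reindex(ev["patient_id"]).to_numpy()
    keep_ev = pd.isna(ev_index) | (ev["date"].to_numpy() < ev_index)
    ev = ev[keep_ev]

    # Cases whose censored record is empty lack pre-index data.
    case_ids = inc.index[inc["label"] == "case"]
    with_pre = set(ev["patient_id"].unique())
    no_pre = [pid for pid in case_ids if pid not in with_pre]

    members = inc.drop(index=no_pre).reset_index()
    members = members[["patient_id", "label", "index_date",
                       "birth_date", "sex", "race_ethnicity"]]
    ev = ev[~ev["patient_id"].isin(set(no_pre))]
    ev = ev.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)

    ledger = {
        "n_patients": int(len(patients)),
        "n_passing_inclusion": int(included.sum()),
        "excluded": {
            REASON_MIN_VISITS: int(fail_visits.sum()),
            REASON_MIN_SPAN: int(fail_span.sum()),
            REASON_AGE_WINDOW: int(fail_age.sum()),
            REASON_NO_PRE_INDEX: int(len(no_pre)),
        },
        "n_cases": int((members["label"] == "case").sum()),
        "n_noncases": int((members["label"] == "noncase").sum()),
    }
    return Cohort(members, ev), ledger


def read_extracts(patients_path: str | Path,
                  events_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a flat extract pair, parsing dates and normalizing flags."""
    patients = pd.read_csv(patients_path, dtype={"patient_id": str},
                           parse_dates=["birth_date"])
    events = pd.read_csv(events_path, dtype={"patient_id": str, "code": str},
                         parse_dates=["date"], keep_default_na=False,
                         na_values=[])
    events["value_flag"] = events.get("value_flag", "").astype(str)
    return patients, events


def write_cohort(cohort: Cohort, ledger: dict, members_path: str | Path,
                 events_path: str | Path, ledger_path: str | Path) -> None:
    m = cohort.members.copy()
    for col in ("index_date", "birth_date"):
        m[col] = pd.to_datetime(m[col]).dt.strftime("%Y-%m-%d")
    m.to_csv(members_path, index=False)
    e = cohort.events.copy()
    e["date"] = pd.to_datetime(e["date"]).dt.strftime("%Y-%m-%d")
    e.to_csv(events_path, index=False)
    with open(ledger_path, "w") as fh:
        json.dump(ledger, fh, indent=2, sort_keys=True)


def read_cohort(members_path: str | Path, events_path: str | Path) -> Cohort:
    members = pd.read_csv(members_path, dtype={"patient_id": str},
                          parse_dates=["index_date", "birth_date"])
    events = pd.read_csv(events_path, dtype={"patient_id": str, "code": str},
                         parse_dates=["date"], keep_default_na=False, na_values=[])
    events["value_flag"] = events.get("value_flag", "").astype(str)
    return Cohort(members, events)
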