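"""First-occurrence binary concept features on a censored timeline.

Every predictor enters the model once, at its first occurrence, as a
binary variable.  A concept is identified by (domain, code, lab flag):
a laboratory test with a High flag is a different predictor state from
the same test with a Normal flag.  Demographic attributes (sex,
race/ethnicity, age decade at first visit) become DEM concepts dated at
the patient's first event, so they occupy a defined place at the start of
the chronological cumulative sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .cohort_builder import Cohort, CohortPatient

DAYS_PER_YEAR = 365.25

_TIMELINE_COLUMNS = ["patient_id", "label", "date", "domain", "code", "lab_flag", "concept"]


class Concept(NamedTuple):
    """Feature identity: (domain, code, lab_flag); lab_flag only for LAB."""

    domain: str
    code: str
    lab_flag: str | None = None

    @property
    def key(self) -> str:
        if self.domain == "LAB":
            return f"LAB:{self.code}:{self.lab_flag}"
        return f"{self.domain}:{self.code}"


def parse_concept(key: str) -> Concept:
    parts = key.split(":")
    if parts[0] == "LAB":
        domain, flag = parts[0], parts[-1]
        code = ":".join(parts[1:-1])
        return Concept(domain, code, flag)
    return Concept(parts[0], ":".join(parts[1:]))


@dataclass
class FeatureTimeline:
    """Ordered unique-concept first occurrences for one patient."""

    patient_id: str
    label: str
    entries: list[tuple[pd.Timestamp, Concept]]

    def __post_init__(self) -> None:
        dates = [d for d, _ in self.entries]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError("timeline dates must be ascending")
        concepts = [c for _, c in self.entries]
        if len(set(concepts)) != len(concepts):
            raise ValueError("timeline concepts must be unique")

    def __len__(self) -> int:
        return len(self.entries)


def _age_decade_code(age_years: float) -> str:
    if not np.isfinite(age_years) or age_years < 0:
        return "AGE_UNKNOWN"
    lo = min(int(age_years // 10) * 10, 90)
    return "AGE_90_UP" if lo >= 90 else f"AGE_{lo:02d}_{lo + 9:02d}"


def _dem_code(kind: str, value: str) -> str:
    slug = "".join(ch if ch.isalnum() else "_" for ch in str(value).upper())
    return f"{kind}_{slug}"


def extract_timelines(cohort: Cohort) -> pd.DataFrame:
    """Vectorized timeline table for a whole cohort.

    Returns one row per (patient, concept) first occurrence, sorted per
    patient by date (stable, with demographic concepts after same-date
    events), with columns patient_id, label, date, domain, code,
    lab_flag, concept.
    """
    ev = cohort.events
    members = cohort.members

    # Contract: events ascending within each patient.
    if len(ev):
        same = ev["patient_id"].to_numpy()[1:] == ev["patient_id"].to_numpy()[:-1]
        if np.any(same & (np.diff(ev["date"].to_numpy()) < np.timedelta64(0, "ns"))):
            raise ValueError("cohort events must be sorted ascending by date per patient")

    ev = ev.copy()
    is_lab = ev["domain"] == "LAB"
    flag = ev["value_flag"].astype(str).where(is_lab, other=pd.NA)
    ev["lab_flag"] = flag.replace({"": "N", "nan": "N"})
    first = ev[~ev.duplicated(["patient_id", "domain", "code", "lab_flag"])].copy()
    first["seq"] = np.arange(len(first))

    # Demographic concepts at the first event date (index date fallback
    # for externally built cohorts whose patients carry no events).
    first_date = ev.groupby("patient_id")["date"].min()
    dem_date = first_date.reindex(members["patient_id"])
    fallback = pd.to_datetime(members["index_date"]).to_numpy()
    dem_date = pd.Series(np.where(pd.isna(dem_date.to_numpy()), fallback,
                                  dem_date.to_numpy()),
                         index=members.index)
    age = (pd.to_datetime(dem_date.to_numpy()) - pd.to_datetime(
        members["birth_date"]).to_numpy()).days / DAYS_PER_YEAR
    dem_frames = []
    for kind, values in (
        ("SEX", members["sex"].map(lambda v: _dem_code("SEX", v))),
        ("RACE", members["race_ethnicity"].map(lambda v: _dem_code("RACE", v))),
        ("AGE", pd.Series([_age_decade_code(a) for a in age], index=members.index)),
    ):
        dem_frames.append(pd.DataFrame({
            "patient_id": members["patient_id"],
            "date": dem_date.to_numpy(),
            "domain": "DEM",
            "code": values.to_numpy(),
            "lab_flag": pd.NA,
        }))
    dem = pd.concat(dem_frames, ignore_index=True)
    dem = dem[pd.notna(dem["date"])]
    dem["seq"] = len(first) + np.arange(len(dem))

    cols = ["patient_id", "date", "domain", "code", "lab_flag", "seq"]
    tl = pd.concat([first[cols], dem[cols]], ignore_index=True)
    tl = tl.sort_values(["patient_id", "date", "seq"], kind="mergesort")
    tl = tl.drop(columns="seq").reset_index(drop=True)

    labels = members.set_index("patient_id")["label"]
    tl.insert(1, "label", labels.reindex(tl["patient_id"]).to_numpy())
    lab = tl["domain"] == "LAB"
    tl["concept"] = tl["domain"] + ":" + tl["code"]
    tl.loc[lab, "concept"] = ("LAB:" + tl.loc[lab, "code"] + ":"
                              + tl.loc[lab, "lab_flag"].astype(str))
    return tl[_TIMELINE_COLUMNS]


def extract_timeline(patient: CohortPatient) -> FeatureTimeline:
    """Timeline for a single patient (first occurrence per concept).

    Raises if the patient's events are not sorted ascending by date.
    """
    ev = patient.events
    if len(ev) and np.any(np.diff(ev["date"].to_numpy()) < np.timedelta64(0, "ns")):
        raise ValueError("patient events must be sorted ascending by date")
    members = pd.DataFrame({
        "patient_id": [patient.patient_id], "label": [patient.label],
        "index_date": [patient.index_date], "birth_date": [patient.birth_date],
        "sex": [patient.sex], "race_ethnicity": [patient.race_ethnicity],
    })
    table = extract_timelines(Cohort(members, ev))
    entries = [
        (row.date, Concept(row.domain, row.code,
                           None if pd.isna(row.lab_flag) else row.lab_flag))
        for row in table.itertuples(index=False)
    ]
    return FeatureTimeline(patient.patient_id, patient.label, entries)


def timelines_to_table(timelines: Iterable[FeatureTimeline]) -> pd.DataFrame:
    """Convert per-patient FeatureTimeline objects to the table form."""
    rows = []
    for tl in timelines:
        for date, c in tl.entries:
            rows.append((tl.patient_id, tl.label, date, c.domain, c.code,
                         c.lab_flag, c.key))
    return pd.DataFrame(rows, columns=_TIMELINE_COLUMNS)


def concept_universe(timelines: pd.DataFrame | Iterable[FeatureTimeline]) -> pd.DataFrame:
    """Every observed concept with case/noncase patient counts.

    Accepts the timeline table or an iterable of FeatureTimeline.  All
    concepts are retained regardless of how few patients carry them.
    """
    if not isinstance(timelines, pd.DataFrame):
        timelines = timelines_to_table(timelines)
    if timelines.empty:
        return pd.DataFrame(columns=["concept", "domain", "code", "lab_flag",
                                     "case_count", "noncase_count"])
    counts = (
        timelines.groupby(["concept", "domain", "code", "lab_flag", "label"],
                          dropna=False)
        .size().unstack("label", fill_value=0)
    )
    out = counts.reset_index()
    out["case_count"] = out.get("case", 0)
    out["noncase_count"] = out.get("noncase", 0)
    return out[["concept", "domain", "code", "lab_flag", "case_count",
                "noncase_count"]].sort_values("concept").reset_index(drop=True)
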