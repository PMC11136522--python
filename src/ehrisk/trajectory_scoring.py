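"""Cumulative risk trajectories, maximal scores and threshold crossings.

A patient's cumulative risk score is the running sum of the partial
scores of their first-occurrence features, in chronological order.  The
patient-level summary used for evaluation is the maximal value of the
trajectory.  For alerting, the first date on which the cumulative score
strictly exceeds a threshold is the first crossing; for cases, the lead
time is the interval from that date to the index date.

Conventions
-----------
* Features unknown to the model contribute 0 but still produce a step.
* Same-date features are summed in stable input order; only the
  cumulative value at the end of each date is treated as meaningful, so
  the maximum and crossings are evaluated on date-level totals.
* "Surpassed" is a strict ``>``: a score exactly at the threshold does
  not alert (the same convention the specificity quantile uses).
* A patient with no scored features has max_score 0.
* One year = 365.25 days for lead-time conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_extraction import FeatureTimeline
from .nbc_trainer import SiteModel

DAYS_PER_YEAR = 365.25


@dataclass
class RiskTrajectory:
    """Per-feature cumulative steps plus date-level totals for one patient."""

    patient_id: str
    label: str
    steps: list[tuple[pd.Timestamp, float]]        # one per feature
    date_totals: list[tuple[pd.Timestamp, float]]  # cumulative at end of date
    max_score: float
    index_date: pd.Timestamp | None = None


@dataclass
class Crossing:
    threshold: float
    first_crossing_date: pd.Timestamp | None
    lead_time_years: float | None


def score_trajectory(timeline: FeatureTimeline, model: SiteModel,
                     index_date: pd.Timestamp | None = None) -> RiskTrajectory:
    """Cumulative trajectory for one patient's timeline."""
    cum = 0.0
    steps: list[tuple[pd.Timestamp, float]] = []
    for date, concept in timeline.entries:
        cum += model.score(concept)
        steps.append((date, cum))
    date_totals = [
        (date, total) for (date, total), nxt in zip(
            steps, [d for d, _ in steps[1:]] + [None])
        if nxt is None or nxt != date
    ]
    max_score = max((t for _, t in date_totals), default=0.0)
    return RiskTrajectory(timeline.patient_id, timeline.label, steps,
                          date_totals, float(max_score), index_date)


def first_crossing(trajectory: RiskTrajectory, threshold: float) -> Crossing:
    """Earliest date whose date-level cumulative score strictly exceeds
    ``threshold``; lead time (years) for cases with an index date."""
    date = next((d for d, t in trajectory.date_totals if t > threshold), None)
    lead = None
    if date is not None and trajectory.index_date is not None:
        lead = (trajectory.index_date - date).days / DAYS_PER_YEAR
    return Crossing(threshold, date, lead)


# ---------------------------------------------------------------------------
# Vectorized cohort-level equivalents used by the harness.

def score_timeline_table(timelines: pd.DataFrame, model: SiteModel) -> pd.DataFrame:
    """Date-level cumulative scores for a whole timeline table.

    Returns one row per (patient, date) with the cumulative score at the
    end of that date, plus the patient's label.
    """
    tl = timelines.copy()
    tl["score"] = tl["concept"].map(model.scores).fillna(0.0)
    by_date = (
        tl.groupby(["patient_id", "label", "date"], sort=False, observed=True)
        ["score"].sum().reset_index()
    )
    by_date["cumulative"] = by_date.groupby("patient_id", sort=False)["score"].cumsum()
    return by_date[["patient_id", "label", "date", "cumulative"]]


def max_scores(timelines: pd.DataFrame, model: SiteModel,
               members: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-patient maximal cumulative score (0 for members with no features).

    ``members`` (patient_id, label) adds patients absent from the
    timeline table with max_score 0.
    """
    cum = score_timeline_table(timelines, model)
    mx = (cum.groupby(["patient_id", "label"], sort=False, observed=True)
          ["cumulative"].max().reset_index().rename(columns={"cumulative": "max_score"}))
    if members is not None:
        missing = members[~members["patient_id"].isin(set(mx["patient_id"]))]
        if len(missing):
            mx = pd.concat([mx, pd.DataFrame({
                "patient_id": missing["patient_id"],
                "label": missing["label"],
                "max_score": 0.0,
            })], ignore_index=True)
    return mx.sort_values("patient_id").reset_index(drop=True)


def first_crossing_dates(cumulative: pd.DataFrame, threshold: float) -> pd.Series:
    """First date per patient whose cumulative score exceeds ``threshold``.

    ``cumulative`` is the output of :func:`score_timeline_table`; patients
    that never cross are absent from the result.
    """
    above = cumulative[cumulative["cumulative"] > threshold]
    return above.groupby("patient_id")["date"].min()


def lead_times_years(cumulative: pd.DataFrame, threshold: float,
                     index_dates: pd.Series) -> pd.Series:
    """Lead time (years) from first crossing to index date, per crossing case.

    ``index_dates`` maps case patient_id -> index date; only patients
    present there are considered.
    """
    crossings = first_crossing_dates(cumulative, threshold)
    crossings = crossings[crossings.index.isin(index_dates.index)]
    if crossings.empty:
        return pd.Series(dtype=float)
    idx = index_dates.reindex(crossings.index)
    days = (pd.to_datetime(idx).to_numpy() - pd.to_datetime(crossings).to_numpy())
    return pd.Series(days / np.timedelta64(1, "D") / DAYS_PER_YEAR,
                     index=crossings.index)
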