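"""Cumulative trajectories, prefix maxima and first crossings."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ehrisk import Concept, FeatureTimeline, first_crossing, score_trajectory
from ehrisk.nbc_trainer import SiteModel
from ehrisk.trajectory_scoring import (first_crossing_dates, lead_times_years,
                                       max_scores, score_timeline_table)


def _model(scores: dict[str, float]) -> SiteModel:
    return SiteModel("m", scores, n_cases=1, n_noncases=1)


def _timeline(entries, label="case"):
    return FeatureTimeline("p", label, entries)


D = pd.Timestamp  # shorthand


def test_running_sum_and_max():
    model = _model({"DX:a": 1.0, "DX:b": -0.5, "DX:c": 2.0})
    tl = _timeline([(D("2010-01-10"), Concept("DX", "a")),
                    (D("2010-01-20"), Concept("DX", "b")),
                    (D("2010-01-30"), Concept("DX", "c"))])
    traj = score_trajectory(tl, model)
    assert [s for _, s in traj.steps] == pytest.approx([1.0, 0.5, 2.5])
    assert traj.max_score == pytest.approx(2.5)


def test_unknown_concepts_contribute_zero_steps():
    model = _model({})
    tl = _timeline([(D("2010-01-10"), Concept("DX", "mystery")),
                    (D("2010-02-10"), Concept("RX", "another"))])
    traj = score_trajectory(tl, model)
    assert [s for _, s in traj.steps] == [0.0, 0.0]
    assert traj.max_score == 0.0
    assert first_crossing(traj, 0.0).first_crossing_date is None


def test_empty_timeline_max_is_zero():
    traj = score_trajectory(_timeline([]), _model({"DX:a": 3.0}))
    assert traj.max_score == 0.0
    assert traj.steps == []


def test_same_date_features_collapse_to_date_level_total():
    model = _model({"DX:a": 5.0, "DX:b": -5.0, "DX:c": 1.0})
    tl = _timeline([(D("2010-01-10"), Concept("DX", "a")),
                    (D("2010-01-10"), Concept("DX", "b")),
                    (D("2010-02-10"), Concept("DX", "c"))])
    traj = score_trajectory(tl, model)
    # the transient +5 inside 2010-01-10 is not a date-level value
    assert traj.date_totals == [(D("2010-01-10"), 0.0), (D("2010-02-10"), 1.0)]
    assert traj.max_score == pytest.approx(1.0)
    assert first_crossing(traj, 2.0).first_crossing_date is None


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(-3, 3), min_size=1, max_size=200))
def test_max_equals_bruteforce_prefix_max_on_distinct_dates(scores):
    model = _model({f"DX:c{i}": s for i, s in enumerate(scores)})
    entries = [(D("2010-01-01") + pd.Timedelta(days=i), Concept("DX", f"c{i}"))
               for i in range(len(scores))]
    traj = score_trajectory(_timeline(entries), model)
    prefix = np.cumsum(scores)
    assert traj.max_score == pytest.approx(prefix.max())


def test_first_crossing_lead_time_and_year_convention():
    model = _model({"DX:a": 1.0, "DX:b": -0.5, "DX:c": 2.0})
    tl = _timeline([(D("2010-01-10"), Concept("DX", "a")),
                    (D("2010-01-20"), Concept("DX", "b")),
                    (D("2010-01-30"), Concept("DX", "c"))])
    traj = score_trajectory(tl, model, index_date=D("2011-01-30"))
    cr = first_crossing(traj, 2.0)
    assert cr.first_crossing_date == D("2010-01-30")
    assert cr.lead_time_years == pytest.approx(365 / 365.25)


def test_threshold_above_max_never_crosses():
    model = _model({"DX:a": 1.0})
    traj = score_trajectory(
        _timeline([(D("2010-01-10"), Concept("DX", "a"))]), model)
    cr = first_crossing(traj, 1.0)  # strict: equality does not alert
    assert cr.first_crossing_date is None and cr.lead_time_years is None


def test_dip_below_threshold_keeps_first_crossing():
    model = _model({"DX:a": 3.0, "DX:b": -2.0, "DX:c": 0.5})
    tl = _timeline([(D("2010-01-10"), Concept("DX", "a")),
                    (D("2010-06-10"), Concept("DX", "b")),
                    (D("2010-12-10"), Concept("DX", "c"))])
    traj = score_trajectory(tl, model, index_date=D("2011-01-01"))
    cr = first_crossing(traj, 2.0)
    assert cr.first_crossing_date == D("2010-01-10")


def test_noncase_crossing_has_no_lead_time():
    model = _model({"DX:a": 1.0})
    traj = score_trajectory(
        _timeline([(D("2010-01-10"), Concept("DX", "a"))], label="noncase"),
        model)
    cr = first_crossing(traj, 0.5)
    assert cr.first_crossing_date == D("2010-01-10")
    assert cr.lead_time_years is None


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.floats(-2, 4), min_size=1, max_size=50),
       st.lists(st.floats(-1, 6), min_size=1, max_size=5))
def test_lead_time_nonincreasing_in_threshold(scores, thresholds):
    model = _model({f"DX:c{i}": s for i, s in enumerate(scores)})
    entries = [(D("2010-01-01") + pd.Timedelta(days=i), Concept("DX", f"c{i}"))
               for i in range(len(scores))]
    traj = score_trajectory(_timeline(entries), model,
                            index_date=D("2012-01-01"))
    crossings = [first_crossing(traj, t) for t in sorted(thresholds)]
    leads = [c.lead_time_years for c in crossings]
    present = [l for l in leads if l is not None]
    assert all(b <= a + 1e-12 for a, b in zip(present, present[1:]))
    # once absent at a threshold, absent at every higher threshold
    seen_none = False
    for l in leads:
        if l is None:
            seen_none = True
        else:
            assert not seen_none


def test_vectorized_table_agrees_with_per_patient_objects(small_cohort):
    from ehrisk import extract_timeline, extract_timelines, train_site_model
    cohort, _ = small_cohort
    tl = extract_timelines(cohort)
    model, _ = train_site_model(tl)
    mx = max_scores(tl, model, members=cohort.members).set_index("patient_id")
    # spot-check 25 patients through the object API
    for patient in list(cohort)[:25]:
        traj = score_trajectory(extract_timeline(patient), model)
        assert mx.loc[patient.patient_id, "max_score"] == \
            pytest.approx(traj.max_score)


def test_vectorized_crossings_agree_with_object_api(small_cohort):
    from ehrisk import extract_timeline, extract_timelines, train_site_model
    cohort, _ = small_cohort
    tl = extract_timelines(cohort)
    model, _ = train_site_model(tl)
    cum = score_timeline_table(tl, model)
    thr = 2.0
    dates = first_crossing_dates(cum, thr)
    case_index = (cohort.members[cohort.members["label"] == "case"]
                  .set_index("patient_id")["index_date"])
    leads = lead_times_years(cum, thr, case_index)
    checked = 0
    for patient in cohort:
        if patient.label != "case" or checked >= 20:
            continue
        traj = score_trajectory(extract_timeline(patient), model,
                                index_date=patient.index_date)
        cr = first_crossing(traj, thr)
        if cr.first_crossing_date is None:
            assert patient.patient_id not in dates.index
        else:
            assert dates.loc[patient.patient_id] == cr.first_crossing_date
            assert leads.loc[patient.patient_id] == \
                pytest.approx(cr.lead_time_years)
        checked += 1
    assert checked >= 5
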