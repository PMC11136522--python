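"""Shared fixtures: hand-built micro-extracts plus generated sites.

The expensive generated fixtures are session-scoped so the planted-signal
site, the null-signal site and the parameter-recovery replicates are each
produced once per run.
"""

from __future__ import annotations

import pandas as pd
import pytest

from ehrisk import (ConceptEffect, build_cohort, generate_site, run_site)
from ehrisk.synthetic_ehr import SiteSpec, default_concept_catalog


def make_patients(rows):
    """rows: (patient_id, birth_date, sex, race)"""
    return pd.DataFrame(rows, columns=["patient_id", "birth_date", "sex",
                                       "race_ethnicity"]).assign(
        birth_date=lambda d: pd.to_datetime(d["birth_date"]))


def make_events(rows):
    """rows: (patient_id, date, domain, code[, value_flag])"""
    rows = [r if len(r) == 5 else (*r, "") for r in rows]
    return pd.DataFrame(rows, columns=["patient_id", "date", "domain", "code",
                                       "value_flag"]).assign(
        date=lambda d: pd.to_datetime(d["date"]))


@pytest.fixture
def micro_extract():
    """Four hand-built patients: one clean case, one case with only
    index-day data, one includable noncase, one too-sparse noncase."""
    patients = make_patients([
        ("p1", "1980-06-15", "F", "White"),
        ("p2", "1990-01-01", "M", "Asian"),
        ("p3", "1975-03-10", "F", "Other or unknown"),
        ("p4", "2000-12-31", "M", "White"),
    ])
    events = make_events([
        # p1: case with two years of history, index 2012-03-01
        ("p1", "2010-01-10", "DX", "30183"),
        ("p1", "2010-06-20", "RX", "fluoxetine"),
        ("p1", "2011-02-05", "LAB", "acetaminophen", "H"),
        ("p1", "2011-02-05", "DX", "30590"),
        ("p1", "2012-03-01", "DX", "E9503"),
        ("p1", "2012-04-01", "DX", "30183"),
        # p2: case whose only events share the index date
        ("p2", "2013-05-05", "DX", "96509"),
        ("p2", "2013-05-05", "DX", "4659"),
        ("p2", "2013-06-05", "PX", "99213"),
        ("p2", "2013-07-05", "PX", "99213"),
        # p3: noncase with three spread-out visits
        ("p3", "2009-01-01", "DX", "4019"),
        ("p3", "2009-06-01", "LAB", "cbc", "N"),
        ("p3", "2010-01-01", "PX", "93000"),
        # p4: only two visit dates -> excluded
        ("p4", "2014-01-01", "DX", "4659"),
        ("p4", "2014-03-01", "DX", "4659"),
    ])
    return patients, events


@pytest.fixture
def micro_cohort(micro_extract):
    patients, events = micro_extract
    return build_cohort(patients, events)


@pytest.fixture(scope="session")
def small_site():
    """A modest planted-signal site for mid-weight integration tests."""
    spec = SiteSpec("SM", 6000, 0.02, years_of_data=10.0, visit_rate=5.0,
                    concept_catalog=default_concept_catalog(), seed=11)
    patients, events = generate_site(spec)
    return spec, patients, events


@pytest.fixture(scope="session")
def small_cohort(small_site):
    _, patients, events = small_site
    return build_cohort(patients, events)


@pytest.fixture(scope="session")
def planted_site_result():
    """Full pipeline on a large planted-signal site (calibration-grade)."""
    spec = SiteSpec("PL", 55_000, 0.012, years_of_data=10.0, visit_rate=5.0,
                    concept_catalog=default_concept_catalog(), seed=0)
    patients, events = generate_site(spec)
    return run_site(patients, events, site_id="PL", verbose=False)


@pytest.fixture(scope="session")
def null_site_result():
    """Full pipeline on a site whose catalog carries no planted signal."""
    catalog = [ConceptEffect(c.domain, c.code, c.baseline_rate, 0.0,
                             c.lab_flag_probs)
               for c in default_concept_catalog()]
    spec = SiteSpec("NU", 20_000, 0.02, years_of_data=10.0, visit_rate=5.0,
                    concept_catalog=catalog, seed=7)
    patients, events = generate_site(spec)
    return run_site(patients, events, site_id="NU", verbose=False)


RECOVERY_EFFECTS = {
    "DX:RISK_POS_2": 2.0,
    "DX:RISK_POS_15": 1.5,
    "DX:PROT_NEG_12": -1.2,
    "RX:RISK_POS_25": 2.5,
}


@pytest.fixture(scope="session")
def recovery_replicates():
    """Per-replicate concept stats for planted-effect recovery.

    20 generator replicates at 50 000 patients each, all with the same
    catalog of planted log odds ratios (magnitudes >= 1, baseline rates
    >= 0.005); the whole cohort is used for training so the 2x2 counts
    are as informative as the replicate allows.
    """
    from ehrisk import extract_timelines, train_site_model

    catalog = [
        ConceptEffect("DX", "RISK_POS_2", 0.05, 2.0),
        ConceptEffect("DX", "RISK_POS_15", 0.01, 1.5),
        ConceptEffect("DX", "PROT_NEG_12", 0.02, -1.2),
        ConceptEffect("RX", "RISK_POS_25", 0.005, 2.5),
        ConceptEffect("DX", "NULL_BG", 0.03, 0.0),
    ]
    out = []
    for rep in range(20):
        spec = SiteSpec("RC", 50_000, 0.02, years_of_data=10.0, visit_rate=5.0,
                        concept_catalog=catalog, seed=1000 + rep,
                        no_history_case_fraction=0.0)
        patients, events = generate_site(spec)
        cohort, _ = build_cohort(patients, events)
        _, stats = train_site_model(extract_timelines(cohort))
        out.append(stats.set_index("concept"))
    return out
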