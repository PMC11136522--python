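"""Synthetic multi-site EHR extract generator.

Emulates the kind of flat i2b2-style extracts a federated clinical data
network would produce: per site, a patient table (demographics) and a
timestamped coded event table spanning diagnoses (DX), medications (RX),
procedures (PX) and laboratory results (LAB, with a normal/low/high flag).
A configurable fraction of patients are "cases": they receive an ICD-9
suicide-attempt code (families E95*/965*/967*/969*/881*) at a generated
index date, and their pre-index history is enriched (or thinned) per
concept according to planted odds ratios.

Model of a patient record
-------------------------
Each patient has an observation window inside the site's calendar span;
visit dates follow a homogeneous Poisson process within the window, and
every visit independently emits each catalog concept.  Window lengths are
exponentially distributed (truncated at the end of the span), which yields
the right-skewed follow-up durations typical of health-system data.

Planted effects are expressed on the scale used for reporting risk
factors: the patient-level first-occurrence odds ratio.  Noncases emit a
concept per visit at ``baseline_rate``; the realized presence probability
``pi0`` among inclusion-eligible noncases is measured, and each case with
pre-index history carries the concept with probability
``expit(logit(pi0) + log_or)``.  This calibration makes the planted
``log_or`` recoverable by downstream 2x2 estimation despite cases having
systematically shorter (censored) pre-index records.

The generator emits *complete* histories: cases keep their post-index
events.  Censoring at the index date is deliberately left to the cohort
builder so that it is itself testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

DAYS_PER_YEAR = 365.25

#: Fixed end of every site's calendar span (ICD-9 era).
DATA_END = pd.Timestamp("2015-01-01")

#: Suicide-attempt ICD-9 codes sampled for case index events; every code
#: belongs to one of the wildcard families E95*, 965*, 967*, 969*, 881*.
DEFAULT_CASE_CODES: tuple[str, ...] = (
    "E9500", "E9502", "E9509", "E9531",
    "96500", "96509", "9654",
    "9670", "9678",
    "9690", "9694",
    "8810", "88102",
)

DEFAULT_SEX_MIX: dict[str, float] = {"F": 0.57, "M": 0.43}

DEFAULT_RACE_MIX: dict[str, float] = {
    "White": 0.55,
    "African American": 0.18,
    "Hispanic or Latino": 0.10,
    "Asian": 0.04,
    "Other or unknown": 0.13,
}

_EVENT_COLUMNS = ["patient_id", "date", "domain", "code", "value_flag"]
_PATIENT_COLUMNS = ["patient_id", "birth_date", "sex", "race_ethnicity"]

_DOMAINS = ("DX", "RX", "PX", "LAB")


class SpecValidationError(ValueError):
    """A site or concept specification violates one of its invariants."""


@dataclass(frozen=True)
class ConceptEffect:
    """One catalog concept with its planted effect size.

    Parameters
    ----------
    domain, code
        Concept identity (DX/RX/PX/LAB plus a code string).
    baseline_rate
        Per-visit emission probability among noncases, in (0, 1).
    log_or
        Planted log odds ratio on the patient-level first-occurrence
        scale; 0 means no association with case status.
    lab_flag_probs
        For LAB concepts only: (normal, low, high) probabilities for the
        value flag attached to each emission; must sum to 1.
    """

    domain: str
    code: str
    baseline_rate: float
    log_or: float = 0.0
    lab_flag_probs: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.domain not in _DOMAINS:
            raise SpecValidationError(
                f"concept domain must be one of {_DOMAINS}, got {self.domain!r}"
            )
        if not self.code:
            raise SpecValidationError("concept code must be non-empty")
        if not 0.0 < self.baseline_rate < 1.0:
            raise SpecValidationError(
                f"baseline_rate must lie in (0,1), got {self.baseline_rate}"
            )
        if not np.isfinite(self.log_or):
            raise SpecValidationError("log_or must be finite")
        # Case emission probability implied by (baseline_rate, log_or)
        # must itself be a probability; the logistic transform guarantees
        # (0,1) for finite inputs, checked here for interface fidelity.
        p_case = expit(logit(self.baseline_rate) + self.log_or)
        if not 0.0 < p_case < 1.0:
            raise SpecValidationError(
                "case emission probability derived from (baseline_rate, log_or) "
                f"lies outside (0,1): {p_case}"
            )
        if self.lab_flag_probs is not None:
            if self.domain != "LAB":
                raise SpecValidationError("lab_flag_probs only allowed for LAB concepts")
            if len(self.lab_flag_probs) != 3 or any(p < 0 for p in self.lab_flag_probs):
                raise SpecValidationError("lab_flag_probs must be 3 nonnegative values")
            if abs(sum(self.lab_flag_probs) - 1.0) > 1e-9:
                raise SpecValidationError("lab_flag_probs must sum to 1")


@dataclass
class SiteSpec:
    """Full description of one synthetic site.

    ``no_history_case_fraction`` controls the fraction of cases whose
    pre-index visits are removed entirely (they exist only from the index
    event onward), exercising the downstream rule that cases without data
    before their first suicidal event are excluded.
    ``age_tail_fraction`` puts a small mass of patients outside the
    10-90-year window to exercise the age filter.
    """

    site_id: str
    n_patients: int
    case_fraction: float
    years_of_data: float = 10.0
    visit_rate: float = 5.0
    concept_catalog: Sequence[ConceptEffect] = ()
    demographics_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"sex": dict(DEFAULT_SEX_MIX),
                                 "race_ethnicity": dict(DEFAULT_RACE_MIX)}
    )
    seed: int = 0
    no_history_case_fraction: float = 0.2
    age_tail_fraction: float = 0.04
    case_codes: Sequence[str] = DEFAULT_CASE_CODES
    visit_marker_code: str = "99213"  # E&M office-visit CPT on every encounter

    def validate(self) -> None:
        if not self.site_id:
            raise SpecValidationError("site_id must be non-empty")
        if self.n_patients < 1:
            raise SpecValidationError(f"n_patients must be >= 1, got {self.n_patients}")
        if not 0.0 < self.case_fraction < 1.0:
            raise SpecValidationError(
                f"case_fraction must lie in (0,1), got {self.case_fraction}"
            )
        if self.years_of_data <= 0:
            raise SpecValidationError("years_of_data must be positive")
        if self.visit_rate <= 0:
            raise SpecValidationError("visit_rate must be positive")
        if not 0.0 <= self.no_history_case_fraction <= 1.0:
            raise SpecValidationError("no_history_case_fraction must lie in [0,1]")
        if not 0.0 <= self.age_tail_fraction < 1.0:
            raise SpecValidationError("age_tail_fraction must lie in [0,1)")
        for attr in ("sex", "race_ethnicity"):
            mix = self.demographics_mix.get(attr)
            if not mix:
                raise SpecValidationError(f"demographics_mix must define {attr!r}")
            total = float(sum(mix.values()))
            if abs(total - 1.0) > 1e-9:
                raise SpecValidationError(
                    f"demographics_mix[{attr!r}] proportions sum to {total}, not 1"
                )
            if any(p < 0 for p in mix.values()):
                raise SpecValidationError(f"demographics_mix[{attr!r}] has negative proportion")
        for ce in self.concept_catalog:
            if not isinstance(ce, ConceptEffect):
                raise SpecValidationError("concept_catalog entries must be ConceptEffect")


def _draw_categorical(rng: np.random.Generator, mix: Mapping[str, float], n: int) -> np.ndarray:
    cats = sorted(mix)  # sorted for determinism independent of dict order
    probs = np.array([mix[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    return np.array(cats, dtype=object)[rng.choice(len(cats), size=n, p=probs)]


def generate_site(spec: SiteSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one site's (patient table, event table).

    Pure function of ``spec`` (including its ``seed``): identical specs
    produce identical tables.  Dates are pandas Timestamps; use
    :func:`write_site_extracts` to serialize to the flat CSV format.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    span_days = spec.years_of_data * DAYS_PER_YEAR
    site_start = DATA_END - pd.Timedelta(days=round(span_days))

    # Observation windows: start uniform over the span, exponential length
    # truncated at the end of the span.
    w_start = rng.uniform(0.0, span_days, n)
    w_len = np.minimum(rng.exponential(0.35 * span_days, n), span_days - w_start)

    # Ages at window start: bulk in 12-85 with a small tail outside 10-90.
    u = rng.uniform(size=n)
    bulk = rng.uniform(12.0, 85.0, n)
    young = rng.uniform(2.0, 9.5, n)
    old = rng.uniform(90.5, 99.0, n)
    tail = spec.age_tail_fraction
    age0 = np.where(u < 1.0 - tail, bulk, np.where(u < 1.0 - tail / 2.0, young, old))
    birth_day = w_start - age0 * DAYS_PER_YEAR  # day offset from site_start

    is_case = rng.uniform(size=n) < spec.case_fraction
    # Index date in the last 60% of the window so most cases have history.
    index_day = np.floor(w_start + (0.4 + 0.6 * rng.uniform(size=n)) * w_len).astype(np.int64)
    no_history = is_case & (rng.uniform(size=n) < spec.no_history_case_fraction)

    # Visits: Poisson count over each window, uniform dates within it.
    n_visits = rng.poisson(spec.visit_rate * w_len / DAYS_PER_YEAR)
    vpid = np.repeat(np.arange(n), n_visits)
    vday = np.floor(w_start[vpid] + rng.uniform(size=vpid.size) * w_len[vpid]).astype(np.int64)
    # Cases flagged "no history" lose every visit before their index date.
    keep = ~(no_history[vpid] & (vday < index_day[vpid]))
    vpid, vday = vpid[keep], vday[keep]

    pre_index = is_case[vpid] & (vday < index_day[vpid])

    eligible_mask = _inclusion_proxy(vpid, vday, birth_day, n)
    frames: list[pd.DataFrame] = []

    # Every visit carries a generic evaluation-and-management procedure
    # code, as encounters in real billing extracts do; this grounds the
    # downstream visit proxy (distinct event dates) in the visit process.
    if vpid.size:
        frames.append(pd.DataFrame({
            "pid": vpid, "day": vday, "domain": "PX",
            "code": spec.visit_marker_code, "value_flag": "",
        }))
    noncase_eligible = eligible_mask & ~is_case
    n_noncase_eligible = int(noncase_eligible.sum())

    # Case-defining index events.
    case_idx = np.nonzero(is_case)[0]
    if case_idx.size:
        codes = np.array(list(spec.case_codes), dtype=object)
        frames.append(pd.DataFrame({
            "pid": case_idx,
            "day": index_day[case_idx],
            "domain": "DX",
            "code": codes[rng.choice(codes.size, size=case_idx.size)],
            "value_flag": "",
        }))

    # Catalog concept emissions.
    has_pre_visit = np.bincount(vpid[pre_index], minlength=n) > 0
    for ce in spec.concept_catalog:
        emit = rng.uniform(size=vpid.size) < ce.baseline_rate

        # Realized noncase presence among inclusion-eligible patients,
        # lightly smoothed so the logit is always defined.
        carriers = np.zeros(n, dtype=bool)
        carriers[vpid[emit]] = True
        n_carry = int((carriers & noncase_eligible).sum())
        pi0 = (n_carry + 0.5) / (n_noncase_eligible + 1.0)
        pi1 = float(np.clip(expit(logit(pi0) + ce.log_or), 1e-12, 1 - 1e-12))

        # Resample pre-index presence for cases that have pre-index visits:
        # drop their baseline pre-index emissions, then plant the concept at
        # one uniformly chosen pre-index visit with probability pi1.
        resample = has_pre_visit & is_case
        emit = emit & ~(pre_index & resample[vpid])
        planted = resample & (rng.uniform(size=n) < pi1)

        sel = np.nonzero(emit)[0]
        add_rows: np.ndarray
        if planted.any():
            # one uniformly chosen pre-index visit per planted patient
            cand = np.nonzero(pre_index & planted[vpid])[0]
            key = rng.uniform(size=cand.size)
            order = np.lexsort((key, vpid[cand]))
            cand_sorted = cand[order]
            pid_sorted = vpid[cand][order]
            last_of_group = np.r_[pid_sorted[1:] != pid_sorted[:-1], True]
            add_rows = cand_sorted[last_of_group]
        else:
            add_rows = np.empty(0, dtype=np.int64)
        sel = np.union1d(sel, add_rows)

        if sel.size == 0:
            continue
        if ce.domain == "LAB":
            probs = ce.lab_flag_probs or (0.8, 0.1, 0.1)
            flags = np.array(["N", "L", "H"], dtype=object)[
                rng.choice(3, size=sel.size, p=np.asarray(probs, dtype=float))
            ]
        else:
            flags = ""
        frames.append(pd.DataFrame({
            "pid": vpid[sel],
            "day": vday[sel],
            "domain": ce.domain,
            "code": ce.code,
            "value_flag": flags,
        }))

    ids = np.array([f"{spec.site_id}-{i:06d}" for i in range(n)], dtype=object)
    patients = pd.DataFrame({
        "patient_id": ids,
        "birth_date": site_start + pd.to_timedelta(np.round(birth_day), unit="D"),
        "sex": _draw_categorical(rng, spec.demographics_mix["sex"], n),
        "race_ethnicity": _draw_categorical(rng, spec.demographics_mix["race_ethnicity"], n),
    })

    if frames:
        events = pd.concat(frames, ignore_index=True)
    else:
        events = pd.DataFrame(
            {"pid": np.empty(0, dtype=np.int64), "day": np.empty(0, dtype=np.int64),
             "domain": [], "code": [], "value_flag": []})
    events["patient_id"] = ids[events["pid"].to_numpy(dtype=np.int64)]
    events["date"] = site_start + pd.to_timedelta(events["day"], unit="D")
    events = (
        events[_EVENT_COLUMNS]
        .sort_values(_EVENT_COLUMNS, kind="mergesort")
        .reset_index(drop=True)
    )
    return patients, events


def _inclusion_proxy(vpid: np.ndarray, vday: np.ndarray, birth_day: np.ndarray,
                     n: int) -> np.ndarray:
    """Which patients would plausibly pass downstream inclusion.

    Mirrors the default rules (>=3 distinct visit dates, >=30-day span,
    some record after age 10 and before age 90); used only to calibrate
    planted effects against the population the model will actually see.
    """
    if vpid.size == 0:
        return np.zeros(n, dtype=bool)
    order = np.lexsort((vday, vpid))
    p, d = vpid[order], vday[order]
    new_pair = np.r_[True, (p[1:] != p[:-1]) | (d[1:] != d[:-1])]
    n_dates = np.bincount(p[new_pair], minlength=n)
    dmin = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    dmax = np.full(n, np.iinfo(np.int64).min, dtype=np.int64)
    np.minimum.at(dmin, vpid, vday)
    np.maximum.at(dmax, vpid, vday)
    has = n_dates > 0
    span_ok = np.zeros(n, dtype=bool)
    span_ok[has] = (dmax[has] - dmin[has]) >= 30
    age_ok = np.zeros(n, dtype=bool)
    age_ok[has] = ((dmax[has] - birth_day[has]) / DAYS_PER_YEAR > 10.0) & (
        (dmin[has] - birth_day[has]) / DAYS_PER_YEAR < 90.0
    )
    return (n_dates >= 3) & span_ok & age_ok


def write_site_extracts(patients: pd.DataFrame, events: pd.DataFrame,
                        out_dir: str | Path, site_id: str) -> dict[str, str]:
    """Write one site's extract pair as CSV; returns relative file names."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p_name, e_name = f"{site_id}_patients.csv", f"{site_id}_events.csv"
    p = patients.copy()
    p["birth_date"] = pd.to_datetime(p["birth_date"]).dt.strftime("%Y-%m-%d")
    p.to_csv(out_dir / p_name, index=False)
    e = events.copy()
    e["date"] = pd.to_datetime(e["date"]).dt.strftime("%Y-%m-%d")
    e.to_csv(out_dir / e_name, index=False)
    return {"patients": p_name, "events": e_name}


def generate_network(specs: Sequence[SiteSpec], out_dir: str | Path) -> dict:
    """Generate per-site extract pairs plus a JSON manifest.

    Raises on an empty spec list or duplicate site ids.  The manifest
    lists, per site, the file names, seed, and requested sizes.
    """
    specs = list(specs)
    if not specs:
        raise SpecValidationError("at least one SiteSpec is required")
    ids = [s.site_id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SpecValidationError(f"duplicate site_id(s): {dupes}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"sites": []}
    for s in specs:
        patients, events = generate_site(s)
        files = write_site_extracts(patients, events, out_dir, s.site_id)
        manifest["sites"].append({
            "site_id": s.site_id,
            "seed": int(s.seed),
            "n_patients": int(s.n_patients),
            "case_fraction": float(s.case_fraction),
            "years_of_data": float(s.years_of_data),
            **files,
        })
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def default_concept_catalog() -> list[ConceptEffect]:
    """A catalog patterned on the risk-factor landscape of a real network.

    Adverse effects have odds ratios roughly in the 2-15 range seen for
    psychiatric, substance-use, toxicology and self-harm-adjacent codes;
    null and mildly protective concepts model routine care.
    """
    log = np.log
    return [
        # Diagnoses
        ConceptEffect("DX", "9779", 0.0008, log(14.0)),    # poisoning, unspecified drug
        ConceptEffect("DX", "2920", 0.0015, log(10.0)),    # drug withdrawal syndrome
        ConceptEffect("DX", "30420", 0.0012, log(9.0)),    # cocaine dependence
        ConceptEffect("DX", "V6284", 0.0035, log(11.0)),   # suicidal ideation
        ConceptEffect("DX", "30183", 0.0015, log(10.0)),   # borderline personality
        ConceptEffect("DX", "30590", 0.005, log(8.0)),     # drug abuse, unspecified
        ConceptEffect("DX", "3030", 0.002, log(8.5)),      # acute alcoholic intoxication
        ConceptEffect("DX", "29650", 0.003, log(7.0)),     # bipolar, depressed
        ConceptEffect("DX", "29620", 0.006, log(5.0)),     # major depressive disorder
        ConceptEffect("DX", "4019", 0.030, 0.0),           # hypertension (null)
        ConceptEffect("DX", "4659", 0.040, 0.0),           # acute URI (null)
        ConceptEffect("DX", "V700", 0.050, log(0.6)),      # routine exam (protective)
        # Medications
        ConceptEffect("RX", "lithium", 0.0012, log(6.0)),
        ConceptEffect("RX", "fluoxetine", 0.005, log(4.0)),
        ConceptEffect("RX", "nicotine-replacement", 0.004, log(2.5)),
        ConceptEffect("RX", "amoxicillin", 0.050, 0.0),
        # Laboratory tests (with value flags)
        ConceptEffect("LAB", "acetaminophen", 0.002, log(13.0), (0.55, 0.05, 0.40)),
        ConceptEffect("LAB", "salicylate", 0.0015, log(13.0), (0.60, 0.05, 0.35)),
        ConceptEffect("LAB", "cbc", 0.120, 0.0, (0.80, 0.10, 0.10)),
        # Procedures
        ConceptEffect("PX", "90801", 0.003, log(5.0)),     # psychiatric evaluation
        ConceptEffect("PX", "93000", 0.030, 0.0),          # ECG (null)
    ]


def five_site_network_specs(n_patients: int = 20_000, seed: int = 0,
                            catalog: Sequence[ConceptEffect] | None = None,
                            ) -> list[SiteSpec]:
    """Five heterogeneous SiteSpecs emulating a real federated network.

    Case fractions span 0.34%-1.68%, calendar spans 8-17 years, and the
    race/ethnicity mixes differ strongly by site, echoing the published
    between-site heterogeneity of a five-system validation network.
    """
    if catalog is None:
        catalog = default_concept_catalog()
    rows = [
        # site, case_fraction, years, visit_rate, race mix
        ("S1", 0.0110, 17.0, 5.0, {"White": 0.727, "African American": 0.064,
                                   "Hispanic or Latino": 0.069, "Asian": 0.037,
                                   "Other or unknown": 0.103}),
        ("S2", 0.0168, 17.0, 5.5, {"White": 0.364, "African American": 0.308,
                                   "Hispanic or Latino": 0.098, "Asian": 0.044,
                                   "Other or unknown": 0.186}),
        ("S3", 0.0131, 10.0, 4.5, {"White": 0.747, "African American": 0.175,
                                   "Hispanic or Latino": 0.001, "Asian": 0.010,
                                   "Other or unknown": 0.067}),
        ("S4", 0.0055, 13.0, 4.0, {"White": 0.424, "African American": 0.199,
                                   "Hispanic or Latino": 0.081, "Asian": 0.004,
                                   "Other or unknown": 0.292}),
        ("S5", 0.0034, 8.0, 4.0, {"White": 0.577, "African American": 0.076,
                                  "Hispanic or Latino": 0.106, "Asian": 0.026,
                                  "Other or unknown": 0.215}),
    ]
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(len(rows))]
    specs = []
    for (site_id, cf, years, rate, race), child in zip(rows, child_seeds):
        mix = {"sex": dict(DEFAULT_SEX_MIX), "race_ethnicity": race}
        specs.append(SiteSpec(
            site_id=site_id, n_patients=n_patients, case_fraction=cf,
            years_of_data=years, visit_rate=rate, concept_catalog=list(catalog),
            demographics_mix=mix, seed=child,
        ))
    return specs
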