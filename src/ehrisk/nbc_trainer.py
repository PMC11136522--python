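"""Site-specific naive-Bayes scorer: partial risk scores, ORs, CIs.

Each concept observed in the training split receives a partial risk
score: the natural log of the ratio of its (smoothed) prevalence among
cases to its prevalence among noncases.  Negative scores are protective,
positive scores adverse.  Smoothing is an additive pseudocount k on each
cell (denominator +2k), so scores stay finite even for concepts seen in
one class only; k = 1 by default and is a configuration knob.

Only recorded features contribute to a patient's cumulative score: the
absence-likelihood term of a full naive-Bayes model is intentionally not
included, matching a scorer that sums partial scores of features in the
order they were recorded.

The per-concept odds ratio (a*d)/(b*c) with a Haldane-Anscombe 0.5
correction on zero cells, plus its Wald 95% CI on the log scale, is
reported alongside the score for interpretability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort_builder import Cohort
from .feature_extraction import Concept, FeatureTimeline, timelines_to_table

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def split_cohort(cohort: Cohort, fraction: float = 0.5,
                 seed: int = 0) -> tuple[Cohort, Cohort]:
    """Simple random, unstratified patient-level split.

    Returns (training, validation); disjoint and exhaustive, reproducible
    from ``seed`` regardless of member-row order.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0,1), got {fraction}")
    ids = np.sort(cohort.members["patient_id"].to_numpy())
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    n_train = int(round(fraction * len(ids)))
    return cohort.subset(perm[:n_train]), cohort.subset(perm[n_train:])


def partial_score(a, b, c, d, k: float = 1.0):
    """Log prevalence-ratio score from 2x2 counts, with pseudocount k.

    score = log( ((a+k)/(a+b+2k)) / ((c+k)/(c+d+2k)) ), natural log.
    Accepts scalars or arrays.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(a + b <= 0) or np.any(c + d <= 0):
        raise ValueError("each class margin (a+b, c+d) must be positive")
    if k <= 0:
        raise ValueError("smoothing constant k must be positive")
    p_case = (a + k) / (a + b + 2 * k)
    p_noncase = (c + k) / (c + d + 2 * k)
    out = np.log(p_case / p_noncase)
    return float(out) if out.ndim == 0 else out


def compute_or(a, b, c, d) -> tuple[float, tuple[float, float]]:
    """Odds ratio (a*d)/(b*c) with 95% Wald CI.

    If any cell is zero, 0.5 is added to all four cells
    (Haldane-Anscombe) before computing both the OR and the CI.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b <= 0 or c + d <= 0:
        raise ValueError("each class margin must be positive")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_value) - Z95 * se)
    hi = math.exp(math.log(or_value) + Z95 * se)
    return or_value, (lo, hi)


def _or_arrays(a, b, c, d) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    zero = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0)
    a, b, c, d = (x + 0.5 * zero for x in (a, b, c, d))
    or_value = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_value)
    return or_value, np.exp(log_or - Z95 * se), np.exp(log_or + Z95 * se)


@dataclass
class SiteModel:
    """Concept -> partial-score map trained at one site."""

    site_id: str
    scores: dict[str, float]
    n_cases: int
    n_noncases: int
    k: float = 1.0
    split_seed: int | None = None

    def score(self, concept: Concept | str) -> float:
        key = concept.key if isinstance(concept, Concept) else concept
        return self.scores.get(key, 0.0)

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "n_cases": self.n_cases,
            "n_noncases": self.n_noncases,
            "smoothing_k": self.k,
            "split_seed": self.split_seed,
            "log_base": "e",
            "scores": self.scores,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "SiteModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(site_id=d["site_id"], scores=d["scores"],
                   n_cases=d["n_cases"], n_noncases=d["n_noncases"],
                   k=d.get("smoothing_k", 1.0), split_seed=d.get("split_seed"))


def train_site_model(timelines: pd.DataFrame | Iterable[FeatureTimeline],
                     k: float = 1.0, site_id: str = "site",
                     split_seed: int | None = None,
                     ) -> tuple[SiteModel, pd.DataFrame]:
    """Train on a training split's timelines.

    Returns the SiteModel plus a per-concept stats table with the 2x2
    counts (a: cases with concept, b: cases without, c/d likewise for
    noncases), smoothed prevalences, partial score, OR and 95% CI.
    """
    if not isinstance(timelines, pd.DataFrame):
        timelines = timelines_to_table(timelines)
    if k <= 0:
        raise ValueError("smoothing constant k must be positive")
    pats = timelines[["patient_id", "label"]].drop_duplicates()
    n_cases = int((pats["label"] == "case").sum())
    n_noncases = int((pats["label"] == "noncase").sum())
    if n_cases == 0 or n_noncases == 0:
        raise ValueError(
            "training set must contain at least one case and one noncase")

    counts = (
        timelines.groupby(["concept", "domain", "code", "lab_flag", "label"],
                          dropna=False)
        .size().unstack("label", fill_value=0).reset_index()
    )
    a = counts.get("case", pd.Series(0, index=counts.index)).to_numpy(dtype=float)
    c = counts.get("noncase", pd.Series(0, index=counts.index)).to_numpy(dtype=float)
    b = n_cases - a
    d = n_noncases - c

    stats = counts[["concept", "domain", "code", "lab_flag"]].copy()
    stats["a"] = a.astype(int)
    stats["b"] = b.astype(int)
    stats["c"] = c.astype(int)
    stats["d"] = d.astype(int)
    stats["p_case"] = (a + k) / (n_cases + 2 * k)
    stats["p_noncase"] = (c + k) / (n_noncases + 2 * k)
    stats["partial_score"] = partial_score(a, b, c, d, k)
    or_value, lo, hi = _or_arrays(a, b, c, d)
    stats["or_value"] = or_value
    stats["ci95_low"] = lo
    stats["ci95_high"] = hi
    stats = stats.sort_values("concept").reset_index(drop=True)

    scores = dict(zip(stats["concept"], stats["partial_score"].astype(float)))
    model = SiteModel(site_id=site_id, scores=scores, n_cases=n_cases,
                      n_noncases=n_noncases, k=k, split_seed=split_seed)
    return model, stats


def concept_report(stats: pd.DataFrame, min_total_patients: int = 100,
                   min_case_patients: int = 10) -> pd.DataFrame:
    """Reporting view of a concept-stats table.

    Keeps concepts carried by at least ``min_total_patients`` patients
    (cases and noncases combined) and suppresses the OR (and CI) where
    fewer than ``min_case_patients`` cases carry the concept; adds the
    case-share percentage among carriers.
    """
    out = stats[(stats["a"] + stats["c"]) >= min_total_patients].copy()
    mask = out["a"] < min_case_patients
    out.loc[mask, ["or_value", "ci95_low", "ci95_high"]] = np.nan
    carriers = out["a"] + out["c"]
    out["case_pct"] = np.round(100.0 * out["a"] / carriers, 1)
    return out.reset_index(drop=True)
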