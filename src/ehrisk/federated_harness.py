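"""Multi-site orchestration: per-site pipelines plus cross-site aggregation.

Each site runs the full local pipeline — cohort construction, 50/50
random split, naive-Bayes training on the training half, trajectory
scoring and threshold calibration (thresholds come from the *training*
noncases' maximal scores), evaluation on the validation half — and only
aggregate summaries (per-concept ORs and counts, performance metrics)
cross the site boundary.  Sites run sequentially and independently;
aggregation is the only shared step.

Cross-site means are unweighted arithmetic means over sites reporting a
metric; concept counts are pooled by summation across reporting sites.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort_builder import (CaseDefinition, InclusionRules, build_cohort,
                             read_extracts)
from .evaluation import (SiteEvaluation, derive_thresholds,
                         evaluate_validation)
from .feature_extraction import extract_timelines
from .nbc_trainer import SiteModel, split_cohort, train_site_model
from .trajectory_scoring import (lead_times_years, max_scores,
                                 score_timeline_table)


@dataclass
class HarnessConfig:
    """Knobs shared by every site in a federated run."""

    smoothing_k: float = 1.0
    specificity_levels: tuple[float, ...] = (0.90, 0.99)
    split_fraction: float = 0.5
    split_seed: int = 0
    privacy_mode: bool = True
    case_definition: CaseDefinition = field(default_factory=CaseDefinition)
    inclusion: InclusionRules = field(default_factory=InclusionRules)

    @classmethod
    def from_dict(cls, d: Mapping) -> "HarnessConfig":
        kwargs = dict(d)
        if "case_code_patterns" in kwargs:
            kwargs["case_definition"] = CaseDefinition(
                tuple(kwargs.pop("case_code_patterns")))
        if "inclusion" in kwargs and isinstance(kwargs["inclusion"], Mapping):
            kwargs["inclusion"] = InclusionRules(**kwargs["inclusion"])
        if "specificity_levels" in kwargs:
            kwargs["specificity_levels"] = tuple(kwargs["specificity_levels"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HarnessConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SiteResult:
    site_id: str
    evaluation: SiteEvaluation
    model: SiteModel
    concept_stats: pd.DataFrame
    ledger: dict


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def run_site(patients: pd.DataFrame, events: pd.DataFrame,
             config: HarnessConfig | None = None,
             site_id: str = "site", verbose: bool = True) -> SiteResult:
    """Run the full local pipeline for one site's extract pair.

    With ``privacy_mode`` on (the default), the returned concept-stats
    table and evaluation contain only aggregate quantities — no
    patient-level rows or identifiers.
    """
    config = config or HarnessConfig()
    try:
        cohort, ledger = build_cohort(patients, events,
                                      config.case_definition, config.inclusion)
        if verbose:
            _log(f"[{site_id}] cohort: {ledger['n_cases']} cases, "
                 f"{ledger['n_noncases']} noncases, excluded {ledger['excluded']}")
        train, val = split_cohort(cohort, config.split_fraction, config.split_seed)

        tl_train = extract_timelines(train)
        model, stats = train_site_model(tl_train, k=config.smoothing_k,
                                        site_id=site_id,
                                        split_seed=config.split_seed)
        if verbose:
            _log(f"[{site_id}] trained on {model.n_cases} cases / "
                 f"{model.n_noncases} noncases, {len(stats)} concepts")

        train_max = max_scores(tl_train, model, members=train.members)
        noncase_train = train_max.loc[train_max["label"] == "noncase", "max_score"]
        thresholds = derive_thresholds(noncase_train, config.specificity_levels)

        tl_val = extract_timelines(val)
        cum_val = score_timeline_table(tl_val, model)
        val_max = max_scores(tl_val, model, members=val.members)

        case_index = (val.members[val.members["label"] == "case"]
                      .set_index("patient_id")["index_date"])
        leads = {q: lead_times_years(cum_val, thr, case_index)
                 for q, thr in thresholds.levels.items()}
        evaluation = evaluate_validation(site_id, val_max, thresholds, leads)
        if verbose:
            _log(f"[{site_id}] validation AUC {evaluation.auc:.3f} "
                 f"(SE {evaluation.auc_se:.4f})")
    except Exception as exc:
        raise RuntimeError(f"site {site_id}: {exc}") from exc

    if config.privacy_mode:
        stats = stats.reset_index(drop=True)  # aggregate-only already
    return SiteResult(site_id, evaluation, model, stats, ledger)


def run_site_files(patients_path: str | Path, events_path: str | Path,
                   config: HarnessConfig | None = None,
                   site_id: str = "site", verbose: bool = True) -> SiteResult:
    patients, events = read_extracts(patients_path, events_path)
    return run_site(patients, events, config, site_id, verbose)


def concept_case_share(pooled_cases: int, pooled_noncases: int) -> float:
    """Percentage of concept carriers who are cases, to 1 decimal."""
    if pooled_cases < 0 or pooled_noncases < 0:
        raise ValueError("counts must be nonnegative")
    total = pooled_cases + pooled_noncases
    if total == 0:
        raise ValueError("concept has no carriers")
    return round(100.0 * pooled_cases / total, 1)


@dataclass
class NetworkSummary:
    """Cross-site aggregation of per-site evaluations and concept stats."""

    site_ids: list[str]
    metrics: dict          # cross-site means/ranges, per specificity level
    concept_table: pd.DataFrame | None
    site_evaluations: list[SiteEvaluation]

    def to_dict(self) -> dict:
        return {
            "site_ids": self.site_ids,
            "metrics": self.metrics,
            "sites": [e.to_dict() for e in self.site_evaluations],
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _mean_range(values: Sequence[float]) -> dict:
    vals = sorted(float(v) for v in values
                  if v is not None and np.isfinite(v))  # order-invariant sums
    if not vals:
        return {"mean": None, "min": None, "max": None, "n_sites": 0}
    return {"mean": float(np.mean(vals)), "min": float(min(vals)),
            "max": float(max(vals)), "n_sites": len(vals)}


def aggregate(site_evaluations: Sequence[SiteEvaluation],
              concept_stats_by_site: Mapping[str, pd.DataFrame] | None = None,
              ) -> NetworkSummary:
    """Unweighted cross-site means and min-max ranges, plus the pooled
    concept table (per-site ORs joined with summed carrier counts)."""
    evs = list(site_evaluations)
    if not evs:
        raise ValueError("at least one site evaluation is required")

    metrics: dict = {"auc": _mean_range([e.auc for e in evs])}
    levels = sorted({q for e in evs for q in e.levels})
    metrics["levels"] = {}
    for q in levels:
        ms = [e.levels[q] for e in evs if q in e.levels]
        metrics["levels"][f"{q:g}"] = {
            "sensitivity": _mean_range([m.sensitivity for m in ms]),
            "specificity": _mean_range([m.specificity for m in ms]),
            "ppv": _mean_range([m.ppv for m in ms]),
            "npv": _mean_range([m.npv for m in ms]),
            "mean_lead_time_years": _mean_range(
                [m.mean_lead_time_years for m in ms]),
        }
    top_decile = [
        float(e.decile_table.loc[e.decile_table["decile"] == 10, "case_pct"].iloc[0])
        for e in evs if e.decile_table is not None
    ]
    if top_decile:
        metrics["top_decile_case_pct"] = _mean_range(top_decile)

    concept_table = None
    if concept_stats_by_site:
        pieces = []
        for sid, stats in concept_stats_by_site.items():
            t = stats[["concept", "a", "c", "or_value"]].copy()
            t["site_id"] = sid
            pieces.append(t)
        allstats = pd.concat(pieces, ignore_index=True)
        ors = allstats.pivot_table(index="concept", columns="site_id",
                                   values="or_value", aggfunc="first")
        ors.columns = [f"or_{c}" for c in ors.columns]
        pooled = allstats.groupby("concept")[["a", "c"]].sum()
        pooled = pooled.rename(columns={"a": "pooled_cases", "c": "pooled_noncases"})
        concept_table = pooled.join(ors)
        concept_table["case_share_pct"] = [
            concept_case_share(int(r.pooled_cases), int(r.pooled_noncases))
            if r.pooled_cases + r.pooled_noncases > 0 else np.nan
            for r in concept_table.itertuples()
        ]
        or_cols = [c for c in concept_table.columns if c.startswith("or_")]
        concept_table["or_mean"] = concept_table[or_cols].mean(axis=1)
        concept_table["or_min"] = concept_table[or_cols].min(axis=1)
        concept_table["or_max"] = concept_table[or_cols].max(axis=1)
        concept_table = concept_table.reset_index()

    return NetworkSummary(
        site_ids=[e.site_id for e in evs],
        metrics=metrics,
        concept_table=concept_table,
        site_evaluations=evs,
    )


def run_network(manifest_path: str | Path, config: HarnessConfig | None = None,
                verbose: bool = True) -> tuple[NetworkSummary, list[SiteResult]]:
    """Run every site listed in a generator manifest, then aggregate."""
    config = config or HarnessConfig()
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    results = []
    for entry in manifest["sites"]:
        results.append(run_site_files(
            base / entry["patients"], base / entry["events"], config,
            site_id=entry["site_id"], verbose=verbose))
    summary = aggregate([r.evaluation for r in results],
                        {r.site_id: r.concept_stats for r in results})
    return summary, results


def performance_table(summary: NetworkSummary) -> pd.DataFrame:
    """Per-site performance in a long table: one row per specificity
    level and site (sensitivity, PPV, NPV, AUC(SE), lead time + CI)."""
    rows = []
    for ev in summary.site_evaluations:
        for q, m in sorted(ev.levels.items(), reverse=True):
            ci = m.lead_time_ci95
            rows.append({
                "specificity_level": q,
                "site_id": ev.site_id,
                "n_validation_cases": ev.n_validation_cases,
                "case_prevalence_pct": round(
                    100.0 * ev.n_validation_cases
                    / (ev.n_validation_cases + ev.n_validation_noncases), 2),
                "sensitivity_pct": round(100.0 * m.sensitivity, 1),
                "ppv_pct": round(100.0 * m.ppv, 1) if np.isfinite(m.ppv) else None,
                "npv_pct": round(100.0 * m.npv, 1) if np.isfinite(m.npv) else None,
                "auc": round(ev.auc, 3),
                "auc_se": round(ev.auc_se, 4),
                "mean_lead_time_years": (round(m.mean_lead_time_years, 2)
                                         if m.mean_lead_time_years is not None else None),
                "lead_time_ci95_low": round(ci[0], 2) if ci else None,
                "lead_time_ci95_high": round(ci[1], 2) if ci else None,
            })
    return pd.DataFrame(rows)
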