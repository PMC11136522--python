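"""Threshold derivation and model performance metrics.

Alert thresholds are specificity quantiles of the *training* noncases'
maximal scores: the threshold for level q is the empirical q-quantile
(inclusive/type-1: the smallest observed score with at least a fraction
q of scores at or below it), so the realized training specificity under
the strict-crossing rule is >= q.  Metrics — sensitivity, realized
specificity, PPV, NPV at the validation prevalence, AUC with
Hanley-McNeil standard error, mean lead time with a normal-approximation
CI, and a decile enrichment table — are computed on the validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

Z95 = 1.959963984540054


@dataclass
class ThresholdSet:
    """Specificity level -> score threshold, nondecreasing in the level."""

    levels: dict[float, float]
    source: str = "training noncases"

    def __post_init__(self) -> None:
        qs = sorted(self.levels)
        ts = [self.levels[q] for q in qs]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be nondecreasing in specificity level")


def derive_thresholds(noncase_max_scores, levels=(0.90, 0.99),
                      source: str = "training noncases") -> ThresholdSet:
    """Empirical type-1 quantiles of noncase maximal scores."""
    s = np.sort(np.asarray(noncase_max_scores, dtype=float))
    if s.size == 0:
        raise ValueError("at least one noncase score is required")
    out = {}
    for q in levels:
        if not 0.0 < q <= 1.0:
            raise ValueError(f"specificity level must lie in (0,1], got {q}")
        out[float(q)] = float(s[_type1_index(q, s.size)])
    return ThresholdSet(out, source)


def _type1_index(q: float, n: int) -> int:
    # smallest index i with (i+1)/n >= q; tolerance guards float fuzz in q*n
    return min(max(int(np.ceil(q * n - 1e-9)) - 1, 0), n - 1)


def confusion_at_threshold(max_scores, labels, threshold: float) -> dict[str, float]:
    """Sensitivity / specificity / PPV / NPV under alert = score > threshold.

    ``labels`` are "case"/"noncase" strings or booleans (True = case).
    PPV (NPV) is NaN when there are no alerts (no non-alerts).
    """
    scores = np.asarray(max_scores, dtype=float)
    lab = np.asarray(labels)
    is_case = lab == "case" if lab.dtype.kind in "OUS" else lab.astype(bool)
    n_case, n_noncase = int(is_case.sum()), int((~is_case).sum())
    if n_case == 0 or n_noncase == 0:
        raise ValueError("both classes must be present")
    alert = scores > threshold
    tp = int((alert & is_case).sum())
    fp = int((alert & ~is_case).sum())
    fn = n_case - tp
    tn = n_noncase - fp
    return {
        "sensitivity": tp / n_case,
        "specificity": tn / n_noncase,
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
        "n_detected": tp,
    }


def auc(case_scores, noncase_scores) -> tuple[float, float]:
    """Mann-Whitney AUC with Hanley-McNeil standard error.

    AUC = P(case score > noncase score) + 0.5 P(tie), computed from
    midranks; SE by the Hanley-McNeil (1982) formula.
    """
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(noncase_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both classes must be non-empty")
    r = rankdata(np.concatenate([x, y]))
    a = (r[: x.size].sum() - x.size * (x.size + 1) / 2.0) / (x.size * y.size)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (x.size - 1) * (q1 - a * a)
           + (y.size - 1) * (q2 - a * a)) / (x.size * y.size)
    return float(a), float(np.sqrt(max(var, 0.0)))


def auc_ci(a: float, se: float) -> tuple[float, float]:
    """95% CI a +/- 1.96*se, clipped to [0, 1]."""
    return max(a - Z95 * se, 0.0), min(a + Z95 * se, 1.0)


@dataclass
class TimelinessSummary:
    n_detected: int
    mean_years: float | None
    ci95: tuple[float, float] | None


def timeliness_summary(lead_times_years) -> TimelinessSummary:
    """Mean lead time over detected cases, with mean +/- 1.96 sd/sqrt(n) CI.

    Zero detections yield an empty summary; a single detection has a
    mean but no CI (sd undefined).
    """
    lt = np.asarray(lead_times_years, dtype=float)
    if np.any(lt < 0):
        raise ValueError("lead times must be nonnegative")
    n = lt.size
    if n == 0:
        return TimelinessSummary(0, None, None)
    mean = float(lt.mean())
    if n == 1:
        return TimelinessSummary(1, mean, None)
    half = Z95 * lt.std(ddof=1) / np.sqrt(n)
    return TimelinessSummary(n, mean, (mean - half, mean + half))


def decile_table(max_scores, labels) -> pd.DataFrame:
    """Percentage of cases and of noncases per risk-score decile.

    Decile boundaries are the 10%..90% type-1 quantiles of the *noncase*
    maximal scores, so with no signal each decile holds ~10% of the
    noncases; case concentration in the top decile indicates
    discrimination.  Scores equal to a boundary fall in the decile above.
    """
    scores = np.asarray(max_scores, dtype=float)
    lab = np.asarray(labels)
    is_case = lab == "case" if lab.dtype.kind in "OUS" else lab.astype(bool)
    nc = np.sort(scores[~is_case])
    if nc.size < 10:
        raise ValueError("at least 10 noncases are required")
    idx = [_type1_index(q, nc.size) for q in np.linspace(0.1, 0.9, 9)]
    bounds = nc[idx]
    assign = np.searchsorted(bounds, scores, side="right")  # 0..9
    rows = []
    n_case, n_noncase = int(is_case.sum()), int((~is_case).sum())
    for dec in range(10):
        in_dec = assign == dec
        cn = int((in_dec & is_case).sum())
        nn = int((in_dec & ~is_case).sum())
        rows.append({
            "decile": dec + 1,
            "case_n": cn,
            "noncase_n": nn,
            "case_pct": 100.0 * cn / n_case if n_case else float("nan"),
            "noncase_pct": 100.0 * nn / n_noncase if n_noncase else float("nan"),
        })
    return pd.DataFrame(rows)


@dataclass
class LevelMetrics:
    """Validation metrics at one specificity level."""

    level: float
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_detected: int
    mean_lead_time_years: float | None
    lead_time_ci95: tuple[float, float] | None

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "n_detected": self.n_detected,
            "mean_lead_time_years": self.mean_lead_time_years,
            "lead_time_ci95": list(self.lead_time_ci95) if self.lead_time_ci95 else None,
        }


@dataclass
class SiteEvaluation:
    """Aggregate performance of one site's validation split."""

    site_id: str
    n_validation_cases: int
    n_validation_noncases: int
    auc: float
    auc_se: float
    levels: dict[float, LevelMetrics] = field(default_factory=dict)
    decile_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "n_validation_cases": self.n_validation_cases,
            "n_validation_noncases": self.n_validation_noncases,
            "auc": self.auc,
            "auc_se": self.auc_se,
            "auc_ci95": list(auc_ci(self.auc, self.auc_se)),
            "levels": {f"{q:g}": m.to_dict() for q, m in self.levels.items()},
            "decile_table": (self.decile_table.to_dict(orient="records")
                             if self.decile_table is not None else None),
        }


def evaluate_validation(site_id: str, val_max: pd.DataFrame,
                        thresholds: ThresholdSet,
                        lead_times_by_level: dict[float, pd.Series]) -> SiteEvaluation:
    """Assemble a SiteEvaluation from validation max scores and crossings.

    ``val_max`` has columns patient_id, label, max_score;
    ``lead_times_by_level`` maps specificity level -> lead times (years)
    of the detected validation cases at that level's threshold.
    """
    scores = val_max["max_score"].to_numpy()
    labels = val_max["label"].to_numpy()
    is_case = labels == "case"
    a, se = auc(scores[is_case], scores[~is_case])
    ev = SiteEvaluation(
        site_id=site_id,
        n_validation_cases=int(is_case.sum()),
        n_validation_noncases=int((~is_case).sum()),
        auc=a, auc_se=se,
        decile_table=decile_table(scores, labels),
    )
    for q, thr in sorted(thresholds.levels.items()):
        conf = confusion_at_threshold(scores, labels, thr)
        tsum = timeliness_summary(lead_times_by_level.get(q, []))
        ev.levels[q] = LevelMetrics(
            level=q, threshold=thr,
            sensitivity=conf["sensitivity"], specificity=conf["specificity"],
            ppv=conf["ppv"], npv=conf["npv"],
            n_detected=tsum.n_detected,
            mean_lead_time_years=tsum.mean_years,
            lead_time_ci95=tsum.ci95,
        )
    return ev
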