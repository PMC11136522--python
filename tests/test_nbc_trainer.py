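"""Partial scores, odds ratios, splits, training and parameter recovery."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ehrisk import (build_cohort, compute_or, concept_report, extract_timelines,
                    partial_score, split_cohort, train_site_model)
from ehrisk.nbc_trainer import SiteModel

from conftest import RECOVERY_EFFECTS


class TestPartialScore:
    def test_equal_prevalence_scores_zero(self):
        # equal prevalence and equal margins: exactly zero for any k
        for k in (0.5, 1.0, 2.0):
            assert partial_score(10, 90, 10, 90, k) == pytest.approx(0.0)
        # unequal margins: the pseudocount shrinks both prevalences toward
        # 1/2 by different amounts, so the score only vanishes as k -> 0
        assert partial_score(10, 90, 100, 900, 1e-9) == pytest.approx(0.0, abs=1e-6)
        assert 0 < partial_score(10, 90, 100, 900, 1.0) < 0.1

    def test_hand_computed_value(self):
        # log((51/1002)/(11/1002)) = log(51/11)
        assert partial_score(50, 950, 10, 990, 1.0) == \
            pytest.approx(math.log(51 / 11))

    def test_zero_cell_stays_finite_and_protective(self):
        s = partial_score(0, 100, 50, 50, 1.0)
        assert np.isfinite(s) and s < 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            partial_score(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            partial_score(0, 0, 1, 1)
        with pytest.raises(ValueError):
            partial_score(1, 1, 1, 1, k=0.0)

    @settings(derandomize=True, max_examples=200)
    @given(a=st.integers(0, 500), b=st.integers(0, 500),
           c=st.integers(0, 500), d=st.integers(0, 500),
           k=st.floats(0.1, 5.0))
    def test_sign_law_and_monotonicity_in_a(self, a, b, c, d, k):
        if a + b == 0 or c + d == 0:
            return
        s = partial_score(a, b, c, d, k)
        p_case = (a + k) / (a + b + 2 * k)
        p_noncase = (c + k) / (c + d + 2 * k)
        assert (s > 0) == (p_case > p_noncase)
        # strictly increasing in a with b, c, d, k fixed
        assert partial_score(a + 1, b, c, d, k) > s


class TestComputeOr:
    def test_cross_product_by_hand(self):
        or_value, _ = compute_or(30, 70, 10, 90)
        assert or_value == pytest.approx((30 * 90) / (70 * 10))

    def test_symmetry_gives_unit_or_with_ci_straddling_one(self):
        or_value, (lo, hi) = compute_or(10, 10, 10, 10)
        assert or_value == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_zero_cell_haldane_anscombe(self):
        or_value, (lo, hi) = compute_or(5, 0, 10, 90)
        expected = (5.5 * 90.5) / (0.5 * 10.5)
        assert or_value == pytest.approx(expected)
        assert np.isfinite(lo) and np.isfinite(hi)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            compute_or(-1, 2, 3, 4)


class TestSplitCohort:
    def test_disjoint_exhaustive_half_split(self, small_cohort):
        cohort, _ = small_cohort
        train, val = split_cohort(cohort, 0.5, seed=3)
        ids_t = set(train.members["patient_id"])
        ids_v = set(val.members["patient_id"])
        assert not ids_t & ids_v
        assert ids_t | ids_v == set(cohort.members["patient_id"])
        assert abs(len(ids_t) - len(ids_v)) <= 1

    def test_same_seed_reproduces_split(self, small_cohort):
        cohort, _ = small_cohort
        t1, _ = split_cohort(cohort, 0.5, seed=42)
        t2, _ = split_cohort(cohort, 0.5, seed=42)
        assert list(t1.members["patient_id"]) == list(t2.members["patient_id"])

    def test_invalid_fraction(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError):
            split_cohort(cohort, 1.0, seed=0)

    def test_mean_training_case_fraction_unbiased_over_reseeds(self):
        """Over 200 reseeded unstratified splits of a 10%-case cohort the
        mean training case fraction matches 0.10 within 3 SE."""
        from ehrisk.cohort_builder import Cohort
        n, p = 600, 0.10
        rng = np.random.default_rng(5)
        labels = np.where(rng.permutation(n) < n * p, "case", "noncase")
        members = pd.DataFrame({
            "patient_id": [f"x{i:04d}" for i in range(n)],
            "label": labels,
            "index_date": pd.NaT, "birth_date": pd.Timestamp("1980-01-01"),
            "sex": "F", "race_ethnicity": "White",
        })
        cohort = Cohort(members, pd.DataFrame(columns=[
            "patient_id", "date", "domain", "code", "value_flag"]))
        fracs = []
        for seed in range(200):
            train, _ = split_cohort(cohort, 0.5, seed=seed)
            fracs.append((train.members["label"] == "case").mean())
        # hypergeometric sampling of n/2 from n with 10% cases
        se_one = math.sqrt(p * (1 - p) / (n / 2) * (n / 2) / (n - 1))
        assert abs(np.mean(fracs) - p) < 3 * se_one / math.sqrt(200)


def test_train_site_model_counts_and_sign_law(small_cohort):
    cohort, _ = small_cohort
    tl = extract_timelines(cohort)
    model, stats = train_site_model(tl, k=1.0, site_id="SM")
    assert (stats["a"] + stats["b"] == model.n_cases).all()
    assert (stats["c"] + stats["d"] == model.n_noncases).all()
    assert np.isfinite(stats["partial_score"]).all()
    sign_ok = (stats["partial_score"] > 0) == (stats["p_case"] > stats["p_noncase"])
    assert sign_ok.all()
    # near-universal concept scores ~0 (visit marker present for everyone)
    marker = stats.set_index("concept").loc["PX:99213", "partial_score"]
    assert abs(marker) < 0.05


def test_train_requires_both_classes(small_cohort):
    cohort, _ = small_cohort
    tl = extract_timelines(cohort)
    with pytest.raises(ValueError, match="case"):
        train_site_model(tl[tl["label"] == "noncase"])


def test_model_json_round_trip(tmp_path, small_cohort):
    cohort, _ = small_cohort
    model, _ = train_site_model(extract_timelines(cohort), site_id="SM")
    model.save(tmp_path / "m.json")
    back = SiteModel.load(tmp_path / "m.json")
    assert back.scores == model.scores
    assert (back.site_id, back.n_cases, back.n_noncases, back.k) == \
        ("SM", model.n_cases, model.n_noncases, 1.0)


def test_planted_log_or_recovered_within_25pct(recovery_replicates):
    """Across 20 replicates at n=50 000 the mean recovered OR for a
    strongly planted concept (log OR 2, baseline 0.05) is within +/-25%
    of exp(2), and its trained partial score is always positive."""
    target = math.exp(2.0)
    ors, scores = [], []
    for stats in recovery_replicates:
        row = stats.loc["DX:RISK_POS_2"]
        ors.append(row["or_value"])
        scores.append(row["partial_score"])
    assert all(s > 0 for s in scores)
    assert 0.75 * target < np.mean(ors) < 1.25 * target


def test_site_models_differ_on_differently_planted_concepts():
    """Two sites generated with opposite planted effects on the same
    concept produce oppositely signed partial scores."""
    from ehrisk import ConceptEffect, generate_site
    from ehrisk.synthetic_ehr import SiteSpec

    def trained_score(log_or, seed):
        cat = [ConceptEffect("DX", "SWING", 0.02, log_or)]
        spec = SiteSpec("W", 20_000, 0.03, concept_catalog=cat, seed=seed,
                        no_history_case_fraction=0.0)
        cohort, _ = build_cohort(*generate_site(spec))
        _, stats = train_site_model(extract_timelines(cohort))
        return stats.set_index("concept").loc["DX:SWING", "partial_score"]

    assert trained_score(1.5, 21) > 0 > trained_score(-1.5, 22)


def test_concept_report_filters_match_reporting_rules(small_cohort):
    cohort, _ = small_cohort
    _, stats = train_site_model(extract_timelines(cohort))
    report = concept_report(stats, min_total_patients=100, min_case_patients=10)
    assert ((report["a"] + report["c"]) >= 100).all()
    suppressed = report[report["a"] < 10]
    assert suppressed["or_value"].isna().all()
    kept = report[report["a"] >= 10]
    assert kept["or_value"].notna().all()
    # case-share percentage matches its definition
    row = report.iloc[0]
    assert row["case_pct"] == pytest.approx(
        round(100.0 * row["a"] / (row["a"] + row["c"]), 1))


def test_score_consistency_on_growing_samples():
    """As the site grows with fixed generating rates, the trained score
    approaches the log prevalence ratio implied by the planted effect."""
    from ehrisk import ConceptEffect, generate_site
    from ehrisk.synthetic_ehr import SiteSpec

    cat = [ConceptEffect("DX", "GROW", 0.03, 1.2)]
    estimates = []
    for n, seed in [(4_000, 31), (16_000, 31), (64_000, 31)]:
        spec = SiteSpec("G", n, 0.03, concept_catalog=cat, seed=seed,
                        no_history_case_fraction=0.0)
        cohort, _ = build_cohort(*generate_site(spec))
        _, stats = train_site_model(extract_timelines(cohort))
        row = stats.set_index("concept").loc["DX:GROW"]
        estimates.append((row["partial_score"], row["or_value"]))
    # largest sample closest to the planted log OR on the OR scale
    errs = [abs(math.log(orv) - 1.2) for _, orv in estimates]
    assert errs[-1] < 0.25
    assert errs[-1] <= errs[0] + 0.05
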