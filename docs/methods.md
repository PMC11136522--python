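# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical conventions, and the design choices made where
the underlying modeling approach leaves room — in the spirit of a model
documentation page rather than a results report. No empirical claim is
made here that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. The risk model

### Partial risk scores

For each concept *c* observed in the training split, with 2×2 counts
(a = cases carrying *c*, b = cases without, c₀ = noncases carrying,
d = noncases without), the partial risk score is

    s(c) = ln( (a + k) / (a + b + 2k) ) − ln( (c₀ + k) / (c₀ + d + 2k) )

— the natural-log ratio of additively smoothed concept prevalence among
cases vs noncases. Positive scores are adverse, negative protective.
This is the per-feature log likelihood-ratio contribution of a
presence-only naive-Bayes classifier.

Two conventions deserve note:

* **Smoothing** (k, default 1, configurable). The pseudocount keeps
  every score finite, including concepts seen in only one class. A side
  effect: with unequal class sizes, equal *raw* prevalences do not give
  exactly zero — the pseudocount shrinks the smaller class harder. The
  score vanishes exactly at equal smoothed prevalence, which is also the
  sign law the tests assert: s > 0 ⇔ smoothed case prevalence >
  smoothed noncase prevalence.
* **Log base.** Natural log. The base rescales all scores and all
  thresholds identically, so quantile-derived alerts, crossings, AUC and
  every reported metric are invariant to it; it is recorded in the model
  file metadata.
* **Absent features contribute nothing.** The score of a patient is the
  sum over *recorded* first occurrences only; the absence-likelihood
  term of a complete naive-Bayes model is deliberately omitted, because
  the longitudinal cumulative score must be computable prospectively at
  each date from what has been recorded so far.

### Cumulative trajectories and alerting

Each patient's features (first occurrences, in chronological order) are
summed into a cumulative score trajectory. Conventions:

* Features sharing a date are summed in stable input order, but only the
  cumulative value at the *end* of each date is meaningful; the
  trajectory maximum and threshold crossings are evaluated on these
  date-level totals. (Within-date transients depend on arbitrary
  within-date event order, which extracts do not define.)
* The patient-level summary is the trajectory maximum; a patient with no
  scored features has maximal score 0.
* An alert threshold is the empirical type-1 (inclusive) q-quantile of
  the *training* noncases' maximal scores: the smallest observed score
  with at least a fraction q of scores at or below it. A patient alerts
  when their cumulative score *strictly exceeds* the threshold, so the
  realized training specificity is ≥ q by construction. Thresholds are
  taken from the training split — deriving them from validation noncases
  would leak the evaluation set into the alert rule.
* Timeliness (lead time) is the interval from a case's first crossing to
  its index date, in years of 365.25 days, averaged over detected cases,
  with a normal-approximation CI (mean ± 1.96·sd/√n; undefined at n = 1).
  A trajectory that later dips below the threshold keeps its first
  crossing.

### Evaluation

* AUC is the Mann–Whitney probability P(case score > noncase score) +
  ½P(tie), computed from midranks; its SE uses the Hanley–McNeil (1982)
  formula. An O(n²) pairwise oracle and an independent library
  implementation cross-check it in the tests.
* PPV and NPV are reported at the validation split's natural prevalence.
* The decile table cuts the validation scores at the 10%…90% quantiles
  of the validation *noncase* maximal scores, so absent any signal each
  decile holds ~10% of noncases; case concentration in the top decile
  measures discrimination in a threshold-free way.

### Federation

Sites run sequentially and independently; only aggregate objects (model
coefficients, per-concept 2×2 summaries and ORs, performance metrics)
leave a site, and with `privacy_mode` on no patient identifier appears
in any output. Cross-site summaries are *unweighted* arithmetic means
and min–max ranges over sites — each health system is one replicate of
the modeling process, regardless of its size. Concept carrier counts are
pooled by summation over all sites reporting the concept, and the
case-share percentage is 100·cases/(cases+noncases) among pooled
carriers. Per-concept ORs use the cross-product (a·d)/(b·c₀) with a
Haldane–Anscombe 0.5 correction on all cells when any cell is zero, and
Wald 95% CIs on the log scale. The Table-style concept report keeps
concepts carried by ≥ 100 patients and suppresses ORs estimated from
< 10 case carriers.

## 2. The synthetic EHR generator

The generator emulates flat i2b2-style extracts from a heterogeneous
multi-site network; it exists so that every pipeline branch (censoring,
exclusion, lab flags, thresholds, federation) is exercised by data whose
ground truth is known.

Per site (all parameters per `SiteSpec`):

* **Calendar & follow-up.** The site has a fixed calendar span (default
  ends 2015-01-01, the ICD-9 era; spans of 8–17 years across the default
  five-site network). Each patient gets an observation window starting
  uniformly in the span with exponentially distributed length (mean 0.35
  of the span, truncated), reproducing the right-skewed follow-up
  durations of real systems.
* **Visits.** A homogeneous Poisson process within the window (default
  4–5.5 visits/patient-year across sites). Every visit carries a generic
  evaluation-and-management procedure code (99213), as encounters in
  billing extracts do; this grounds the downstream visit proxy (distinct
  event dates) in the visit process. Within each visit every catalog
  concept is emitted independently.
* **Demographics.** Sex and race/ethnicity are drawn from site-specific
  category mixes (the default network's mixes differ strongly by site);
  ages are drawn so most patients fall within 10–90 years, with a small
  configurable tail outside to exercise the age filter. Demographic
  attributes live in the patient table; feature extraction converts them
  to DEM concepts dated at the first event, giving them a defined place
  at the start of the cumulative sum. (They are not duplicated as DEM
  rows in the event file.)
* **Cases.** A Bernoulli(case_fraction) label per patient (0.34%–1.68%
  across the default network). Each case receives one case-defining
  ICD-9 code (drawn from the E95*/965*/967*/969*/881* families) at an
  index date uniform in the last 60% of its window, so most cases have
  pre-index history; a configurable fraction of cases (default 20%,
  roughly the exclusion rate a real network reports) have their
  pre-index visits removed entirely, exercising the
  no-pre-index-data exclusion. Generated histories are *complete* —
  post-index events are emitted — so that censoring is observable work
  done by the cohort builder, not an artifact of generation.
* **Planted effects.** `ConceptEffect.log_or` is defined on the scale
  the pipeline estimates: the patient-level first-occurrence odds ratio.
  Noncases emit per visit at `baseline_rate`; the realized presence
  probability π₀ among inclusion-eligible noncases is measured, and each
  case with pre-index history carries the concept with probability
  π₁ = expit(logit(π₀) + log_or), placed at a uniformly chosen pre-index
  visit when not already emitted. Without this calibration, the shorter
  censored records of cases attenuate the recovered OR by roughly the
  ratio of case to noncase visit counts (~30% here), and planted and
  recovered effects could not be compared directly. Negative log-ORs
  thin case emissions symmetrically.
* **Determinism.** Generation is a pure function of the spec (including
  its seed); identical specs yield byte-identical extract files.

What the generator does **not** emulate: disease co-occurrence and
comorbidity structure, coding-intensity drift over calendar time,
dose/duration of medications, continuous lab values, repeat suicidal
episodes, ICD-10. Consequently, passing tests demonstrate that the
*pipeline* is correct (censoring sound, thresholds calibrated, effects
recoverable, aggregation exact) — not that the model attains any
particular performance on real clinical data. Discrimination on the
default synthetic network (AUC ≈ 0.9) is substantially higher than the
0.71–0.76 reported on real multi-site data, because the default catalog
holds ~20 concepts that are mostly strong true risk factors, whereas
real EHRs contribute ~30 000 mostly uninformative features.

## 3. Cohort construction conventions

* **Visit proxy.** The flat extract has no encounter table, so a "visit"
  is a distinct calendar date with ≥ 1 event — the only date-level proxy
  available. Whether the original multi-site study counted encounters or
  dates is unknowable from the outside; the proxy is recorded here.
* **Order of operations.** Inclusion (≥ 3 visits, ≥ 30-day span, age
  window) is evaluated on the full uncensored record; censoring and the
  no-pre-index-data exclusion happen afterwards as a separate step, and
  the exclusion ledger conserves counts exactly (every input patient is
  a member or tallied under exactly one reason).
* **Strict censoring.** Events *on* the index date are censored
  ("up to but not including" the first suicidal event); a case whose
  only events share the index date is excluded.
* **Age rule.** At least one event after age `min_age` (10) and at least
  one before age `max_age` (90), ages in 365.25-day years.

## 4. Problem sizes in the test and acceptance suites

The statistical suites use sizes chosen to make their Monte-Carlo error
small relative to the asserted effect while running on a single CPU:
specificity calibration uses three replicate 55 000-patient sites
(≥ 20 000 validation noncases each, seeds 0–2); planted-effect sign
recovery uses 20 replicates of 50 000 patients; the arithmetic,
oracle-equivalence and conservation checks are exact and run at small n.
The calibration test compares the replicate-averaged realized validation
specificity to the nominal level using the two-stage binomial variance
q(1−q)(1/n_val + 1/n_train), since the threshold itself is an empirical
quantile of a finite training sample; with an equal split, ignoring the
training-side term would understate the null standard deviation by a
factor √2 and reject a correct implementation ~17% of the time per
level. `scripts/acceptance.py` generates 20 000 patients per site
(five planted sites plus one null site) and seeds every random draw from
`--seed`.

## 5. Known limitations

* The smoothing scheme and log base of the original modeling code are
  not published; both are configuration knobs recorded in the model
  metadata, and neither affects rank-based metrics.
* The split is simple random at patient level (unstratified); at very
  low prevalence and small n a training split can lack cases entirely,
  which the trainer reports as an error rather than silently proceeding.
* Lead-time summaries at different specificity levels average different
  detected subsets; they are reported per level, not as a matched
  comparison.
* The CLI's stagewise commands (`build-cohort`, `train`, `score`) exist
  for inspection and debugging; `evaluate`/`federate` rerun the pipeline
  from the extracts to guarantee split/threshold consistency.
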