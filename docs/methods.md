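# Methods

## The inverse classifier

Guideline-recommended treatment for NSCLC is modeled as a decision function
from TNM (7th edition) stage to a treatment pattern; the classifier is its
inverse, restricted to the subdomain where the pattern determines the stage.
The seven invertible patterns and their stage pre-images are listed in the
README. Two deliberate restrictions keep the inverse single-valued: stage
IIA is ignored in the pre-image of the surgery-plus-adjuvant-chemo class
(class 2), and stage IIIA in the pre-image of the chemoradiation class
(class 6). Consequently the surgery-only class (class 1) aggregates stages
IA, IB and IIA, reported at fine resolution as the `I_IIA` label; classes
3, 4 and 5 all invert to IIIA.

Classification is a deterministic composition: coded events → treatment
courses → temporal pattern → class → stage. Patterns outside the table are
returned as `unclassified` with a rationale string; they are never coerced
into the nearest class. In particular, trimodality chemoradiation followed
by surgery stays unclassified even though it shares features with classes 5
and 6.

### Coarse projection of class 1

When a single coarse stage must be assigned to class 1 (for the 4×4
validation confusion matrix), stage I is used by default: stage I dominates
that class's pre-image in a screening-era referral population, and the
residual IIA patients then surface as imperfect stage-II sensitivity rather
than stage-I specificity. The choice is exposed as `class1_coarse` and can
be flipped to II.

## Course building and temporal windows

Claims data date each chemotherapy administration and radiotherapy fraction
but never label intent. The package therefore reconstructs intent from
timing, with every window configurable (`PatternConfig`):

- `course_gap_days = 30` — consecutive same-modality events merge into one
  course while gaps stay ≤ 30 days: one missed 3-weekly cycle still merges,
  a two-month gap starts a new course. Surgery dates are always their own
  single-day courses. Duplicate (date, modality) events count once.
- `neoadjuvant_window_days = 120` — chemo ending before the first surgery
  and starting within 120 days of it is neoadjuvant.
- `adjuvant_window_days = 180` — chemo/RT starting after the first surgery
  within 180 days is adjuvant.
- `concurrency_start_window_days = 30` — chemo and RT are concurrent when
  their course intervals overlap by ≥ 1 day *or* start within 30 days of
  each other; chemoradiation regimens start both modalities
  near-simultaneously but coding dates jitter.

The first surgery anchors all relations when several resections are coded.
Chemo or RT outside every window relative to surgery is *standalone* and
flows to the classifier as non-invertible. A modality whose courses fall in
conflicting windows (e.g. both neoadjuvant and adjuvant chemo) likewise
reduces to standalone: no invertible row fits such a patient, and collapsing
would fabricate one. Concurrent chemo + RT delivered entirely after surgery
is recorded as adjuvant chemo + adjuvant RT (start order decides class 3
vs 4), because the concurrent-chemoradiation class describes the
non-surgical pathway.

## Cohort selection

`EligibilityCriteria` applies, in a fixed order (chart-review record flags →
age 20–75 → comorbidity → washout → follow-up → treatment presence →
reference-stage availability), the filters of the two study designs, and
logs per-criterion attrition. Order affects per-step counts only, never the
final cohort, and each filter is idempotent. Two conventions were genuinely
open and are frozen as follows (both configurable):

- "last visit more than 180 days before the end of observation" is read as
  a strict inequality;
- the washout window is half-open, `(entry − washout_days, entry)`: a
  lung-cancer code exactly `washout_days` before entry does not exclude,
  mirroring a calendar-year washout (codes in 2002–2003 vs entry from 2004).

External-hospital transfer and erroneous-stage exclusions are manual-review
facts, carried as boolean record flags and honored when set — they cannot
be computed from codes.

## Validation metrics

The confusion matrix is 4×4 over coarse stages, reference in rows, inferred
in columns; unclassified patients are excluded from it and reported as a
separate count. One-vs-rest collapse gives TP/FP/FN/TN per stage, from
which sensitivity, specificity, PPV, NPV, F1 (harmonic mean of sensitivity
and PPV) and the c-statistic are computed. For a hard classifier no score
axis exists, so the c-statistic is defined as balanced accuracy,
(Se + Sp)/2 — equal to the trapezoidal area under the two-point ROC, an
identity the test suite asserts on random matrices. Any metric with a zero
denominator is reported as undefined; the others are still computed.

Confidence intervals are percentile bootstrap over patient-level resamples
with replacement (default B = 1000, seeded): the simplest reproducible
choice; bias-corrected variants would change intervals by less than their
own Monte-Carlo noise at these sample sizes. Resamples in which the target
metric is undefined are redrawn up to a cap, after which the CI is declared
undefined with a count. Reported values are rounded half away from zero (2
decimals for metrics, 1 for percentages) — the convention that makes
(0.99 + 0.94)/2 print as 0.97 — with full-precision values available from
the API.

## Survival analysis

Overall survival runs from diagnosis date to death, censored at the end of
observation. The Kaplan–Meier product-limit estimator is computed directly
with Greenwood variance, with deaths preceding censorings at tied times;
the 95 % CI is the plain-scale normal approximation S(t) ± 1.96·√var,
clipped to [0, 1]. The plain scale (rather than a log(−log) transform) is a
deliberate, configurable-in-principle choice matching how such intervals
are conventionally reported alongside risk tables; lifelines'
`KaplanMeierFitter` serves as an independent cross-check in the tests, not
as the implementation, precisely because it does not expose this interval.
Log-rank machinery is delegated to `lifelines.statistics`: the global
K-group chi-square (df = K − 1, hypergeometric tie handling) and all
pairwise tests, with Bonferroni applied as a threshold adjustment
(significance at α / n_pairs; decisions identical to p-value
multiplication). Curve evaluation at t is right-continuous; evaluation
beyond the last follow-up returns the last estimate flagged as
extrapolated, and classes followed for less than 5 years get their 5-year
comparison cells flagged unavailable.

The reference 2-/5-year survival probabilities per fine stage (IASLC
staging-project rates) ship as a small CSV; the comparison table reports,
per class, its KM 2-/5-year estimate with CI, the reference rate(s) of the
stage(s) it inverts to, and the signed difference where the mapping is
one-to-one (class 1 spans three stages and gets one row per stage, no
single difference).

The proportional-hazards model is intentionally absent: survival contrast
here is non-parametric by design, and a Cox fit is standard statistical
machinery orthogonal to the classifier.

## Synthetic cohort generator

The generator is the forward model of the same decision rules and exists so
every pipeline stage is testable without access-restricted hospital or
insurance data. Defaults encode the study conditions:

- **Stage mixture.** Coarse mix 68.6 / 8.9 / 7.9 / 14.5 % (I/II/III/IV),
  the validation-cohort distribution. Fine splits: stage I is IA:IB =
  60:40; coarse II defaults entirely to IIB — the invertible subdomain
  folds IIA into the surgery-only class, so the zero-IIA default represents
  the subdomain the classifier is defined on (a nonzero IIA share is one
  config key away and degrades stage-I/II metrics exactly as the aggregate
  pre-image predicts); coarse III splits IIIA:IIIB = 50:50 (no empirical
  split is published; even is the neutral choice). Stage IIIA patients draw
  their class from weights 1021 : 999 : 448 for classes 3 : 4 : 5, the
  observed class sizes in the application cohort.
- **Treatment sequences.** With probability `concordance` (default 1.0) the
  canonical sequence of the guideline class is emitted: surgery at day 14
  post-diagnosis; adjuvant chemo as 3-weekly cycles from day 30 post-op;
  adjuvant RT as a 30-day course; neoadjuvant chemo ending three weeks
  before resection; overlapping chemo and RT courses for chemoradiation;
  six cycles for chemo-only. Timings are stylized — real administration
  dates scatter — but they exercise every temporal window. Deviations
  follow `random_other_class` (a uniformly drawn other class's sequence;
  stresses the confusion matrix) or `unclassified` (RT-only, a
  non-invertible pattern; stresses exclusion accounting).
- **Survival.** Per fine stage, death times are Weibull with (shape, scale)
  solved in closed form so that S(2) and S(5) equal the reference rates
  exactly: k = ln(ln s₅ / ln s₂)/ln(5/2), λ = 2/(−ln s₂)^(1/k). A
  one-parameter exponential cannot hit both horizons, which is why the law
  is Weibull. Entry is uniform over a 5-year accrual window with
  administrative censoring at a 10-year horizon, so every patient has at
  least 5 years of potential follow-up and the 2-/5-year calibration is
  recoverable by KM.
- **Reproducibility.** One seed; each patient consumes an independent
  substream spawned from it, so cohorts are bit-reproducible and
  insensitive to generation order.

Treatment events are not truncated at death: the generator draws the
treatment schedule and the survival time independently, as if the recorded
regimen was completed. Survival is attached to the *true* stage, not the
emitted class, so under deviations the class-level curves show genuine
misclassification bias — a feature, since quantifying that bias is the
point of the validation machinery.

What passing tests on synthetic cohorts do **not** show: robustness to
coding practices that differ from the canonical timings (drifting cycle
intervals, split claims), to palliative radiotherapy mixed into advanced
disease, or to histology/genotype/performance-status effects on treatment
choice — none of which the generator models. Results on real claims depend
on the user-supplied code map and on local guideline adherence.

## Problem sizes in the shipped checks

The bundled end-to-end checks run at the sizes the analyses themselves use:
1375-patient validation cohorts, n = 5000 per stage for survival
calibration (±0.02 tolerance), 1000 null replications for log-rank type-I
error (0.05 ± 0.02), 1000 bootstrap resamples with 200-replication coverage
(95 % ± 5 points). The full suite completes in well under a minute of
compute per heavy check.
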