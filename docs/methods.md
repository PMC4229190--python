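# Methods

`artrisk` implements an end-to-end pipeline for predicting antiretroviral
therapy (ART) failure from EMR-style pharmacy, laboratory and encounter
tables: pharmacy-refill adherence measures, WHO immunologic/clinical failure
ascertainment, a derivation/validation risk score, and
capacity-constrained targeting projections. Because no patient-level data
are distributed, the pipeline is exercised on a synthetic EMR generator
with known ground truth; every claim the tests make is about quantities the
package itself computes.

## Adherence measures

All five measures are computed over a fixed 182-day baseline window that
starts on (and includes) the ART start date, i.e. day offsets 0..181. The
initiation dispense therefore counts; a convention this package fixes
explicitly since the first pickup typically happens on the start date.

For a multi-drug regimen the days supplied of a dispense is the minimum
over its drugs ("the regimen runs out when the first drug runs out"); if
any per-drug quantity is unknown the regimen quantity is unknown, because a
minimum over a set with an unknown member is unknown.

* **MPR** = min(1, total days supplied by in-window dispenses / effective
  window days). Supply is credited in full even when it extends past the
  window end, the usual claims-data convention; truncation at 100% bounds
  the effect. The denominator is the full window — days before the first
  dispense are *not* excluded (declared convention).
* **PDC**: each dispense covers `[date, date + days)` truncated at the next
  dispense (supersession discards leftover stock) and at the window end;
  PDC = covered days / effective window days. PDC ≤ MPR always.
* **Missing-quantity exclusion**: the interval from a missing-quantity
  dispense to the next dispense (or window end) is removed from both the
  numerator and the denominator of MPR and PDC — it is the interval the
  unknown supply would have covered.
* **TVR**: every known-supply dispense generates a refill due date
  (dispense date + days supplied). Due dates inside the window are
  opportunities; an opportunity is timely if any later pickup occurs no
  more than 2 days after it (early pickups are timely). Due dates past the
  window end are not judged, so censored observation is not penalized.
* **VAS mean** (0–1) and **%NoMD** are means over in-window self-report
  assessments; both are missing when no assessment exists.

A brute-force per-day boolean grid re-implements MPR/PDC in the test suite
and is checked against the interval arithmetic on thousands of random
histories.

**A note on monotonicity.** "Removing a dispense can only lower PDC" holds
only for known-quantity histories without stockpiling. Under supersession a
short early refill *truncates* a longer supply, so deleting it can raise
coverage; and deleting a missing-quantity dispense reshapes the excluded
interval. The property tests run on the domain where the property is true,
and a dedicated test documents the counterexample.

## Failure ascertainment

Baseline CD4 is the result closest in time to ART start within −180..+7
days (ties go to the pre-ART side). Failure in an outcome window (days
183–365 for the 12-month analysis, 183–1281 for the 42-month analysis) is
the earliest date at which any criterion fires:

1. CD4 falls to the baseline level or below (≤, reading "to the baseline
   level or below" inclusively);
2. CD4 falls below 50% of the post-ART peak, the peak being taken over
   post-ART results strictly preceding the evaluated result — the first
   follow-up cannot fire this criterion;
3. CD4 < 100 cells/µl. By default a single qualifying result suffices;
   `persistent_requires_two=True` demands two consecutive sub-100 results,
   exposing the ambiguity in "persistent";
4. a new WHO stage IV diagnosis in the window not attributed to immune
   reconstitution syndrome (the generator emits the IRIS flag explicitly;
   real-world IRIS adjudication is out of scope).

The 12-month cohort requires ≥182 days of potential follow-up, a baseline
CD4 (waived in sensitivity mode, where criterion 1 is skipped) and ≥1 CD4
at 182–365 days. The survival dataset requires ≥365 days of follow-up and
divides time into seven 183-day periods (7 × 183 = 1281 days ≈ 42 months;
integer-day arithmetic). Patients are censored at the last fully observed
period or at loss to follow-up — 180 days with no clinical encounter, dated
as last encounter + 180 — whichever is earlier. Exclusion flows are
reported and conserve counts by construction.

## Risk-score development

1. **Screening**: each adherence measure enters a univariate logistic model
   (complete case); measures are ranked by AUC with a DeLong-variance CI
   (hand-implemented; no installed package provides it).
2. **Enrichment**: the cohort is split 50:50 (unstratified, seeded);
   forward stepwise selection on AIC runs in the derivation half with the
   winning measure forced in. Categorical covariates enter as whole dummy
   blocks with an explicit missing-data category.
3. **Dichotomization**: retained continuous covariates are cut into
   deciles; the threshold is the boundary with the largest jump in observed
   failure proportion, oriented toward the side with higher risk. With
   fewer than 10 distinct values the bins fall back to distinct values
   (logged).
4. **Score**: weights are round(10 × coefficient) to one decimal (half away
   from zero) from the all-binary logistic model; the intercept is
   discarded. Indicators that do not vary in the derivation half are
   dropped (logged) rather than allowed to make the design singular.
   Missing indicator inputs count as risk-factor-absent.
5. **Groups**: tertile cuts of the derivation-score distribution; ties at a
   cut go to the lower group; validation patients are classified with the
   derivation cuts. Calibration is checked with the Hosmer–Lemeshow test
   (g = 10 predicted-risk groups, χ² with g−2 df, empty or degenerate
   groups merged into a neighbour). The g−2 reference distribution is the
   one derived for fitted model probabilities, and that is the setting in
   which the type-I-error simulation runs.

## Targeting evaluation

Treating a risk-group cut-off as a screening test gives sensitivity,
specificity, PPV, NPV (reported as undefined when there are no
test-negatives) and accuracy. Projection onto a hypothetical population of
1,000 at the observed prevalence: without constraints, expected failures
among targeted = round(sens × F) and false positives = round((1−spec) × NF);
with capacity C, targeted = C and failures among targeted = round(PPV × C),
since the targeted are drawn from the test-positives. Rounding is half away
from zero; an exact .5 product is flagged and both conventions reported
rather than silently picking one.

Survival by risk group uses discrete-period Kaplan–Meier curves (lifelines;
log(−log) confidence intervals, bounded in [0, 1]), the log-rank test across
groups, and per-measure Cox screening of z-scored adherence measures
(complete case per measure; zero-variance measures skipped; the winner is
the largest |coefficient|).

## Synthetic EMR generator

Each patient carries a latent adherence propensity (clipped normal, default
mean 0.80, sd 0.16). Twelve-month failure follows a logistic model on four
binary factors — low latent adherence (propensity < 0.80), baseline
CD4 ≥ 250, pre-ART enrollment ≤ 160 days, male sex — with default log-odds
ln(2.16), ln(2.60), ln(2.43), ln(1.87) and the intercept calibrated by root
finding so the population prevalence hits the configured 21.2%. Later
failures occur among the remainder with probability increasing in the same
linear predictor, which is what separates the long-horizon survival curves.

Observable data are drawn conditional on this latent state:

* **Dispensing**: days supplied from a discretized gamma matched to mean
  40.8 and IQR 32–50 (shape solved numerically). Refills are mostly on time
  within a ±2-day jitter; with probability ~1.4 × (1−propensity) a pickup
  is delayed by a gamma-distributed treatment gap whose mean also grows as
  propensity falls. A propensity-1.0 patient is gap-free (PDC exactly 1).
  About 2% of dispenses lose one drug's quantity, independent of
  propensity (a data-quality artifact, not a behaviour).
* **CD4**: non-failures follow a saturating recovery (+180 cells at
  plateau, time constant 240 days); failures begin a decline 120 days
  before the latent failure day, crossing baseline near it and reaching
  ~45% of baseline; measurement noise sd 30, scheduled samples roughly
  every 6 months with dropout-truncation and a configurable missingness
  flag for the 6–12-month result. The CD4 noise model is a free choice of
  the generator and is documented here rather than claimed from data.
* **Self-report**: whether a patient ever provides assessments follows a
  logistic model in (1−propensity) calibrated to the configured 40.4%
  marginal missingness, so poor adherers are the ones lacking self-report.
  VAS values are compressed toward high scores (83 + 10 × propensity,
  sd 12), emulating social-desirability bias: self-report carries little
  discriminating signal by design.
* **Mess**: ~1% enrollment-after-ART conflicts, ~0.5% visits before
  registration, ~0.5% ×10 weight and cm-for-m height entry errors, 10%/5%
  missing birth day / birth month+day — exercising every cleaning rule.

What the generator does **not** emulate: facility stock-outs, transfers,
drug resistance, mortality as a competing risk, or correlated within-site
effects. Passing tests therefore demonstrate the machinery is correct and
calibrated under these conditions, not that the published effect sizes
would re-emerge from real iSanté-like data.

**Attenuation is expected and realistic.** The planted odds ratios apply to
the *latent* indicators. In the analyzed cohort the measured-PDC indicator
is a misclassified proxy and inclusion (baseline CD4 present, follow-up CD4
present, no early dropout) selectively removes poor adherers, so
cohort-level adherence ORs and AUCs sit well below the latent values. The
parameter-recovery tests fit the latent model on ground truth, where
coverage is nominal; the pipeline-level tests assert direction (risk-group
separation, pharmacy measures beating self-report), not effect magnitude.

## Numerical and design choices

* 6-month window fixed at 182 days; periods at 183 days; both integer-day.
* Cleaning rules are declared substitutes (registration → earliest event;
  enrollment after ART start → enrollment := ART start; weight ∈ [25, 250]
  kg, height ∈ [1.20, 2.20] m; missing birth day → 15th, missing month+day
  → July 1) — deterministic, order-independent, idempotent, and counted in
  a report.
* Logistic fits use statsmodels maximum likelihood; non-convergence,
  perfect separation and |coef| > 15 raise an explicit diagnostic, and
  stepwise candidates that fail are skipped.
* One global seed fans out to per-stage seeds through `SeedSequence`, so
  stages can be rerun in isolation and end-to-end runs are byte-identical.
* Problem sizes in the test suite (cohorts of 1,200–5,000; 200 replicates
  for CI coverage; 1,000 replicates for type-I error; 50 for stepwise
  recovery) were chosen as the smallest sizes at which the Monte-Carlo
  bands are meaningfully tight.

## Known limitations

* The binary-factor latent model caps the achievable AUC of any single
  adherence measure near 0.57; published single-measure AUCs of ~0.6 are a
  calibration reference, not a reproduction target.
* Which pharmacy measure (MPR/PDC/TVR) tops the screening table varies by
  seed — all three read the same latent trait — so only "a pharmacy measure
  wins" is a stable property.
* Tertile cuts on a discrete score can collapse groups when the score takes
  few values; the code warns and downstream evaluation reports degenerate
  strategies as undefined rather than failing.
* Viral-load outcomes, live-EMR alert integration and chart-review
  concordance are out of scope.
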