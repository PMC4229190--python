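# artrisk

Risk scoring for HIV antiretroviral-therapy (ART) failure from
electronic-medical-record extracts, built for settings where viral-load
testing is scarce and clinicians must act on pharmacy refills, CD4 counts
and clinical staging. The package computes pharmacy-claims adherence
measures, ascertains treatment failure by WHO immunologic/clinical
criteria, derives and validates an additive clinical risk score, and
projects what capacity-constrained targeting of adherence support would
catch or miss. A synthetic EMR generator with known ground truth makes
every stage testable without patient data.

## The model

Five baseline adherence measures are computed over the first 6 months
(182 days) on ART: the medication possession ratio
`MPR = min(1, Σ days supplied / window days)`, the proportion of days
covered (PDC, supersession discards leftover stock, so PDC ≤ MPR), the
timely visit ratio (TVR, share of refill due dates met within a 2-day
grace), and two self-reported measures (mean visual-analogue-scale
adherence; proportion of visits reporting no missed doses).

Failure after month 6 is flagged when any WHO criterion fires: CD4 at or
below baseline; CD4 below half the post-ART peak; CD4 < 100 cells/µl; or a
new non-IRIS WHO stage IV diagnosis. The development pipeline screens the
measures by AUC, enriches the best one with patient characteristics by
forward-AIC selection on a random half-sample, dichotomizes retained
covariates at the decile where predicted risk jumps, and converts
coefficients to weights via round(10 × β). With the four canonical binary
factors the score is

```
score = 7.7·[PDC ≤ 0.80] + 9.6·[CD4 ≥ 250] + 8.9·[pre-ART ≤ 160 d] + 6.3·[male]
```

with range 0–32.5; tertiles of the derivation-score distribution define
low/medium/high risk groups, evaluated by screening-test characteristics,
capacity-constrained targeting projections, and 42-month Kaplan–Meier /
log-rank / Cox analyses on seven 183-day periods.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort of 2,500 patients (bulky intermediate tables land in `scratch/emr/`,
derived tables in `results/analysis/`):

```bash
python analysis/01_simulate.py
python analysis/02_clean.py
python analysis/03_adherence.py
python analysis/04_outcomes.py
python analysis/05_fit_risk_score.py
python analysis/06_evaluate_targeting.py
```

Highlights of one run (seed 20260926):

```
latent 12-month failure prevalence: 0.216 (configured 0.212)
  mpr: available 2500/2500, mean 0.880
  pdc: available 2500/2500, mean 0.831
  vas_mean: available 1453/2500 (41.9% missing), mean 0.897
12-month cohort flow: {... 'included': 775}
  failure prevalence among included: 0.194
42-month log-rank across risk groups: chi2 = 15.3, p = 4.67e-04
with capacity 500, targeting the high-risk group misses 15 failures
vs 96 under untargeted selection
```

Reading this: the generator hits its configured failure prevalence; the
pharmacy measures are nearly complete while ~40% of patients lack any
self-report; roughly a third of the registry qualifies for the 12-month
analysis; the fitted risk groups separate the 42-month failure curves; and
when only half the population can receive adherence support, targeting by
risk group misses far fewer eventual failures than untargeted selection.

The same stages are available as a CLI (`artrisk simulate|clean|adherence|
outcomes|fit|evaluate|run-all|validate`); `artrisk run-all --config c.yaml
--workdir out --seed 7` reproduces the pipeline byte-for-byte under a
fixed seed and writes a manifest.

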