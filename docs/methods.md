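# Methods

## Problem and model

The package estimates, for a patient under nephrology follow-up, the
probability of end-stage kidney disease (ESKD, cause 1) and of death (cause
2) over a fixed horizon, updated as laboratory history accumulates. The
approach is landmarking: at each landmark time *s* (defaults 0.5–3.0 years
in half-year steps, matching the half-yearly review cycle of stable CKD
patients) a model is fitted to the risk set {patients with event time > *s*}
using covariates built only from data at or before *s*; outcomes are
restricted to (*s*, *s* + *w*] with *w* = 5 years and administrative
censoring at *s* + *w*. Internally each landmark model works on the residual
time *t* − *s*; predictions are mapped back to absolute time for display.

The per-landmark learner is a competing-risk random survival forest:
bootstrap trees (reference configuration: 1,000; the examples, tests and the
acceptance script use 20–200, chosen as scaled-down problem sizes), split
scores summing the squared standardised Gray statistics of the two causes,
Aalen–Johansen terminal-node CIFs, ensemble = arithmetic mean of
terminal-node CIFs over trees on a common time grid (distinct event times,
capped at 200 quantile-spaced points).

### Gray splitting score

For cause *k* the score is the subdistribution log-rank statistic on the
extended risk set: a subject whose competing event occurred before *t*
remains at risk at *t*; censored and cause-*k* subjects leave at their
observed time. At each distinct cause-*k* event time the observed-minus-
expected left-child event count and its hypergeometric variance are
accumulated; the standardised score is U/√V (0 when V = 0). With no
competing events this is exactly the two-sample log-rank statistic (tested
against lifelines). This extended-risk-set form is one documented reading of
"log-rank splitting based on Gray's test"; it is the one implemented here.

### Numerical and structural choices

- **Candidate splits**: up to `nsplit` = 10 random midpoints per candidate
  variable per node (exhaustive with `nsplit=None`, used by the oracle
  tests). Ties in the split score keep the first candidate in the seeded,
  shuffled variable order.
- **Admissibility**: each child must contain at least max(nodesize, 2)
  in-bag members — the Gray statistic needs two members per side, so
  nodesize = 1 behaves like nodesize = 2.
- **Missing covariates**: splits are evaluated on observed values; missing
  cases follow the majority direction of the node's in-bag cases, and each
  node stores that direction for prediction time (test-fold data are filled
  only by carry-forward, so missingness at prediction time is expected).
- **Tuning**: nodesize over the 28-value grid (1–10, then 15–100 by 5s);
  mtry stepwise from ⌈p/2⌉ with doubling/halving neighbours accepted while
  the out-of-bag error (mean over causes of 1 − concordance at the horizon)
  improves; forest seeds derived deterministically from (seed, nodesize,
  mtry) so repeated evaluations are reproducible. Concordance was chosen as
  the tuning error; Brier-based tuning can be substituted by the caller.
- **VIMP**: permutation importance per cause — permute a variable among each
  tree's out-of-bag cases, recompute the OOB error; a variable never used in
  any split has importance exactly zero.

## Cohort preparation

Raw long-format results are averaged into calendar-month (YYYY-MM) buckets,
then re-indexed as month number from time 0 (bucket mid-date offset divided
by 30.44 days, clipped at 0; colliding buckets are averaged again). Time 0
is the date of the first eGFR; the `sens` variant instead anchors on the
earliest eGFR within 10 years of the event or last test and censors at the
last test date. ESKD is adjudicated as the earlier of dialysis/transplant
start or the first monthly eGFR ≤ 15 mL/min/1.73m² never followed by any
eGFR > 17 (the recovery clause is used as the operational meaning of
"sustained"; no fixed-duration window is imposed). Threshold events are
timed at their month with a half-month floor so event times stay positive.
The ≥3-entries density filter counts monthly aggregates (it runs after
resampling); `acr3` additionally requires ≥3 urine albumin-creatinine
entries, with uPCR convertible through a user-supplied hook (no conversion
formula is built in; the hook raises if absent).

Baseline (month-0) imputation is a simplified predictive mean matching:
linear regression of each analyte on age, sex and baseline eGFR among
complete cases, one donor drawn from the k = 5 nearest predicted values
(k = 5 is the common default). It is applied to training folds only; test
folds are filled only by last-observation-carried-forward, mirroring
clinical use of prior results.

The biopsy-verified glomerulonephritis/vasculitis flag is three-level
(absent / verified / missing, encoded 0/1/2) because unverified diagnoses
are recorded as missing, and missingness itself is informative. Age enters
as initial age at presentation (fixed), not current age.

Covariate strategies at the landmark: LOCF (most recent monthly value ≤ s);
LME — per-analyte linear mixed model with random intercept and slope fitted
to all observations up to *s* of the fitting cohort (the training fold
inside cross-validation), predicting each patient at exactly *s* via fixed
effects plus the BLUP of the patient's random effects, computed from the
fitted variance components so it applies identically to patients outside
the fit; LMEpoly adds a fixed and random quadratic term. Non-convergence
falls back to LOCF for that analyte with a logged warning.

## Evaluation

All metrics are CIF-based and cause-specific; competing-event subjects count
as non-cases (controls). The C-index compares pairs (i, j) with i failing
from cause *k* at *t*ᵢ and *T*ⱼ > *t*ᵢ; prediction ties score ½. The
time-dependent AUC is the cumulative/dynamic variant at the horizon with
inverse-probability-of-censoring weights (the incident/dynamic variant was
the alternative; cumulative/dynamic matches horizon-type prediction). The
censoring Kaplan–Meier uses the censoring-after-events tie rule and is
estimated on the same landmark test set. The Brier score weights subjects
with an event by 1/Ĝ(T⁻), subjects at risk at *t* by 1/Ĝ(t), censored-by-*t*
subjects 0; the integrated score is the trapezoidal integral over residual
time from 0 to *w*, divided by *w*. Cross-validation is event-stratified
(round-robin within ESKD/death/censored strata); strategy and predictor-set
variants are compared on fold-level values by Kruskal–Wallis (≥3 variants)
or the exact rank-sum test (2).

## Synthetic cohort generator

No real cohort is distributed, and the data source this package emulates
publishes only descriptive statistics; every generative choice is therefore
a stand-in. The generator draws, per patient: initial age N(62, 16²) clipped
to [18, 95]; sex (45% female); a biopsy-verified GN/vasculitis flag (10%
verified, otherwise missing); linear mixed trajectories for 13 analytes
whose means and between-patient SDs are matched to the published medians and
IQRs of a dense CKD cohort (eGFR mean 50 mL/min/1.73m² with slope −2.5/year,
albumin 42 g/L, bicarbonate 23.5 mmol/L, …), with floors preventing
non-physiological values. Cause-specific hazards are log-linear in current
latent biomarkers, piecewise-constant on a monthly grid: the ESKD hazard
declines in eGFR (slope −0.13 per mL/min/1.73m²) and the death hazard rises
with age (0.07 per year); intercepts were calibrated once so the observed
margins match the published cohort (~25% ESKD, ~15% death, ~60% censored,
median follow-up ≈ 5–7 years). Event times are inversion-sampled per
interval; exponential dropout (rate 0.015/year) and staggered administrative
follow-up (uniform 2–16 years before a fixed extraction date) produce
censoring; 18% of analyte values are deleted completely at random (never the
entry eGFR — time 0 is defined by it). Visits follow a homogeneous Poisson
process (10/year) plus a guaranteed entry visit.

ESKD events surface downstream by two routes: half carry a recorded dialysis
start; the rest are made visible by clamping measured eGFR below the
threshold from the event time on, so threshold adjudication recovers the
hazard-based truth up to visit-schedule resolution. Ground truth returned
with every cohort includes the per-patient latent effects, the true
(pre-censoring) cause and time, and the marginal true CIF per cause —
computed by averaging each patient's exact conditional CIF (closed form
under piecewise-constant hazards), with Monte-Carlo standard errors.

Seeding uses one master seed with per-patient substreams, so enlarging the
cohort never reshuffles earlier patients; identical configuration and seed
reproduce the tables bit for bit.

What the generator does **not** emulate: inter-analyte correlation beyond the
shared dependence on latent eGFR, hospitalisation clustering of tests,
informative (outcome-dependent) visit schedules or missingness, measurement
batch effects, and secular trends. Tests passing on this cohort therefore
demonstrate correctness of the machinery and recoverability of planted
signal — not clinical performance on real data.

## Dynamic prediction

For a patient with history covering landmark *s*, each landmark model
contributes its residual-time CIF mapped to absolute time *s* + *t*; curves
are aggregated by the unweighted arithmetic mean (weighting by landmark
recency is available but off by default) on a 0.25-year grid from year 3 to
year 8. A model whose window ends before a grid time contributes its last
value (a CIF is constant beyond the last event time); grid times at a
model's own landmark contribute 0 — edge handling here is a package choice,
as is the grid step. The rolling window re-anchors a long history by
discarding the first `shift` years, advancing age accordingly and leaving
the adjudicated outcome on the absolute scale.

## Known limitations

- The Gray-splitting variant and the OOB "error rate" metric (concordance
  vs Brier) are each one documented interpretation among possible ones; both
  are isolated behind small functions and config.
- The LME strategy fits one population model per analyte per landmark;
  analytes with almost no longitudinal signal can fall back to LOCF, so
  LME and LOCF results converge on sparse data.
- Calendar-month resampling followed by month-index conversion can merge
  two calendar months into one index near time 0; values are averaged.
- The simplified predictive mean matching uses a fixed predictor set (age,
  sex, baseline eGFR) rather than chained equations.
- Problem sizes in tests and the acceptance script (cohorts of 120–2,000
  patients, 20–200 trees, 3–5 folds) are scaled-down study conditions chosen
  for desk-scale reproducibility; the reference configuration (1,000 trees,
  six landmarks, 5-fold CV) is exposed through the same interfaces.
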