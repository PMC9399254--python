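# Methods

This note documents the statistical model behind `oatrisk`, the
assumptions baked into each pipeline stage, the synthetic-cohort
generator used for validation, and the design choices made where the
methodology was genuinely open.

## 1. Study design being implemented

The pipeline implements a retrospective open-cohort design for adults
(18–64 at cohort entry) prescribed opioid agonist treatment (OAT) in
primary care. A patient enters at the **index date** — the first
eligible methadone or buprenorphine prescription — and is followed until
the earliest of registration end, death, the global study end, a
modality switch, or an optional sensitivity censor. The outcome is
non-fatal overdose requiring hospital admission, allowing multiple
events per patient; a first-event (incidence) view supports hazard-ratio
analyses with censoring at the event.

## 2. Exposure model

OAT prescriptions are instalment scripts with a legal maximum supply;
exposure must be reconstructed from issue dates.

* Each script covers `[issue, issue + supply_days)` with
  `supply_days = 14` by default (7 as a sensitivity variant).
* If the next script is issued while supply is running ("overlapping and
  duplicated"), the expiry is extended. Two interpretations are
  implemented because the instalment wording admits both: **extend**
  (default; expiry = overlapping issue + `supply_days`, the more
  conservative, shorter exposure) and **stack** (a further full supply
  on top of the running expiry).
* If the gap between running expiry and the next issue is **strictly
  below** `max_gap_days = 14`, the episode continues and the gap is
  bridged as exposed time; a gap of exactly 14 days or more closes the
  episode at the running expiry. The boundary day is ambiguous in
  common prose descriptions ("less than 14" for continuity, "more than
  14" for discontinuation); we resolve exactly-14 as a discontinuation
  and expose the threshold in configuration.
* Patients receiving both drugs are censored at the issue date of the
  first script of the second drug, so each analysed patient has a single
  modality (needed for a baseline propensity model). Patients whose
  very first scripts of both drugs share a date have no assignable
  modality and are excluded with an audit reason.
* Analgesia formulations (buprenorphine patches, methadone linctus,
  sub-2 mg sublingual tablets) are removed before any of the above via a
  product-code exclusion list.

All intervals throughout the package are half-open `[start, end)` on a
whole-day grid; a year is 365.25 days, a month 30.44 days (used only for
episode-duration bands).

## 3. Risk windows and person-time

Each episode contributes `in_1_4` (its first 28 days, truncated at the
episode end) and `in_gt4` (the remainder, the reference stratum); each
cessation opens `out_1_4` (28 days, truncated at re-initiation) and
`out_gt4`. Windows restart at **every** transition, not only the first,
because repeated initiations and cessations are each hypothesised to
carry transition risk; a flag restricts to first-transition-only if
wanted. Day 28 belongs to the `>4 weeks` stratum (half-open
convention). Intervals tile `[index, observation end)` exactly — a
conservation invariant enforced by tests under every censoring variant.

Events are attributed to the unique interval containing their day.
Admission date (not discharge) dates an overdose, since discharge dates
are unreliable in admissions data. Several diagnosis codes on one
admission still count once; separate admissions on one day count
separately. Fatal overdoses censor follow-up (death) but are not
counted as non-fatal outcomes. In the first-event view, follow-up ends
at the end of the event day (`event day + 1`), so the event day itself
contributes person-time and no zero-length risk interval arises.

Age is handled as a time-fixed band at index (18–24, 25–34, 35–44,
45–64) in the default models; `add_age_bands` provides time-varying
banding with splits at band-crossing birthdays for analyses that need
it.

## 4. Weighting

Treatment assignment is modelled with a main-effects logistic regression
of methadone (vs buprenorphine) on baseline covariates: age band,
gender, IMD quintile, region, and whatever binary history flags the
patient table carries (overdose/self-harm history, co-prescriptions,
severe mental illness). Stabilised inverse-probability weights are
`P(T=t) / P(T=t|X)`; their cohort mean is ~1 by construction, a property
the tests check. Weight truncation (1st/99th percentile) exists as a
robustness flag but is off by default. Balance is reported as signed
standardised differences (methadone minus buprenorphine) for every
covariate indicator, unweighted and weighted; |ASD| < 0.1 is the
conventional balance criterion.

Complete separation (fitted scores at 0/1) raises an error suggesting
category collapsing rather than silently producing infinite weights.

## 5. Rate and hazard models

The unit of analysis is the patient × risk-interval record with a log
person-time offset, so exposure is time-varying; aggregation invariance
(re-chunking intervals changes nothing) is a tested identity.

* **uRR** — single-factor Poisson fits. With a saturated categorical
  exposure the Poisson MLE equals the crude stratum rate ratios exactly,
  so the "unadjusted" column is genuinely crude. (Closed-form identity,
  used as a test oracle.)
* **aRR / wRR** — a joint exposure model containing both time-varying
  factors (risk window × modality), plus the baseline covariates for
  aRR, plus stabilised weights for wRR. The joint model is deliberate:
  with 13-fold rate differences between windows, a single-factor
  negative-binomial model is inconsistent for the marginal contrast —
  the dispersion parameter absorbs the window heterogeneity and drags
  the estimate off the crude (person-time-weighted) estimand, which we
  verified numerically against the generator's ledger. Conditioning on
  both factors restores a correctly specified mean model, for which both
  Poisson and NB estimating equations are consistent.
* **Family** — Poisson by default; NB2 (variance `μ + αμ²`) when a
  likelihood-ratio test of `α = 0` vs `α > 0` rejects. Because the null
  lies on the boundary, the statistic is referred to a 50:50 mixture of
  a point mass at zero and χ²₁ (`p = ½·P(χ²₁ > LRT)`); the test's ~5%
  type-I error under Poisson data is verified by simulation. Unweighted
  NB fits are full ML (warm-started from the Poisson solution); weighted
  fits profile α over the weighted GLM likelihood.
* **Variance** — all interval-level fits report cluster-robust sandwich
  covariances by patient (records within a patient are correlated;
  model-based errors are invalid under weighting). The sandwich is
  assembled from per-record score contributions
  `w(y−μ)x/(1+αμ)` with expected-information bread and a G/(G−1)
  small-sample factor. When the NB Hessian is singular at the `α → 0`
  boundary, the profile information with fixed dispersion is used.
* **Hazard ratios** — first-event Cox proportional-hazards fits on the
  counting-process intervals (time scale: days since index; Breslow
  ties), with the same uHR/aHR/wHR structure. Weighted fits use a
  cluster-robust sandwich built from weighted Breslow score residuals
  with prefix-sum accumulation over distinct event times (the installed
  time-varying Cox fitter does not provide robust variances); it
  reproduces the standard robust Cox variance on non-time-varying data.

E-values use the standard risk-ratio-scale formula
`E = RR* + sqrt(RR*(RR*−1))` with protective ratios inverted first; the
CI E-value is computed on the limit nearer the null and equals 1 when
the interval crosses it. Rate ratios are assessed on the risk-ratio
scale directly, without rare-outcome conversion.

## 6. The synthetic-cohort generator

The generator emulates the joint structure the analysis assumes, with
every latent quantity recorded:

* **Prescription cascade.** Scripts per episode are geometric (mean 2.5)
  with a long-retention mixture component (mean 25 scripts, probability
  0.15), giving the empirically typical shape: most episodes shorter
  than a month, yet most in-treatment person-time inside long episodes.
  Within-episode issue gaps are uniform on 7–27 days, producing both
  overlapping scripts and bridged refill delays; out-of-treatment gaps
  are 14 + Exponential(250) days, so every break is a genuine
  discontinuation. 15% of patients switch modality once, at an episode
  start. Follow-up is uniform on 1–10 years, truncated by a staggered
  entry over a 20-year study window.
* **Confounded assignment.** Binary baseline covariates (default:
  overdose history 20%, benzodiazepine use 23%, severe mental illness
  12%) shift assignment towards methadone (log-odds −0.8/−0.4/−0.5 for
  buprenorphine) *and* raise the overdose hazard (log-rates
  0.7/0.4/0.5) — confounding by indication with a marginal
  buprenorphine share near 27%.
* **Events.** A Poisson process on the realised segment ledger with rate
  `baseline × window_rr[w] × modality_rr^{bup} × exp(Σγx)`; defaults
  `baseline = 0.08`/person-year, `window_rr = (5.5, 1, 13, 1.4)`,
  `modality_rr = 0.4`. Death (fatal poisoning proportional to the event
  hazard, plus a flat other-cause rate) censors follow-up. Non-outcome
  admissions (0.3/py, non-overdose codes) and occasional
  analgesia-formulation scripts exercise the filtering steps.
* **Ground truth.** The segment ledger (interval × window × modality ×
  hazard) makes expected counts per stratum exact analytic quantities,
  so recovery tests compare against truth, not against another
  simulation.

What the generator does **not** emulate: dosage and titration,
supervised consumption, treatment transfer between providers,
calendar-time trends, regional practice differences, coding error or
outcome misclassification, and covariate-by-treatment effect
modification. Passing recovery tests therefore show that the pipeline's
estimators are consistent and calibrated *under the stated model*; they
cannot show robustness to exposure misclassification or unmeasured
time-varying confounding in real records.

One known, deliberate mismatch: when death occurs inside a bridged
refill gap, the ledger counts up to 13 final days as in-treatment that
the rebuilt episodes classify as out-of-treatment (the script that would
have bridged them is never written). This affects only the last days of
death-censored patients (~0.02% of person-time) and is tolerated in the
ledger-comparison tests.

## 7. Validation problem sizes

The test suite validates parameter recovery with full pipeline runs on
two independent cohorts of 5,000 patients (a 95%-CI coverage check on a
single replicate fails ~5% of the time per parameter even for a
perfectly calibrated estimator, so each parameter must be covered in at
least one of the two runs, while the crude-bias check must hold in
both); the overdispersion test's size is checked over 200 Poisson
replicates of 400 records; Cox coverage over 40 replicates. The
acceptance script runs one 5,000-patient cohort plus three sensitivity
re-runs, completing in about a minute on one CPU.

## 8. Limitations

* The propensity model is main-effects only and baseline-only, matching
  the design it implements; time-varying confounding needs marginal
  structural models with time-updated weights, which are out of scope.
* Weighted NB dispersion is profiled, so CI widths ignore uncertainty in
  α (standard practice; the cluster sandwich largely absorbs this).
* The weighted Cox sandwich assumes Breslow tie handling and does not
  support stratified baselines.
* The crude-rate CI uses the log-normal approximation with
  `SE = sqrt(1/e₁ + 1/e₀)`, which is undefined when either cell has zero
  events (flagged, not imputed).
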