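# oatrisk

Non-fatal overdose risk during and after opioid agonist treatment (OAT):
a tested, reusable analysis pipeline for pharmacoepidemiological cohorts
of methadone and buprenorphine recipients, built from primary-care
prescription records linked to coded hospital admissions and mortality
registrations.

People treated for opioid use disorder are at sharply elevated overdose
risk in the first weeks after starting OAT and — even more so — in the
first weeks after supply stops, and the two medications differ: the
partial agonist buprenorphine carries lower respiratory-depression risk
than the full agonist methadone. Quantifying these contrasts from routine
records requires a chain of non-trivial steps, each implemented and
tested here:

1. **Exposure reconstruction** (`oatrisk.episodes`) — each prescription
   is assumed to supply 14 days; scripts whose issue date falls within
   14 days of the running expiry continue the episode (overlapping
   scripts extend the expiry, instalment-style); a gap of 14 days or
   more opens an out-of-treatment period. Patients who switch modality
   are censored at the switch.
2. **Risk-window person-time** (`oatrisk.persontime`) — follow-up is
   tiled into half-open intervals labelled `in_1_4` (days 0–27 of each
   episode), `in_gt4` (reference), `out_1_4` (days 0–27 after each
   cessation) and `out_gt4`, with windows restarting at every
   transition.
3. **Outcome ascertainment** (`oatrisk.ascertain`) — configurable code
   lists (ICD-10, Read/SNOMED, product codes) classify admissions,
   deaths and history records; ICD-10 matching is prefix-based
   (`T40` captures `T40.1`), any diagnosis position by default.
4. **Confounding control** (`oatrisk.weighting`) — a main-effects
   logistic propensity model for methadone vs buprenorphine yields
   stabilised inverse-probability weights
   `sw = P(T=t) / P(T=t | X)`, with balance reported as standardised
   differences before and after weighting.
5. **Estimation** (`oatrisk.models`) — event rates per 100 person-years;
   unadjusted, adjusted and weighted rate ratios from Poisson or NB2
   negative-binomial models with a log person-time offset (the family is
   chosen by a boundary-corrected likelihood-ratio test of
   overdispersion); first-event hazard ratios from a Cox model on
   counting-process intervals. All weighted fits use a cluster-robust
   sandwich variance by patient.
6. **Bias analysis** (`oatrisk.evalue`) — E-values quantify how strong
   an unmeasured confounder would have to be, on the risk-ratio scale
   (`E = RR* + sqrt(RR*(RR*-1))`), to explain an observed association
   away.

Because the real linked cohorts are not public, the package ships a
first-class synthetic-cohort generator (`oatrisk.simulate`) whose event
process is a piecewise-constant-hazard Poisson process

```
rate = baseline_hazard × window_rr[w] × modality_rr^{buprenorphine} × exp(Σ γ_j x_j)
```

with confounding by indication (covariates that raise the overdose
hazard push assignment towards methadone) and an exact person-time
ledger as ground truth, so every stage is validated by parameter
recovery. See `docs/methods.md` for model details and design choices.

## Worked example

```
$ oatrisk simulate --n-patients 2000 --seed 42 --out demo/input
wrote 2000 patients to demo/input
$ oatrisk run-all --inputs demo/input --out demo/report
analysed 2000 patients; report in demo/report
```

`demo/report/crude_window_rates.csv` (rounded):

| window  | person-years | events | rate /100py | RR    | 95% CI        |
|---------|-------------:|-------:|------------:|------:|---------------|
| in_1_4  |        741.9 |    404 |        54.5 |  4.50 | 3.84–5.28     |
| in_gt4  |       2008.4 |    243 |        12.1 |  1.00 | (reference)   |
| out_1_4 |        864.0 |   1121 |       129.7 | 10.72 | 9.33–12.32    |
| out_gt4 |       6554.7 |    933 |        14.2 |  1.18 | 1.02–1.35     |

Overdose rates spike in the four weeks after initiation and, most of
all, in the four weeks after cessation — the pattern the pipeline is
built to expose. For the modality contrast
(`demo/report/rate_ratios.csv`), this cohort was simulated with a true
buprenorphine-vs-methadone rate ratio of 0.40 under confounding by
indication:

```
drug[buprenorphine]  uRR  0.341  (0.299-0.390)   <- crude: biased by indication
drug[buprenorphine]  aRR  0.410  (0.363-0.463)
drug[buprenorphine]  wRR  0.423  (0.347-0.516)   <- weighted: covers the truth 0.40
```

Weighting works because it balances the baseline covariates: the largest
absolute standardised difference across covariate indicators drops from
0.283 unweighted to 0.020 weighted (`demo/report/balance_asd.csv`).
The dispersion test in `demo/report/summary.json` chose the negative
binomial family (LRT statistic 10.8, p ≈ 0.0005, alpha ≈ 0.25).

E-values are available on any estimate:

```
$ oatrisk evalue 0.39 0.38 0.41
{"rr": 0.39, "e_value": 4.567, "e_value_ci": 4.312}
```

i.e. an unmeasured confounder would need a >4.5-fold association with
both modality and overdose to fully explain a weighted rate ratio of
0.39 — comfortably beyond a two-fold confounder.

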