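# Methods

## Decision problem

A cohort of adults (start age 60, 79.6% male) presents at haematuria
clinics; a fraction *p* (base case 12.95%, pooled as 871/6728 over three
clinic series) has urothelial bladder cancer. Two diagnostic strategies are
compared from a provider perspective:

* **Cystoscopy for all** — flexible cystoscopy (sensitivity 0.980 = 145/148,
  specificity 0.938 = 562/599); positives receive a diagnostic TURBT.
* **Biomarker triage** — a urine test (sensitivity 0.905 = 57/63,
  specificity 0.795 = 31/39) given to everyone; only test-positives are
  referred for cystoscopy, and TURBT requires both tests positive.

The triage rule assumes the two tests are conditionally independent given
disease status (no correlation data exist) and series positivity, so the
pathway's sensitivity is `se_d·se_c = 0.887` and its false-positive rate
`(1−sp_d)(1−sp_c) = 0.0127`.

## Cohort model

States: Well; five diagnosed cancer states — low-risk (LR) NMIBC, high-risk
(HR) NMIBC on BCG, HR NMIBC post-cystectomy, MIBC post-cystectomy,
metastasis; five undiagnosed mirrors; and two absorbing dead states
(disease-related, other-cause). Cycle length 0.5 years, horizon 5 years
(10 cycles).

Newly diagnosed patients are allocated LR : HR-BCG : HR-cystectomy : MIBC :
metastasis = 105 : 47 : 13 : 14 : 13 (of 192). Six-month transition
probabilities: LR recurrence 0.0638, HR recurrence 0.1393 (9/52 of
recurrences convert to cystectomy), HR-BCG progression 0.030 to MIBC and
0.010 to metastasis, post-cystectomy progression to metastasis 0.030,
MIBC progression 0.0771 (0.0060 beyond five years from entry — inert at
the default horizon), disease-specific death 0.0048 (NMIBC and
post-cystectomy states), 0.0497 (MIBC; 0.0327 late), 0.236 (metastasis).
Procedure mortality: TURBT 0.008 at every TURBT including the diagnostic
one, cystectomy 96/4484.

**Within-cycle ordering.** Disease-specific branch probabilities are
applied first, exactly as printed; all-cause mortality (from the life
table, at the cohort's current age) then removes a fraction of the residual
*stay* probability only. Rows are never rescaled; a draw that makes a
row's exits exceed one raises an error (and is redrawn in the PSA, with the
count logged). This preserves every printed probability at the cost of
slightly undercounting other-cause deaths among patients who transition —
negligible at six-month scale.

**False-negative track.** Undiagnosed patients progress and die at
RR = 2.56 times the treated rates (RR applied to progression to MIBC,
progression to metastasis, and disease mortality; draws below 1 are floored
at 1 — untreated disease cannot do better than treated). All undiagnosed
NMIBC states share the pooled NMIBC progression rates (2.56 × 0.030 to
MIBC, 2.56 × 0.010 to metastasis): the LR/HR distinction encodes treatment
intensity, which undiagnosed patients do not receive, and an undiagnosed-LR
state that could never progress would contradict the model's premise that
missed cancers are at increased risk of MIBC and metastasis. Detection
follows the staged schedule — per-cycle probability `1−√0.5 = 0.29289` in
cycles 1–4 (cumulative 50% by year 1, 75% by year 2) and 1 from cycle 5 —
and moves the patient to the diagnosed counterpart state via a TURBT plus
that state's entry treatment (cystectomy, chemotherapy, BCG, palliative
care as appropriate).

## Costs (GBP, 2014)

Cystectomy £9,816; TURBT £2,435; flexible cystoscopy £537; CT £395; BCG
£71.61/vial (6 vials per cycle for cycles 1–6, i.e. 3 vials every 3 months
for 3 years); cisplatin £50.22/vial, 3 vials per chemotherapy course;
palliative care £160.46 (same-day tariff). Surveillance mapped to cycles:
LR — 1 cystoscopy in cycle 1 then 0.5/cycle; HR-BCG — 2/cycle in years
1–2, 1.5/cycle in year 3, 0.5/cycle after, plus 0.5 CT urograms/cycle;
post-cystectomy states — 1.5 CT/cycle in year 1, 1/cycle in years 2–3,
0.5/cycle after. Metastatic patients responsive to chemotherapy (42.5%)
receive one 3-vial course per cycle. All schedule-to-cycle roundings are
module-level constants.

**Palliative care** is charged once, on entry to metastasis, at the
same-day tariff. The alternative reading — tariff × 135 days (≈ £21,700
per patient) — is available via `palliative_per_day: true`; it was not made
the default because it inflates the cystoscopy-arm 5-year cost to ~£2,450,
out of keeping with the rest of the cost structure and with the published
base-case total this package reproduces.

## Utilities

Well = 1. Patients living with bladder cancer (diagnosed LR and HR-BCG,
and all undiagnosed states) = 0.78. No standing utility is published for
the diagnosed NMIBC states; 0.78 — the same value assumed for undetected
disease — is the only choice we found consistent with the published
QALY-vs-LYG gap (~0.124 discounted QALYs per patient), and it treats
living-with-cancer utility as a property of the disease, not of detection.
Post-cystectomy = 0.96, multiplied by 0.91 for the impotent fraction
(0.59), both permanent and combined multiplicatively. Metastasis is the
response-weighted mixture 0.425 × 0.62 + 0.575 × 0.30.

One-off decrements (duration-weighted): TURBT −0.1 over 7 days; BCG
induction −0.02 over 6 weeks plus a complication (probability 0.286) of
−0.2 over 6 months; cystectomy recovery at utility 0.8 for 60 days plus a
short-term complication (0.267) of −0.3 over 60 days; chemotherapy −0.36
over 103 days. Each cystoscopy multiplies that cycle's utility by 0.997
(a loss of 0.0015 QALYs — about half a day of full health — covering the
procedure and the anxiety around it).

## Accumulation

Half-cycle correction averages start- and end-of-cycle occupancy for
state-based rewards; event-based rewards use the transition flows of the
cycle. Costs and QALYs are discounted at 3.5%/year at the cycle midpoint,
consistent with the occupancy averaging; time-zero testing and initial
treatment effects are undiscounted. Life years are discounted alive-time.

## Life table

A synthetic stand-in (no national-statistics data ship with the package):
sex-specific Gompertz hazards `h(a) = A·exp(B(a−60))` with A = 0.0088 (men)
/ 0.0056 (women) per year and B ≈ 0.094/0.099, mixed at the cohort male
fraction 0.796, giving a six-month death probability of 0.0042 at age 60 —
UK-plausible for 2014. The mixture weight is fixed over the horizon
(differential survival by sex is negligible over 5 years).

## Probabilistic sensitivity analysis

Sampled distributions, fitted so each mean equals its base-case value:

* binomial-count parameters (test accuracies, prevalence, TURBT and
  cystectomy mortality, recurrence-to-cystectomy): Beta(successes,
  failures) — no pseudo-counts, so the mean is exactly k/n;
* the diagnosis split: Dirichlet(105, 47, 13, 14, 13);
* recurrence probabilities: Beta by method of moments with SE recovered
  from the printed 95% CI as (U−L)/(2×1.96);
* progression/disease-mortality probabilities (printed six-month values
  derived from source event counts by an unstated time conversion): Beta
  by moments with mean = printed value and SE = value × relative SE of the
  source count ratio — preserving the printed point and the source's
  proportional uncertainty;
* range-only utilities and event probabilities: Beta by moments with SE
  from the range;
* utility decrements: log-normal by moments on the magnitude;
* RR untreated: log-normal with natural-scale mean 2.56 and SE 1,
  truncated below at 1;
* costs: fixed (no uncertainty is published); the test price is drawn
  Uniform(£50, £620) per draw (configurable to fixed).

Each draw uses its own seed substream (SeedSequence spawn keys), so the
outcome matrix is order-invariant and reproducible from `(seed, n)`.
CEAC ties contribute 0.5 to each strategy.

## Value of information

EVPI = E[maxₛ NBₛ] − maxₛ E[NBₛ] over the PSA sample. EVPPI uses the
regression estimator: per strategy, net benefit is regressed on the subset
with additive cubic-spline bases (knot count capped relative to √n) for up
to three parameters, second-order polynomials above; EVPPI is the mean of
the fitted maxima minus the maximum of the fitted means. OLS with an
intercept preserves each strategy's mean exactly; estimates are floored at
zero. Reported per patient (population scale-up needs an incidence and
decision horizon the user must supply).

## Problem sizes

Base case and threshold price are closed-form-deterministic (<0.1 s).
Sweeps use 0.005 prevalence steps on [0, 0.20] and [0, 0.14]. The PSA uses
10,000 draws; the microsimulation cross-check in the test suite uses
40,000 simulated patients; distribution-mean checks use 10⁵ draws.

## What the synthetic inputs do and do not show

The life table is a smooth Gompertz idealisation: it reproduces the level
and age-slope of all-cause mortality but none of the cohort effects or
tabulated irregularities of real national life tables. Results are
insensitive to this over a 5-year horizon at age 60 (all-cause risk ~4–5%)
but the fixture should be replaced for older cohorts or longer horizons.
Passing tests demonstrate internal consistency of the model and agreement
with the published headline values at their stated tolerances — not
external validity of the secondary data sources themselves.

## Known limitations

* The incremental cost between arms is the difference of two ~£2,000
  totals and is sensitive at the ~£50 (2.5%) level to surveillance- and
  detection-cost conventions that are not fully pinned down; the base-case
  ICER (a ratio of two near-zero increments) should be read through the
  threshold-price and NMB analyses, which are stable.
* No test-refusal, no upper-tract imaging or cytology pathways, no
  radiotherapy or palliative TURBT, no individual-level heterogeneity
  beyond the sex-weighted life table.
* Utility evidence is not preference-elicited; the PSA distributions carry
  that uncertainty but not its structural component (e.g. the 0.78
  standing-utility convention above).
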