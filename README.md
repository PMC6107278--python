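# cystotriage

Early cost-utility analysis of a urine-biomarker triage test (DCRSHP) versus
flexible cystoscopy for diagnosing bladder cancer in patients presenting
with haematuria.

Flexible cystoscopy is the gold-standard diagnostic but is invasive,
uncomfortable and expensive (over £500 per procedure). A non-invasive urine
test used as a *triage* — only test-positives go on to cystoscopy — could
spare most patients the scope, at the price of missing some cancers
(series testing lowers sensitivity). This package quantifies that trade-off
for a health-care provider: is the triage pathway worth it, at what test
price, and for which patient groups?

It is written for health-economic modellers: every model quantity is
exposed as a typed, documented Python API, and the headline analyses are
small narrative scripts over that API.

## The model

* **Diagnostic decision tree.** A presenting cohort with bladder-cancer
  prevalence *p* is split into true/false positives/negatives per strategy.
  The triage arm uses a series-positivity rule (positive on both tests)
  under conditional independence: sensitivity `se_d·se_c`, false-positive
  rate `(1−sp_d)(1−sp_c)`. Test-positives receive a diagnostic TURBT
  (false positives unnecessarily).
* **Markov cohort model**, 6-month cycles over 5 years. Diagnosed cancer
  states: low-risk NMIBC, high-risk NMIBC on BCG, high-risk NMIBC
  post-cystectomy, MIBC post-cystectomy, metastasis — with recurrence,
  progression and disease-specific mortality, plus age-dependent all-cause
  mortality from a synthetic sex-weighted life table. False negatives
  occupy undiagnosed mirror states with progression and cancer mortality
  inflated by an untreated relative risk (RR = 2.56) and are detected on a
  staged schedule (50% in year 1, 75% cumulative by year 2, all after).
* **Economics.** Costs (GBP 2014) and QALYs are accumulated with half-cycle
  correction and 3.5%/year mid-cycle discounting. Strategies are compared
  by the incremental cost-effectiveness ratio ICER = ΔC/ΔE and net monetary
  benefit NMB = λ·QALYs − Cost at willingness-to-pay λ.
* **Uncertainty.** Deterministic sweeps (test price, prevalence, cystoscopy
  disutility, two-way price × prevalence), a 10,000-draw probabilistic
  sensitivity analysis (Beta/Dirichlet/log-normal parameter distributions,
  test price ~ Uniform(£50, £620)) summarised as a CEAC, and
  regression-based EVPI/EVPPI value-of-information analysis.

## Worked example

```python
from cystotriage import build_base_case, evaluate_both, icer
from cystotriage.sensitivity import threshold_price

params = build_base_case()            # prevalence 12.95%, test price £465.48
ref, alt = evaluate_both(params)      # cystoscopy-only, triage
print(ref.cost, ref.qalys, ref.life_years)
print(alt.cost, alt.qalys, alt.life_years)
print(threshold_price(params, 20000.0))
```

prints (to 4 s.f.):

```
2025.0 4.300 4.421
1975.7 4.301 4.420
(529.50, True)
```

Per patient over 5 years, the cystoscopy-for-all arm costs £2,025 and
yields 4.300 discounted QALYs (4.421 discounted life years); the triage arm
at a £465.48 test price costs £49 less and yields 0.0007 more QALYs, so at
this price triage is dominant in this parameterisation. The threshold
analysis says the test could be priced up to £529.50 and remain
cost-effective at £20,000/QALY; sweeping prevalence shows triage gains
QALYs only below a prevalence of ~0.17 (the benefit of sparing scopes and
false-positive TURBTs is outweighed by missed cancers in higher-risk
cohorts), and the two-way analysis caps the price at ~£607 for low-risk
groups. The same numbers come from the narrative drivers:

```bash
python analysis/01_base_case.py
python analysis/02_threshold_price.py
python analysis/03_prevalence_and_price.py
python analysis/04_psa_ceac.py          # ~30 s: 10,000-draw PSA + CEAC
python analysis/05_value_of_information.py
```

or from the CLI (`cystotriage base-case --price 465.48`, `cystotriage owsa`,
`cystotriage twsa`, `cystotriage psa`, `cystotriage voi`, `cystotriage all`),
which also accepts a YAML override file mirroring the parameter names:

```yaml
# my_scenario.yaml
dcrshp_price: 300.0
prevalence: 0.05
```

```bash
cystotriage base-case --config my_scenario.yaml --out results/
```

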