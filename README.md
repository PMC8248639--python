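# pnsurv — postnatal infection surveillance analytics

Maternal and newborn infections in the month after childbirth are a major
source of morbidity in low-resource settings, yet most of them start after
hospital discharge and are invisible to facility-based records. Telephone
surveillance — structured symptom interviews at about day 7 and day 28
after delivery — can capture them, but turning questionnaire answers into
incidence estimates takes a chain of reproducible steps: syndromic case
definitions, rules for merging reports into distinct infection episodes,
person-time accounting around deaths and missed interviews, and
risk-factor regression that tolerates recurrent events and missing
case-note covariates.

`pnsurv` implements that chain as a tested Python library and CLI for
epidemiologists and biostatisticians working with this study design:

* **Syndromic classification** of seven infection types — caesarean
  surgical-site infection (SSI), urinary tract infection (UTI), perineal
  wound infection, endometritis, mastitis, newborn possible severe
  bacterial infection (pSBI, the seven young-infant clinical signs) and
  umbilical cord infection — including the inter-definition dependency
  rules (UTI can "explain away" abdominal pain for endometritis; an
  endometritis pattern in a caesarean mother is an organ-space SSI).
* **Episode construction**: symptom reports from the two interview waves
  and hospital case-notes are merged unless they started >14 days apart,
  were different types >7 days apart, or the earlier symptoms had
  resolved by the day-7 interview.
* **Incidence**: rates per 1000 person-months with log-normal CIs
  (`rate × exp(±z/√events)`), early (day 0–7) and late (day 8–28)
  cumulative risks.
* **Risk factors**: Andersen–Gill recurrent-event Cox regression with a
  subject-clustered sandwich variance (Breslow or Efron ties),
  Grambsch–Therneau proportional-hazards checks, p<0.1 crude screening
  with a one-parameter-per-ten-events cap, and chained-equation multiple
  imputation for categorical covariates pooled by Rubin's rules.
* **Secondary outcomes**: care-seeking levels per episode, readmission by
  infection status, five-item depression scoring (possible depression at
  a total of 6+), maternal-function items, mother–baby infection
  association.
* **A synthetic cohort generator** that emulates the whole observation
  process — covariate mix, piecewise-constant infection hazards with
  injected hazard ratios, symptom emission that classifies back to the
  intended type, telephone reachability, newborn deaths and case-note
  missingness — with a ground-truth table for oracle testing.

## Worked example

```python
from pnsurv import SimulationConfig, simulate_cohort, run_pipeline

cohort, truth = simulate_cohort(SimulationConfig(seed=7))
report = run_pipeline(cohort)

print(report["maternal"]["rate"])
# {'events': 58, 'person_months': 745.1, 'rate_per_1000pm': 77.8,
#  'ci_low': 60.2, 'ci_high': 100.7, 'method': 'log_normal'}
print(report["maternal"]["risk_day0_7"])
# {'numerator': 47, 'denominator': 790, 'percent': 5.9}
print(report["risk_factors"]["maternal"]["factors"]["delivery_mode"]["levels"])
# {'caesarean': {'crude_hr': 2.17, 'crude_ci': [1.28, 3.68],
#                'adjusted_hr': 2.2, 'adjusted_ci': [1.28, 3.78]}}
```

Reading: among 790 simulated women with at least one interview, 47 (5.9%)
had a possible postnatal infection starting in the first week; over full
follow-up the rate was 77.8 infections per 1000 person-months (95% CI
60.2–100.7); caesarean delivery carried roughly twice the infection
hazard of vaginal delivery after adjusting for age group and hospital —
consistent with the hazard ratio of 1.93 the generator injects (the
adjusted model here retained 5 parameters for 58 events, within the
one-per-ten cap).

The same steps are available as a shell pipeline:

```bash
pnsurv simulate --seed 7 --out cohort/
pnsurv classify --cohort cohort/ --out findings.csv
pnsurv incidence --findings findings.csv --cohort cohort/ --out rates.json
pnsurv riskfactors --findings findings.csv --cohort cohort/ \
    --outcome maternal --out coxtable.json
pnsurv report --cohort cohort/ --out report.json
```

## Data layout

Three CSV tables keyed by `subject_id` (one first-born baby per mother):
`maternal_case_notes.csv` (demographics, pregnancy factors, delivery mode,
antibiotics, documented infection, case-note availability),
`newborn_case_notes.csv` (liveborn, Apgar, resuscitation, admission,
documented sepsis) and `interviews.csv` (one row per wave with per-symptom
presence/onset fields, resolution flags, care-seeking, readmission, infant
vital status and day-28 depression/function items). Missing values are
empty fields; day 0 is the day of delivery. `read_cohort` validates
eligibility (age ≥ 18), ID uniqueness, mode/symptom consistency and
onset/interview-day ordering, and every rejected row is attached to a
named error — no silent drops.

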