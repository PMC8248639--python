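# Methods

`pnsurv` analyses postnatal-infection surveillance data of the kind
collected by telephone follow-up after hospital childbirth: each woman is
interviewed around day 7 and day 28 after delivery, answering closed
questions about specific infection symptoms (with onset days), her baby's
symptoms, care-seeking, readmission, and — at day 28 — depression and
functional-difficulty items. Case-note extracts from the birth admission
supply risk-factor covariates and any infections documented in hospital.

## Syndromic case definitions

Seven symptom-based definitions are evaluated per report. Maternal:
caesarean surgical-site infection (wound pus; or wound breakdown with pain,
swelling or redness; or any two of fever, abdominal pain, foul/pus vaginal
discharge), urinary tract infection (dysuria and frequency, or any three of
dysuria/frequency/urgency/fever/abdominal pain), perineal wound infection
(wound pus, or breakdown with pain or swelling), endometritis (two of
fever/abdominal pain/foul discharge, where abdominal pain does not count if
the full UTI definition is met and foul discharge does not count if the
full perineal definition is met), mastitis (hard swollen breast area, or
painful red breast with fever). Newborn: possible severe bacterial
infection (any one of the seven young-infant clinical signs) and umbilical
cord infection (cord redness or pus).

Design choices where the definitions leave room:

* **"Explained by" is the full definition.** Abdominal pain is discounted
  for endometritis only when the woman's report meets the complete UTI
  rule; likewise foul discharge and the perineal rule. No weaker reading is
  applied.
* **Organ-space relabelling.** Endometritis is evaluated for all mothers;
  in a caesarean mother a positive pattern is emitted as a single SSI
  finding flagged `organ_space_ssi` (never double-counted when the
  incision-site criteria are also met).
* **Onset of a multi-symptom diagnosis** is the earliest onset among the
  present symptoms that participate in at least one satisfied clause of
  that definition.
* A symptom reported present without an onset day takes the interview day
  as a conservative onset and is flagged.

The engine is verified against an independently coded brute-force truth
table over every symptom combination (2^13 caesarean, 2^12 vaginal, 2^9
newborn) and the enumerated UTI truth table (17 of 32 item subsets).

## Episodes, person-time and rates

Findings from the two waves and the case-notes are merged greedily left to
right. A finding starts a new episode when it begins more than 14 days
after the current episode's start, or is of a different type and begins
more than 7 days after it, or when the current episode's symptoms were
flagged resolved at the day-7 interview (applied only to a strictly later
onset, so same-day findings always merge). A merged episode starts at the
earliest onset. The greedy single-pass merge keeps episode count and start
days stable under re-application; when a single episode carries several
types, re-feeding its types as separate findings can redistribute them
between adjacent episodes — counts and starts, the quantities the rates
use, are unaffected.

Follow-up runs from delivery (day 0) to the day-28 interview day when
completed, else the day-7 interview day. Babies who died before the day-7
interview contribute no person-time (their infection data were never
collected); babies who died later exit at the day-7 interview. Subjects
remain at risk after an episode (recurrent events; person-time is not
truncated at the first event). A person-month is 365.25/12 = 30.4375 days
(configurable; recorded in output).

Rates are events per 1000 person-months with the log-scale normal interval
`rate × exp(±z/√events)`; this interval reproduces published rate CIs of
this study design at 1-dp rounding. Cumulative risks use the early window
day 0–7 inclusive (denominator: subjects with ≥1 interview) and day 8–28
(denominator: day-28 completers). Episodes starting after day 28 but
before a late final interview count toward the rate (full follow-up) but
not the windowed risks.

## Risk-factor models

The recurrent-event model is an Andersen–Gill counting-process Cox
regression: one `(start, stop]` row per at-risk interval, split at event
days (an event on day *d* sits at *d* + 0.5 so day-0 events are inside the
first interval), with a sandwich variance clustered on the subject. Ties
use the Breslow approximation by default (Efron available); Breslow
matches the convention of the mainstream survey-analysis stacks for this
kind of data and is indistinguishable here at the observed tie density.
The fit is a damped Newton maximiser of the partial likelihood; score
residuals for the sandwich use the Breslow form. Proportional hazards are
checked with the Grambsch–Therneau scaled-Schoenfeld correlation test
(rank time transform by default) per covariate plus a global test; its
null calibration and power are verified by simulation.

Model building mirrors epidemiological practice: every candidate factor
gets a crude fit; factors with crude Wald p < 0.1 join the a-priori
confounders (maternal age group and hospital for the maternal outcome); if
the parameter count exceeds 10% of the event count, non-a-priori factors
are dropped in descending crude-p order (ties by name, so the retained set
is order-independent). Women without located case-notes are excluded.

Missing categorical covariates are imputed by chained equations: logistic
conditionals for binary variables, multinomial (softmax) for multi-level,
each fitted by a Newton solver with a small L2 ridge (λ = 1e-4) so that
quasi-separated sparse strata cannot diverge; coefficients are drawn from
their asymptotic normal before each predictive draw; delivery mode and
hospital enter every conditional as complete auxiliaries; 10 datasets, 10
cycles. Variables missing above 35% (gestational age in practice) are
excluded from imputation and left missing. Per-imputation fits are pooled
by Rubin's rules with Barnard–Rubin degrees of freedom; factor-level Wald
tests use D1 multivariate pooling.

## Secondary outcomes

The five-item depression score is summed and grouped as none (0–5) versus
possible depression (6–30). A five-item scale spanning 0–30 implies an
unusual per-item range; the per-item maximum defaults to 6 and is
configurable rather than guessed. Function items are analysed item-wise as
any-versus-no difficulty. Care-seeking reports the highest care level per
episode (case-note-only episodes form their own stratum). 2×2 associations
use Pearson chi-squared without continuity correction by default
(configurable), Wald odds-ratio intervals (0.5 continuity when a cell is
zero, flagged), and a two-predictor logistic model for the adjusted
mother–baby odds ratio.

## The synthetic cohort generator

The generator emulates the surveillance design so the whole pipeline is
testable without study data. Defaults describe a cohort of 879 women,
17.6% caesarean, two hospitals, with covariate marginals and per-variable
case-note missingness taken from the cohort description (gestational age
39% missing; case-notes located for 95.6%). The published age-group
proportions sum to 0.98 of the cohort; the generator uses them
renormalised (0.411/0.286/0.303).

Latent infections follow piecewise-constant per-day hazards over days
0–28, higher in the first week: maternal reference (vaginal) hazards
0.00638/0.00049 per day, derived from 47 early events over 791×8
person-days and 9 late events over 753×21, divided by the cohort-average
caesarean multiplier; newborn 0.00709/0.00168 likewise. Injected
proportional effects: caesarean HR 1.93 on the maternal hazard,
bag-and-mask resuscitation HR 4.45 and maternal early infection HR 2.5 on
the newborn hazard. Mastitis is an independent process (it is outside the
primary composite). Recurrence resumes on day *t* + 15 after an event on
day *t*, so a recurrence is always more than 14 days after the previous
onset and the episode rules reconstruct the truth exactly; onset days are
otherwise uniform within the hazard window, as nothing in the design pins
a finer distribution.

Each observed infection emits a symptom bundle drawn uniformly from the
subsets of that definition's items that classify to exactly the intended
type (the pool is enumerated through the classifier itself), with onset
equal to the true onset; optional upward jitter of one day is off by
default so the noise-free closure invariant — classified findings equal
the truth table — holds exactly. A single interview records one onset per
symptom, so when several same-population events fall in the same wave only
the first is emitted and the truth table marks the rest as unobservable;
the cross-wave episode rules, not within-wave recall, are what the study
design can identify. Background noise adds independent spurious symptoms
at a configurable per-symptom-per-interview rate (default 0.001).

The observation process draws an unreachable stratum (9.5%), then day-7
and day-28 contact at 95%/94.7% among the reachable, reproducing ≈90% with
any interview, ≈86% completing day 28 and ≈38 day-7-only women; interview
days follow discrete distributions (day-28 median 29, range up to 43).
Perinatal deaths occur before day 7 with probability 0.035 and between
interviews 0.008; babies dead before the day-7 interview yield no symptom
data. Day-28 outcomes (depression, function items, breastfeeding) and
care-seeking/readmission are drawn from logistic models with configured
baselines and odds multipliers for early infection.

What the generator does **not** emulate: reporting error in onset days
beyond the optional jitter, symptom persistence across waves (each event
is reported once), correlated missingness beyond an MAR-by-auxiliary
option, stillbirths and multiple births (excluded by design), and
hospital antibiotic-prescribing behaviour beyond a covariate flag. Passing
tests therefore demonstrate correctness of the analysis machinery under
the stated generating model, not questionnaire validity on real cohorts.

## Numerical choices and problem sizes

Newton iterations stop at |Δloglik| < 1e-9 with gradient < 1e-6 and step
halving; the Cox fit agrees with an independently maximised partial
likelihood to 1e-6 and with an independent survival library to 1e-6 on
coefficients (robust SEs within 5%, the two stacks differing in tie
handling of score residuals). Hazard-ratio recovery checks use 500
replicates of n = 3000 through a fast event-history path that draws the
same latent process as the full generator but skips symptom emission —
the estimator, not the questionnaire layer, is what those replicates
test; recovery is asserted within 3 Monte-Carlo standard errors with CI
coverage in [0.92, 0.98]. Imputation checks use n = 2000 with 20% missing
at random and 10 imputations.

## Known limitations

* The Wald odds-ratio and log-normal rate intervals are asymptotic; exact
  intervals are not provided.
* The PH test uses the information-matrix approximation to the residual
  variance (the standard practical form), not the per-time variance.
* The greedy episode merge is order-defined; pathological interleavings of
  many types within 14 days can depend on scan order (documented above).
* Conditional imputation models are main-effects only.
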