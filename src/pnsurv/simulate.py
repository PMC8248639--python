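"""Synthetic-cohort generator for the surveillance pipeline.

Generates cohorts with the statistical structure the analysis assumes:

* case-note covariates with realistic marginals and per-variable
  missingness, stratified by delivery mode;
* latent maternal and newborn infection processes: piecewise-constant
  per-day hazards over days 0-28 (higher in the first week), proportional
  multipliers for caesarean delivery (mothers), bag-and-mask resuscitation
  and maternal early infection (babies), and recurrence after a refractory
  gap of 15 days so that a recurrence always starts more than 14 days
  after the previous onset;
* symptom emission: each observed infection produces a symptom bundle
  drawn uniformly from the subsets of that definition's items that
  classify to exactly the intended type, with onset equal to the true
  onset day (plus optional jitter); uninfected subjects report spurious
  symptoms at a configurable background rate;
* the telephone observation process: a latent unreachable stratum, then
  day-7/day-28 contact, interview-day distributions, newborn deaths (no
  infection data before the day-7 interview), case-note availability;
* day-28 outcome models: depression score, maternal-function items,
  care-seeking and readmission, each with an odds multiplier for early
  infection.

The generator returns the three cohort tables in the analysis schema plus
a ground-truth event table for oracle testing. A single interview can
record only one onset per symptom, so when several same-population events
fall in the same interview wave only the first is emitted; the truth table
marks the rest ``unobservable`` (reported_wave empty).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import classify as clf
from .cohort import (
    Cohort, EPDS_ITEMS, FUNCTION_ITEMS, INTERVIEW_COLUMNS, MATERNAL_COLUMNS,
    MATERNAL_SYMPTOMS, NEWBORN_COLUMNS, NEWBORN_SYMPTOMS, CS_SITE_SYMPTOMS,
    PERINEAL_SYMPTOMS, SYMPTOM_GROUPS, coerce_interviews, coerce_maternal,
    coerce_newborn, validate_cohort,
)

REFRACTORY_DAYS = 15      # recurrence starts > 14 days after the previous onset
HORIZON_DAY = 28          # last day of the latent infection window


def _logit(p):
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class SimulationConfig(BaseModel):
    """All generator knobs; defaults emulate the study cohort."""

    seed: int = 20180315
    n_women: int = Field(default=879, gt=0)
    cs_fraction: float = Field(default=0.176, ge=0, le=1)

    # covariate mix (age-group proportions renormalised from the cohort table)
    age_group_mix: tuple[float, float, float] = (0.411, 0.286, 0.303)
    parity_mix: tuple[float, float, float, float] = (0.351, 0.313, 0.182, 0.154)
    p_hiv: float = 0.044
    p_prom: float = 0.035
    p_hypertensive: float = 0.041
    p_pph: float = 0.011
    p_episiotomy_vaginal: float = 0.015
    p_tear_vaginal: float = 0.361
    p_resuscitation: dict[str, float] = {"vaginal": 0.013, "caesarean": 0.054}
    p_admission: dict[str, float] = {"vaginal": 0.015, "caesarean": 0.081}
    p_apgar_low: dict[str, float] = {"vaginal": 0.007, "caesarean": 0.034}
    p_abx_labour: dict[str, float] = {"vaginal": 0.038, "caesarean": 0.243}
    p_abx_postpartum: dict[str, float] = {"vaginal": 0.552, "caesarean": 0.939}
    p_preterm: float = 0.14

    # latent infection hazards (per person-day, reference stratum)
    maternal_hazard_early: float = Field(default=0.00638, ge=0)
    maternal_hazard_late: float = Field(default=0.00049, ge=0)
    newborn_hazard_early: float = Field(default=0.00709, ge=0)
    newborn_hazard_late: float = Field(default=0.00168, ge=0)
    mastitis_hazard_early: float = Field(default=0.0025, ge=0)
    mastitis_hazard_late: float = Field(default=0.0005, ge=0)
    early_hazard_end: int = 7
    true_hr_caesarean: float = Field(default=1.93, gt=0)
    true_hr_resuscitation: float = Field(default=4.45, gt=0)
    newborn_hr_maternal_infection: float = Field(default=2.5, gt=0)

    # infection-type mixture given delivery mode (composite types only)
    maternal_type_mix: dict[str, dict[str, float]] = {
        "vaginal": {"UTI": 0.44, "endometritis": 0.35, "perineal_wound": 0.21},
        "caesarean": {"SSI": 0.63, "UTI": 0.37},
    }
    newborn_type_mix: dict[str, float] = {"pSBI": 0.92, "umbilical_cord": 0.08}

    # symptom reporting
    background_symptom_rate: float = Field(default=0.001, ge=0, le=1)
    onset_jitter_days: int = Field(default=0, ge=0, le=1)
    p_resolved_by_day7: float = 0.6
    p_documented_sepsis: float = 0.03   # per true newborn event

    # observation process
    p_unreachable: float = 0.095
    p_reached_day7: float = 0.95        # given reachable
    p_reached_day28: float = 0.947      # given reachable
    day7_interview_days: tuple[int, ...] = (7, 8, 9, 10, 11, 12)
    day7_interview_probs: tuple[float, ...] = (0.45, 0.25, 0.12, 0.09, 0.05, 0.04)
    day28_interview_days: tuple[int, ...] = (26, 27, 28, 29, 30, 31, 32, 33, 34,
                                             35, 36, 38, 40, 43)
    day28_interview_probs: tuple[float, ...] = (0.04, 0.10, 0.18, 0.20, 0.14, 0.10,
                                                0.07, 0.05, 0.04, 0.03, 0.02, 0.02,
                                                0.005, 0.005)
    p_death_before_day7: float = 0.035
    p_death_day8_28: float = 0.008
    p_case_note_available: float = 0.956

    # per-variable case-note missingness (fraction of available case-notes)
    missingness: dict[str, float] = {
        "age_years": 0.021, "parity": 0.031, "gestation_weeks": 0.392,
        "hypertensive_disorder": 0.007, "hiv": 0.018, "prom": 0.004,
        "episiotomy": 0.017, "perineal_tear": 0.004, "pph": 0.002,
        "antibiotics_labour": 0.007, "antibiotics_postpartum": 0.010,
        "apgar5": 0.004, "resuscitation_bag_mask": 0.005, "admission": 0.002,
    }

    # day-28 outcome models
    p_depression_base: float = 0.038
    or_depression_infection: float = 2.1
    function_base: dict[str, float] = {
        "difficulty_washing": 0.009, "difficulty_housework": 0.133,
        "difficulty_carrying_baby": 0.057, "difficulty_caring_for_baby": 0.056,
    }
    function_or: dict[str, float] = {
        "difficulty_washing": 5.5, "difficulty_housework": 1.7,
        "difficulty_carrying_baby": 1.9, "difficulty_caring_for_baby": 2.5,
    }
    p_exclusive_breastfeeding: float = 0.997
    care_level_probs: dict[str, dict[str, float]] = {
        "maternal": {"delivery_hospital": 0.43, "other_hospital": 0.14,
                     "lower_facility": 0.09, "none": 0.34},
        "newborn": {"delivery_hospital": 0.46, "other_hospital": 0.30,
                    "lower_facility": 0.11, "none": 0.13},
    }
    p_readmit: dict[str, dict[str, float]] = {
        "maternal": {"infected": 0.12, "uninfected": 0.007},
        "newborn": {"infected": 0.44, "uninfected": 0.018},
    }

    @model_validator(mode="after")
    def _check_mixtures(self) -> "SimulationConfig":
        mixtures = [self.age_group_mix, self.parity_mix,
                    tuple(self.newborn_type_mix.values()),
                    tuple(self.day7_interview_probs),
                    tuple(self.day28_interview_probs)]
        mixtures += [tuple(m.values()) for m in self.maternal_type_mix.values()]
        mixtures += [tuple(m.values()) for m in self.care_level_probs.values()]
        for m in mixtures:
            if any(w < 0 for w in m):
                raise ValueError(f"mixture weights must be non-negative: {m}")
            if abs(sum(m) - 1.0) > 1e-6:
                raise ValueError(f"mixture weights must sum to 1: {m}")
        return self


# ---------------------------------------------------------------------------
# symptom emission

@lru_cache(maxsize=None)
def _qualifying_bundles(infection_type: str, delivery_mode: str) -> tuple[frozenset, ...]:
    """All subsets of a definition's own items that classify to exactly the
    intended type (enumerated through the classifier itself)."""
    universe = {
        "SSI": CS_SITE_SYMPTOMS + ("fever", "abdominal_pain", "foul_discharge"),
        "UTI": clf.UTI_ITEMS,
        "perineal_wound": PERINEAL_SYMPTOMS,
        "endometritis": clf.ENDO_ITEMS,
        "mastitis": ("breast_hard_swollen", "breast_painful_red", "fever"),
        "pSBI": SYMPTOM_GROUPS["newborn_psbi"],
        "umbilical_cord": SYMPTOM_GROUPS["newborn_cord"],
    }[infection_type]
    newborn = infection_type in ("pSBI", "umbilical_cord")
    bundles = []
    for mask in range(1, 2 ** len(universe)):
        items = frozenset(s for i, s in enumerate(universe) if mask >> i & 1)
        onsets = {s: 0 for s in items}
        found = clf.classify_newborn(onsets) if newborn \
            else clf.classify_maternal(onsets, delivery_mode)
        if len(found) == 1 and found[0].infection_type == infection_type:
            bundles.append(items)
    return tuple(bundles)


def emit_symptoms(infection_type: str, onset_day: int, delivery_mode: str,
                  rng: np.random.Generator,
                  jitter_days: int = 0) -> dict[str, int]:
    """Draw a symptom bundle that classifies to the intended infection type.

    Raises ``ValueError`` for type/mode incompatibilities (caesarean-site
    infection in a vaginal delivery, perineal wound after caesarean, and an
    endometritis pattern in a caesarean mother, which the definitions record
    as organ-space SSI).
    """
    if infection_type == "SSI" and delivery_mode != "caesarean":
        raise ValueError("surgical-site infection requires a caesarean delivery")
    if infection_type == "perineal_wound" and delivery_mode != "vaginal":
        raise ValueError("perineal wound infection requires a vaginal delivery")
    if infection_type == "endometritis" and delivery_mode == "caesarean":
        raise ValueError("an endometritis pattern in a caesarean mother is "
                         "recorded as organ-space SSI; emit SSI instead")
    bundles = _qualifying_bundles(infection_type, delivery_mode)
    items = bundles[rng.integers(len(bundles))]
    out = {}
    for s in items:
        jitter = int(rng.integers(0, jitter_days + 1)) if jitter_days else 0
        out[s] = onset_day + jitter
    # the episode start uses the minimum; anchor one symptom at the true onset
    anchor = min(items, key=lambda s: out[s])
    out[anchor] = onset_day
    return out


# ---------------------------------------------------------------------------
# latent event processes

def simulate_event_history(n: int, hazard_early: float, hazard_late: float,
                           multiplier: np.ndarray, rng: np.random.Generator,
                           early_end: int = 7, horizon: int = HORIZON_DAY,
                           at_risk_until: np.ndarray | None = None
                           ) -> list[tuple[int, int]]:
    """Draw recurrent events from a piecewise-constant daily hazard.

    Returns (subject index, onset day) pairs; after an event on day ``d``
    the subject is not at risk again until day ``d + 15``.
    """
    if at_risk_until is None:
        at_risk_until = np.full(n, horizon)
    refractory_until = np.full(n, -1)
    events: list[tuple[int, int]] = []
    for day in range(horizon + 1):
        lam = hazard_early if day <= early_end else hazard_late
        if lam <= 0:
            continue
        p = 1.0 - np.exp(-lam * multiplier)
        u = rng.random(n)
        hit = (u < p) & (day > refractory_until) & (day <= at_risk_until)
        for i in np.nonzero(hit)[0]:
            events.append((int(i), day))
        refractory_until[hit] = day + REFRACTORY_DAYS - 1
    return events


def event_history_rows(events: list[tuple[int, int]], n: int,
                       exposure: np.ndarray, exit_day: float = HORIZON_DAY + 0.6
                       ) -> pd.DataFrame:
    """Counting-process rows (refractory time removed) for the Cox fit."""
    by_subject: dict[int, list[int]] = {}
    for i, day in events:
        by_subject.setdefault(i, []).append(day)
    rows = []
    for i in range(n):
        prev = 0.0
        for day in sorted(by_subject.get(i, [])):
            t = day + 0.5
            rows.append((i, prev, t, 1, exposure[i]))
            prev = day + REFRACTORY_DAYS
        if prev < exit_day:
            rows.append((i, prev, exit_day, 0, exposure[i]))
    return pd.DataFrame(rows, columns=["subject_id", "start", "stop", "event", "x"])


# ---------------------------------------------------------------------------
# the full generator

def _choice(rng, values, probs, size):
    return rng.choice(np.asarray(values, dtype=object), size=size, p=list(probs))


def _bernoulli(rng, p, size):
    return (rng.random(size) < p).astype(int)


def simulate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None) -> tuple[Cohort, pd.DataFrame]:
    """Generate one cohort plus its ground-truth event table.

    Deterministic given the seed; returns ``(cohort, truth)`` where truth
    has one row per latent infection event with columns subject_id,
    population, infection_type, onset_day and reported_wave (empty when the
    observation process could not capture the event).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_women
    sid = np.array([f"W{i:05d}" for i in range(1, n + 1)])

    # --- case-note covariates (true values first, missingness applied later)
    mode = np.where(rng.random(n) < config.cs_fraction, "caesarean", "vaginal")
    cs = mode == "caesarean"
    hospital = _choice(rng, ["Amana", "Temeke"], [0.5, 0.5], n)
    group = _choice(rng, [0, 1, 2], config.age_group_mix, n).astype(int)
    age = np.where(group == 0, rng.integers(18, 25, n),
                   np.where(group == 1, rng.integers(25, 30, n),
                            rng.integers(30, 46, n)))
    parity = _choice(rng, ["0", "1", "2", "3plus"], config.parity_mix, n)
    preterm = _bernoulli(rng, config.p_preterm, n)
    gestation = np.where(preterm == 1,
                         np.round(rng.uniform(31, 36.9, n), 1),
                         np.round(rng.uniform(37, 41.9, n), 1))
    hiv = _bernoulli(rng, config.p_hiv, n)
    prom = _bernoulli(rng, config.p_prom, n)
    hypertensive = _bernoulli(rng, config.p_hypertensive, n)
    pph = _bernoulli(rng, config.p_pph, n)
    episiotomy = np.where(cs, -1, _bernoulli(rng, config.p_episiotomy_vaginal, n))
    tear = np.where(cs, -1, _bernoulli(rng, config.p_tear_vaginal, n))
    p_mode = lambda d: np.where(cs, d["caesarean"], d["vaginal"])  # noqa: E731
    abx_lab = (rng.random(n) < p_mode(config.p_abx_labour)).astype(int)
    abx_pp = (rng.random(n) < p_mode(config.p_abx_postpartum)).astype(int)
    resus = (rng.random(n) < p_mode(config.p_resuscitation)).astype(int)
    admission = (rng.random(n) < p_mode(config.p_admission)).astype(int)
    apgar_low = rng.random(n) < p_mode(config.p_apgar_low)
    apgar = np.where(apgar_low, rng.integers(3, 7, n),
                     _choice(rng, [7, 8, 9, 10], [0.05, 0.15, 0.45, 0.35], n)).astype(int)

    # --- observation process
    reachable = rng.random(n) >= config.p_unreachable
    reached7 = reachable & (rng.random(n) < config.p_reached_day7)
    reached28 = reachable & (rng.random(n) < config.p_reached_day28)
    d7_day = np.asarray(_choice(rng, config.day7_interview_days,
                                config.day7_interview_probs, n), dtype=int)
    d28_day = np.asarray(_choice(rng, config.day28_interview_days,
                                 config.day28_interview_probs, n), dtype=int)

    # --- newborn deaths
    u = rng.random(n)
    death_day = np.full(n, 10_000)
    early_death = u < config.p_death_before_day7
    late_death = (~early_death) & (u < config.p_death_before_day7 + config.p_death_day8_28)
    death_day[early_death] = rng.integers(0, 7, int(early_death.sum()))
    death_day[late_death] = rng.integers(8, 28, int(late_death.sum()))

    # --- latent infection processes
    m_mult = np.where(cs, config.true_hr_caesarean, 1.0)
    m_events = simulate_event_history(
        n, config.maternal_hazard_early, config.maternal_hazard_late, m_mult,
        rng, config.early_hazard_end)
    mast_events = simulate_event_history(
        n, config.mastitis_hazard_early, config.mastitis_hazard_late,
        np.ones(n), rng, config.early_hazard_end)
    mother_infected_early = np.zeros(n, bool)
    for i, day in m_events:
        if day <= 7:
            mother_infected_early[i] = True
    n_mult = np.where(resus == 1, config.true_hr_resuscitation, 1.0)
    n_mult = n_mult * np.where(mother_infected_early,
                               config.newborn_hr_maternal_infection, 1.0)
    nb_events = simulate_event_history(
        n, config.newborn_hazard_early, config.newborn_hazard_late, n_mult,
        rng, config.early_hazard_end, at_risk_until=np.minimum(HORIZON_DAY, death_day - 1))

    # assign infection types
    truth_rows = []
    for i, day in m_events:
        mix = config.maternal_type_mix[mode[i]]
        t = _choice(rng, list(mix), list(mix.values()), 1)[0]
        truth_rows.append([sid[i], "maternal", t, day])
    for i, day in mast_events:
        truth_rows.append([sid[i], "maternal", "mastitis", day])
    for i, day in nb_events:
        t = _choice(rng, list(config.newborn_type_mix),
                    list(config.newborn_type_mix.values()), 1)[0]
        truth_rows.append([sid[i], "newborn", t, day])
    truth = pd.DataFrame(truth_rows, columns=["subject_id", "population",
                                              "infection_type", "onset_day"])
    truth = truth.sort_values(["subject_id", "population", "onset_day"],
                              kind="stable").reset_index(drop=True)

    # --- route each event to an interview wave
    idx_of = {s: i for i, s in enumerate(sid)}
    m_sym: dict[tuple[int, str], dict[str, int]] = {}
    n_sym: dict[tuple[int, str], dict[str, int]] = {}
    occupied: set[tuple[int, str, str]] = set()   # (subject, wave, population)
    reported_wave = []
    documented_sepsis = np.zeros(n, int)
    documented_sepsis_day = np.full(n, -1)
    for _, ev in truth.iterrows():
        i = idx_of[ev["subject_id"]]
        day, pop, etype = int(ev["onset_day"]), ev["population"], ev["infection_type"]
        wave = None
        if pop == "newborn":
            if rng.random() < config.p_documented_sepsis and etype == "pSBI":
                documented_sepsis[i] = 1
                documented_sepsis_day[i] = day
            if death_day[i] < d7_day[i] or not reachable[i]:
                reported_wave.append("")
                continue
            # infection data collected up to day 7 for babies who die later
            if reached7[i] and day <= d7_day[i]:
                wave = "day7"
            elif (reached28[i] and death_day[i] > 10_000 - 1 and day <= d28_day[i]
                  and (not reached7[i] or day > d7_day[i])):
                wave = "day28"
        else:
            if reached7[i] and day <= d7_day[i]:
                wave = "day7"
            elif reached28[i] and day <= d28_day[i] and (not reached7[i] or day > d7_day[i]):
                wave = "day28"
        if wave is None:
            reported_wave.append("")
            continue
        # a single interview records one onset per symptom: only the first
        # event per population can be emitted into a given wave
        key = (i, wave, pop)
        if key in occupied:
            reported_wave.append("")
            continue
        occupied.add(key)
        reported_wave.append(wave)
        store = m_sym if pop == "maternal" else n_sym
        bundle = emit_symptoms(etype, day, mode[i], rng, config.onset_jitter_days)
        store.setdefault((i, wave), {}).update(bundle)
    truth["reported_wave"] = reported_wave

    # --- background symptom noise
    if config.background_symptom_rate > 0:
        for i in range(n):
            for wave, reached, ivday in (("day7", reached7[i], d7_day[i]),
                                         ("day28", reached28[i], d28_day[i])):
                if not reached:
                    continue
                for s in MATERNAL_SYMPTOMS:
                    if s in CS_SITE_SYMPTOMS and mode[i] != "caesarean":
                        continue
                    if s in PERINEAL_SYMPTOMS and mode[i] != "vaginal":
                        continue
                    if rng.random() < config.background_symptom_rate:
                        m_sym.setdefault((i, wave), {}).setdefault(
                            s, int(rng.integers(0, ivday + 1)))
                if death_day[i] >= d7_day[i] and (wave == "day7" or death_day[i] > 10_000 - 1):
                    for s in NEWBORN_SYMPTOMS:
                        if rng.random() < config.background_symptom_rate:
                            cap = min(ivday, 7) if wave == "day7" else ivday
                            n_sym.setdefault((i, wave), {}).setdefault(
                                s, int(rng.integers(0, cap + 1)))

    # --- assemble interview rows
    m_primary = clf.MATERNAL_PRIMARY_TYPES
    early_composite = np.zeros(n, bool)
    for r, wave in zip(truth.itertuples(), truth["reported_wave"]):
        if (r.population == "maternal" and r.infection_type in m_primary
                and r.onset_day <= 7 and wave):
            early_composite[idx_of[r.subject_id]] = True
    nb_early_composite = np.zeros(n, bool)
    for r in truth.itertuples():
        if (r.population == "newborn" and r.onset_day <= 7
            and r.reported_wave):
            nb_early_composite[idx_of[r.subject_id]] = True

    iv_rows = []
    for i in range(n):
        for wave in ("day7", "day28"):
            reached = reached7[i] if wave == "day7" else reached28[i]
            row = dict.fromkeys(INTERVIEW_COLUMNS, None)
            row["subject_id"] = sid[i]
            row["wave"] = wave
            row["reached"] = int(reached)
            if not reached:
                iv_rows.append(row)
                continue
            ivday = int(d7_day[i] if wave == "day7" else d28_day[i])
            row["interview_day"] = ivday
            msym = m_sym.get((i, wave), {})
            for s, onset in msym.items():
                row[f"m_{s}"] = 1
                row[f"m_{s}_onset"] = min(onset, ivday)
            nsym = n_sym.get((i, wave), {})
            for s, onset in nsym.items():
                row[f"n_{s}"] = 1
                row[f"n_{s}_onset"] = min(onset, ivday)
            for s in MATERNAL_SYMPTOMS:
                row.setdefault(f"m_{s}", None)
            # resolution flags per symptom group, day-7 wave only
            if wave == "day7":
                for gname, stems in SYMPTOM_GROUPS.items():
                    prefix = "n_" if gname.startswith("newborn") else "m_"
                    if any(row.get(f"{prefix}{s}") == 1 for s in stems):
                        row[f"resolved_{gname}"] = int(
                            rng.random() < config.p_resolved_by_day7)
            # vital status of the baby
            if wave == "day7":
                alive = death_day[i] >= d7_day[i]
            else:
                alive = death_day[i] > ivday
            row["baby_alive"] = int(alive)
            if not alive and death_day[i] <= ivday:
                row["baby_death_day"] = int(death_day[i])
            # care-seeking: asked when symptoms were reported
            if msym:
                probs = config.care_level_probs["maternal"]
                row["care_level_mother"] = _choice(rng, list(probs),
                                                   list(probs.values()), 1)[0]
            if nsym:
                probs = config.care_level_probs["newborn"]
                row["care_level_baby"] = _choice(rng, list(probs),
                                                 list(probs.values()), 1)[0]
            if wave == "day7":
                pr = config.p_readmit["maternal"]
                row["readmitted_mother"] = int(
                    rng.random() < (pr["infected"] if early_composite[i]
                                    else pr["uninfected"]))
                if alive:
                    pr = config.p_readmit["newborn"]
                    row["readmitted_baby"] = int(
                        rng.random() < (pr["infected"] if nb_early_composite[i]
                                        else pr["uninfected"]))
            if wave == "day28":
                # depression score: latent category, then a compatible total
                p_dep = _expit(_logit(config.p_depression_base)
                               + np.log(config.or_depression_infection)
                               * early_composite[i])
                depressed = rng.random() < p_dep
                total = int(rng.integers(6, 11)) if depressed else int(
                    _choice(rng, [0, 1, 2, 3, 4, 5],
                            [0.35, 0.25, 0.15, 0.12, 0.08, 0.05], 1)[0])
                items = rng.multinomial(total, [0.2] * 5)
                while items.max() > 6:     # per-item cap
                    j = int(items.argmax())
                    k = int(items.argmin())
                    items[j] -= 1
                    items[k] += 1
                for c, v in zip(EPDS_ITEMS, items):
                    row[c] = int(v)
                for item in FUNCTION_ITEMS:
                    if "baby" in item and not alive:
                        continue
                    p_item = _expit(_logit(config.function_base[item])
                                    + np.log(config.function_or[item])
                                    * early_composite[i])
                    row[item] = int(rng.random() < p_item)
                if alive:
                    row["exclusive_breastfeeding"] = int(
                        rng.random() < config.p_exclusive_breastfeeding)
            iv_rows.append(row)

    interviews = pd.DataFrame(iv_rows, columns=list(INTERVIEW_COLUMNS))

    # --- case-note tables with missingness
    available = _bernoulli(rng, config.p_case_note_available, n)
    maternal = pd.DataFrame({
        "subject_id": sid, "hospital": hospital, "age_years": age,
        "parity": parity, "gestation_weeks": gestation,
        "hypertensive_disorder": hypertensive, "hiv": hiv, "prom": prom,
        "delivery_mode": mode,
        "episiotomy": np.where(episiotomy < 0, np.nan, episiotomy),
        "perineal_tear": np.where(tear < 0, np.nan, tear),
        "pph": pph,
        "antibiotics_labour": abx_lab,
        "antibiotics_labour_reason": np.where(
            abx_lab == 1, np.where(cs, "cs_prophylaxis", "other"), "none"),
        "antibiotics_postpartum": abx_pp,
        "antibiotics_postpartum_reason": np.where(
            abx_pp == 1, np.where(cs, "cs_prophylaxis", "routine"), None),
        "documented_infection_type": None, "documented_infection_day": None,
        "case_note_available": available,
    }, columns=list(MATERNAL_COLUMNS))
    newborn = pd.DataFrame({
        "subject_id": sid, "liveborn": 1, "apgar5": apgar,
        "resuscitation_bag_mask": resus, "admission": admission,
        "documented_sepsis": documented_sepsis,
        "documented_sepsis_day": np.where(documented_sepsis_day < 0, np.nan,
                                          documented_sepsis_day),
    }, columns=list(NEWBORN_COLUMNS))

    for var, frac in config.missingness.items():
        if frac <= 0:
            continue
        target = newborn if var in NEWBORN_COLUMNS else maternal
        mask = (rng.random(n) < frac) & (available == 1)
        if var in ("episiotomy", "perineal_tear"):
            mask &= ~cs
        target.loc[mask, var] = np.nan
        if var == "antibiotics_labour":
            maternal.loc[mask, "antibiotics_labour_reason"] = None
        if var == "antibiotics_postpartum":
            maternal.loc[mask, "antibiotics_postpartum_reason"] = None
    unavailable = available == 0
    for var in ("age_years", "parity", "gestation_weeks", "hypertensive_disorder",
                "hiv", "prom", "episiotomy", "perineal_tear", "pph",
                "antibiotics_labour", "antibiotics_labour_reason",
                "antibiotics_postpartum", "antibiotics_postpartum_reason"):
        maternal.loc[unavailable, var] = np.nan if var not in (
            "parity", "antibiotics_labour_reason", "antibiotics_postpartum_reason") else None

    maternal = coerce_maternal(maternal.astype(object).where(maternal.notna(), None)
                               .astype(str).replace({"None": None, "nan": None}))
    newborn = coerce_newborn(newborn.astype(object).where(newborn.notna(), None)
                             .astype(str).replace({"None": None, "nan": None}))
    interviews = coerce_interviews(interviews.astype(object).astype(str)
                                   .replace({"None": None, "nan": None}))
    report = validate_cohort(maternal, newborn, interviews)
    return Cohort(maternal, newborn, interviews, report), truth
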