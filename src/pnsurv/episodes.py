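"""Episode construction, person-time and incidence estimation.

Findings from the two interview waves and the case-notes are merged into
distinct infection *episodes*. Two reports by the same subject are distinct
episodes when they started more than 14 days apart, or met criteria for
different infection types and started more than seven days apart, or when
the earlier report's symptoms had been flagged as resolved by the day-7
interview. Otherwise they are merged, the episode starting at the earliest
onset.

Person-time runs from delivery (day 0) to the last completed interview;
babies who died before the day-7 interview contribute no person-time (their
infection data were never collected), and babies who died later contribute
up to the day-7 interview. Subjects remain at risk after an episode
(recurrent-event convention), so person-time is never truncated at the
first event.

Rates are events per 1000 person-months with a log-scale normal
confidence interval, rate × exp(±z / √events).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import MATERNAL_PRIMARY_TYPES, NEWBORN_PRIMARY_TYPES
from .cohort import Cohort
from .config import RunConfig

# the questionnaire group whose resolution flag covers each infection type
TYPE_RESOLUTION_GROUP = {
    "SSI": "cs_site",
    "UTI": "urinary",
    "perineal_wound": "perineal",
    "endometritis": "general",
    "mastitis": "breast",
    "pSBI": "newborn_psbi",
    "umbilical_cord": "newborn_cord",
}

SAME_TYPE_GAP_DAYS = 14
DIFFERENT_TYPE_GAP_DAYS = 7

EPISODE_COLUMNS = ("subject_id", "population", "types", "start_day",
                   "sources", "resolved_by_day7", "in_primary_composite")


@dataclass
class RateEstimate:
    """Incidence rate per 1000 person-months with a log-normal CI."""

    events: int
    person_months: float
    rate_per_1000pm: float
    ci_low: float | None
    ci_high: float | None
    method: str = "log_normal"

    def to_dict(self) -> dict:
        return {
            "events": self.events,
            "person_months": round(self.person_months, 1),
            "rate_per_1000pm": round(self.rate_per_1000pm, 1),
            "ci_low": None if self.ci_low is None else round(self.ci_low, 1),
            "ci_high": None if self.ci_high is None else round(self.ci_high, 1),
            "method": self.method,
        }


@dataclass
class RiskEstimate:
    """Cumulative risk: subjects with >=1 episode starting in a window."""

    numerator: int
    denominator: int
    percent: float

    def to_dict(self) -> dict:
        return {"numerator": self.numerator, "denominator": self.denominator,
                "percent": self.percent}


def attach_resolution(findings: pd.DataFrame, interviews: pd.DataFrame) -> pd.DataFrame:
    """Add a ``resolved_by_day7`` flag to each finding.

    A finding reported at the day-7 interview is flagged when that
    interview recorded the finding's symptom group as resolved; day-28 and
    case-note findings carry no flag.
    """
    findings = findings.copy()
    findings["resolved_by_day7"] = False
    if not len(findings):
        return findings
    d7 = interviews[(interviews["wave"] == "day7") & (interviews["reached"] == 1)]
    d7 = d7.set_index("subject_id")
    mask = findings["source"] == "interview_day7"
    for idx in findings.index[mask]:
        sid = findings.at[idx, "subject_id"]
        if sid not in d7.index:
            continue
        group = TYPE_RESOLUTION_GROUP[findings.at[idx, "infection_type"]]
        flag = d7.at[sid, f"resolved_{group}"]
        findings.at[idx, "resolved_by_day7"] = bool(pd.notna(flag) and flag == 1)
    return findings


def _merge_one_subject(rows: pd.DataFrame) -> list[dict]:
    """Greedy left-to-right merge of one subject's findings (one population)."""
    episodes: list[dict] = []
    cur: dict | None = None
    for _, f in rows.iterrows():
        onset = int(f["onset_day"])
        ftype = f["infection_type"]
        if cur is not None:
            gap = onset - cur["start_day"]
            distinct = (
                gap > SAME_TYPE_GAP_DAYS
                or (ftype not in cur["types"] and gap > DIFFERENT_TYPE_GAP_DAYS)
                or (cur["resolved_by_day7"] and gap > 0)
            )
        else:
            distinct = True
        if distinct:
            if cur is not None:
                episodes.append(cur)
            cur = {
                "subject_id": f["subject_id"], "population": f["population"],
                "types": {ftype}, "start_day": onset, "sources": {f["source"]},
                "resolved_by_day7": bool(f["resolved_by_day7"]),
            }
        else:
            cur["types"].add(ftype)
            cur["sources"].add(f["source"])
            cur["resolved_by_day7"] = cur["resolved_by_day7"] or bool(f["resolved_by_day7"])
    if cur is not None:
        episodes.append(cur)
    return episodes


def build_episodes(findings: pd.DataFrame) -> pd.DataFrame:
    """Merge findings into distinct episodes per subject and population.

    ``findings`` must carry a ``resolved_by_day7`` column (see
    :func:`attach_resolution`); an empty input yields an empty table.
    """
    records: list[dict] = []
    if len(findings):
        ordered = findings.sort_values(["onset_day", "infection_type"], kind="stable")
        for _, rows in ordered.groupby(["subject_id", "population"], sort=True):
            records.extend(_merge_one_subject(rows))
    out = pd.DataFrame(records, columns=list(EPISODE_COLUMNS[:-1]))
    if len(out):
        primary = out.apply(
            lambda r: bool(r["types"] & (MATERNAL_PRIMARY_TYPES
                                         if r["population"] == "maternal"
                                         else NEWBORN_PRIMARY_TYPES)),
            axis=1,
        )
        out["in_primary_composite"] = primary
        out["types"] = out["types"].map(lambda s: "|".join(sorted(s)))
        out["sources"] = out["sources"].map(lambda s: "|".join(sorted(s)))
        out = out.sort_values(["subject_id", "population", "start_day"],
                              kind="stable").reset_index(drop=True)
    else:
        out["in_primary_composite"] = pd.Series(dtype=bool)
    return out


# ---------------------------------------------------------------------------
# person-time

def person_time(cohort: Cohort, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-subject follow-up intervals for mothers and babies.

    Exit is the day-28 interview day when completed, else the day-7
    interview day. Mothers with no completed interview and babies who died
    before the day-7 interview are excluded (zero person-time, reason
    recorded).
    """
    config = config or RunConfig()
    iv = cohort.interviews
    d7 = iv[(iv["wave"] == "day7") & (iv["reached"] == 1)].set_index("subject_id")
    d28 = iv[(iv["wave"] == "day28") & (iv["reached"] == 1)].set_index("subject_id")
    records = []
    for sid in cohort.maternal["subject_id"]:
        in7, in28 = sid in d7.index, sid in d28.index
        if in28:
            m_exit, m_reason = int(d28.at[sid, "interview_day"]), "day28_interview"
        elif in7:
            m_exit, m_reason = int(d7.at[sid, "interview_day"]), "day7_only"
        else:
            m_exit, m_reason = 0, "excluded"
        records.append((sid, "maternal", 0, m_exit, m_reason))

        if sid not in set(cohort.newborn["subject_id"]):
            continue
        nb = cohort.newborn.set_index("subject_id")
        if nb.at[sid, "liveborn"] == 0:
            records.append((sid, "newborn", 0, 0, "excluded"))
            continue
        if m_reason == "excluded":
            records.append((sid, "newborn", 0, 0, "excluded"))
            continue
        # death handling: dead before the day-7 interview -> excluded;
        # dead after it -> contributes up to day 7.
        if in7 and d7.at[sid, "baby_alive"] == 0:
            records.append((sid, "newborn", 0, 0, "excluded"))
            continue
        if not in7 and in28 and d28.at[sid, "baby_alive"] == 0:
            # never observed alive at a day-7 interview
            records.append((sid, "newborn", 0, 0, "excluded"))
            continue
        if in7 and in28 and d28.at[sid, "baby_alive"] == 0:
            records.append((sid, "newborn", 0, int(d7.at[sid, "interview_day"]),
                            "death_after_day7"))
            continue
        records.append((sid, "newborn", 0, m_exit,
                        m_reason if in28 else "day7_only"))
    out = pd.DataFrame(records, columns=["subject_id", "population", "entry_day",
                                         "exit_day", "exit_reason"])
    out["person_months"] = out["exit_day"] / config.month_days
    out.loc[out["exit_reason"] == "excluded", "person_months"] = 0.0
    return out


# ---------------------------------------------------------------------------
# rates and risks

def incidence_rate(events: int, person_months: float,
                   alpha: float = 0.05) -> RateEstimate:
    """Events per 1000 person-months with the log-scale normal CI."""
    if events < 0 or person_months < 0:
        raise ValueError("events and person_months must be non-negative")
    if person_months == 0:
        raise ValueError("person_months must be positive")
    rate = events / person_months * 1000.0
    if events == 0:
        return RateEstimate(0, person_months, 0.0, None, None)
    z = stats.norm.ppf(1 - alpha / 2)
    factor = math.exp(z / math.sqrt(events))
    return RateEstimate(events, person_months, rate, rate / factor, rate * factor)


def composite_episodes(episodes: pd.DataFrame, population: str) -> pd.DataFrame:
    """Primary-composite episodes for one population (mastitis-only maternal
    episodes never qualify)."""
    if not len(episodes):
        return episodes
    return episodes[(episodes["population"] == population)
                    & episodes["in_primary_composite"]]


def rate_for(episodes: pd.DataFrame, follow_up: pd.DataFrame, population: str,
             config: RunConfig | None = None,
             subject_ids: pd.Series | None = None) -> RateEstimate:
    """Overall (or stratum) composite-infection rate for one population."""
    config = config or RunConfig()
    fu = follow_up[(follow_up["population"] == population)
                   & (follow_up["exit_reason"] != "excluded")]
    ep = composite_episodes(episodes, population)
    if subject_ids is not None:
        fu = fu[fu["subject_id"].isin(subject_ids)]
        ep = ep[ep["subject_id"].isin(subject_ids)] if len(ep) else ep
    # count only episodes inside the subject's observed follow-up
    if len(ep):
        exit_by = fu.set_index("subject_id")["exit_day"]
        ep = ep[ep["subject_id"].isin(exit_by.index)]
        ep = ep[ep["start_day"].values <= exit_by.loc[ep["subject_id"]].values]
    return incidence_rate(len(ep), float(fu["person_months"].sum()), config.ci_alpha)


def cumulative_risk(episodes: pd.DataFrame, follow_up: pd.DataFrame,
                    population: str, window: str,
                    config: RunConfig | None = None) -> RiskEstimate:
    """Proportion of subjects with >=1 composite episode in a window.

    ``window`` is ``"day0_7"`` (denominator: subjects with >=1 interview)
    or ``"day8_28"`` (denominator: subjects completing day-28).
    """
    config = config or RunConfig()
    fu = follow_up[(follow_up["population"] == population)
                   & (follow_up["exit_reason"] != "excluded")]
    if window == "day0_7":
        denom = fu
        lo, hi = 0, config.early_window_end
    elif window == "day8_28":
        denom = fu[fu["exit_reason"] == "day28_interview"]
        lo, hi = config.early_window_end + 1, config.late_window_end
    else:
        raise ValueError(f"unknown window {window!r}")
    if not len(denom):
        raise ValueError("empty denominator")
    ep = composite_episodes(episodes, population)
    if len(ep):
        ep = ep[ep["subject_id"].isin(denom["subject_id"])
                & ep["start_day"].between(lo, hi)]
        numer = ep["subject_id"].nunique()
    else:
        numer = 0
    return RiskEstimate(int(numer), int(len(denom)),
                        round(numer / len(denom) * 100, 1))


def rates_by_factor(episodes: pd.DataFrame, follow_up: pd.DataFrame,
                    population: str, factor: pd.Series,
                    config: RunConfig | None = None) -> dict[str, RateEstimate]:
    """Per-stratum rates for a categorical covariate indexed by subject_id."""
    out = {}
    for level in sorted(factor.dropna().unique()):
        ids = factor.index[factor == level]
        out[str(level)] = rate_for(episodes, follow_up, population, config,
                                   subject_ids=pd.Series(ids))
    return out
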