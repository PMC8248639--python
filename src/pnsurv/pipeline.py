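"""End-to-end analysis: cohort tables in, results report out."""

from __future__ import annotations

import pandas as pd

from .classify import classify_cohort
from .cohort import Cohort
from .config import RunConfig
from .episodes import (attach_resolution, build_episodes, cumulative_risk,
                       person_time, rate_for)
from .outcomes import (care_seeking_summary, epds_table, function_summary,
                       readmission_summary, TwoByTwo, association_2x2)
from .riskfactors import result_table, risk_factor_analysis


def episodes_from_cohort(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify, link resolution flags and merge into episodes."""
    findings = classify_cohort(cohort)
    findings = attach_resolution(findings, cohort.interviews)
    return build_episodes(findings), findings


def mother_baby_table(episodes: pd.DataFrame, follow_up: pd.DataFrame,
                      config: RunConfig) -> TwoByTwo:
    """2x2 of early maternal versus early newborn infection among pairs with
    newborn follow-up."""
    pairs = follow_up[(follow_up["population"] == "newborn")
                      & (follow_up["exit_reason"] != "excluded")]["subject_id"]
    early = episodes[episodes["in_primary_composite"]
                     & (episodes["start_day"] <= config.early_window_end)] \
        if len(episodes) else episodes
    m_inf = set(early[early["population"] == "maternal"]["subject_id"]) if len(early) else set()
    n_inf = set(early[early["population"] == "newborn"]["subject_id"]) if len(early) else set()
    a = sum(1 for s in pairs if s in m_inf and s in n_inf)
    b = sum(1 for s in pairs if s in m_inf and s not in n_inf)
    c = sum(1 for s in pairs if s not in m_inf and s in n_inf)
    d = sum(1 for s in pairs if s not in m_inf and s not in n_inf)
    return TwoByTwo(a, b, c, d, "maternal_infection", "newborn_infection")


def run_pipeline(cohort: Cohort, config: RunConfig | None = None,
                 risk_models: bool = True) -> dict:
    """Full analysis report as a JSON-serialisable dictionary."""
    config = config or RunConfig()
    episodes, findings = episodes_from_cohort(cohort)
    fu = person_time(cohort, config)

    report: dict = {"n_recruited": int(len(cohort.maternal))}
    for pop in ("maternal", "newborn"):
        rate = rate_for(episodes, fu, pop, config)
        section = {"rate": rate.to_dict()}
        for window in ("day0_7", "day8_28"):
            section[f"risk_{window}"] = cumulative_risk(
                episodes, fu, pop, window, config).to_dict()
        section["care_seeking"] = care_seeking_summary(
            episodes, cohort.interviews, pop)
        report[pop] = section

    report["readmission"] = readmission_summary(episodes, cohort, config)

    epds = epds_table(cohort, config)
    n_possible = int((epds["category"] == "possible").sum())
    report["depression"] = {
        "n_scored": int(len(epds)),
        "n_possible": n_possible,
        "pct_possible": round(n_possible / len(epds) * 100, 1) if len(epds) else None,
    }
    report["function"] = function_summary(cohort, episodes, config)

    mb = mother_baby_table(episodes, fu, config)
    assoc = association_2x2(mb, "or_wald")
    report["mother_baby_association"] = {
        "table": {"a": mb.a, "b": mb.b, "c": mb.c, "d": mb.d},
        "crude_or": None if assoc.or_estimate is None else round(assoc.or_estimate, 2),
        "ci": None if assoc.ci_low is None else [round(assoc.ci_low, 2),
                                                 round(assoc.ci_high, 2)],
        "p": assoc.p,
    }

    if risk_models:
        report["risk_factors"] = {
            pop: result_table(risk_factor_analysis(cohort, episodes, fu, pop, config))
            for pop in ("maternal", "newborn")
        }
    return report
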