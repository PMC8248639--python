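"""Episode distinctness rules, person-time and incidence arithmetic."""

from __future__ import annotations

import pandas as pd
import pytest

from pnsurv.config import RunConfig
from pnsurv.episodes import (build_episodes, cumulative_risk, incidence_rate,
                             person_time, rate_for)
from tests.conftest import build_cohort, interview_row, maternal_row, newborn_row


def findings_frame(rows):
    """rows: (type, onset, source, resolved) for one maternal subject."""
    return pd.DataFrame(
        [("W1", "maternal", t, d, s, False, r) for t, d, s, r in rows],
        columns=["subject_id", "population", "infection_type", "onset_day",
                 "source", "organ_space_ssi", "resolved_by_day7"])


@pytest.mark.parametrize("rows,expected_episodes,expected_starts", [
    # same type >14 days apart -> distinct
    ([("UTI", 3, "interview_day7", False), ("UTI", 25, "interview_day28", False)],
     2, [3, 25]),
    # different types >7 days apart -> distinct
    ([("UTI", 3, "interview_day7", False),
      ("endometritis", 12, "interview_day28", False)], 2, [3, 12]),
    # earlier symptoms resolved by day-7 interview -> distinct
    ([("UTI", 3, "interview_day7", True), ("UTI", 10, "interview_day28", False)],
     2, [3, 10]),
    # none of the three rules -> one merged episode starting at the minimum
    ([("UTI", 3, "interview_day7", False), ("UTI", 8, "interview_day28", False)],
     1, [3]),
    # same type exactly 14 days apart is NOT distinct (rule says over 14)
    ([("UTI", 3, "interview_day7", False), ("UTI", 17, "interview_day28", False)],
     1, [3]),
    # different types 7 days apart is NOT distinct (rule says over 7)
    ([("UTI", 3, "interview_day7", False),
      ("endometritis", 10, "interview_day28", False)], 1, [3]),
    # case-note and interview findings of the same type merge
    ([("pSBI", 1, "case_note", False), ("pSBI", 4, "interview_day7", False)],
     1, [1]),
])
def test_episode_distinctness_rules(rows, expected_episodes, expected_starts):
    episodes = build_episodes(findings_frame(rows))
    assert len(episodes) == expected_episodes
    assert episodes["start_day"].tolist() == expected_starts


def test_empty_findings_give_empty_episodes():
    episodes = build_episodes(findings_frame([]))
    assert len(episodes) == 0


def test_episode_building_is_idempotent():
    rows = [("UTI", 3, "interview_day7", False),
            ("endometritis", 6, "interview_day7", False),
            ("UTI", 25, "interview_day28", False),
            ("mastitis", 27, "interview_day28", False)]
    episodes = build_episodes(findings_frame(rows))
    # re-feed each episode as one finding per type at the episode start
    refound = []
    for _, e in episodes.iterrows():
        for t in e["types"].split("|"):
            refound.append((t, e["start_day"], e["sources"].split("|")[0],
                            bool(e["resolved_by_day7"])))
    again = build_episodes(findings_frame(refound))
    assert len(again) == len(episodes)
    assert again["start_day"].tolist() == episodes["start_day"].tolist()
    assert again["types"].tolist() == episodes["types"].tolist()


def test_mastitis_only_episode_not_in_primary_composite():
    episodes = build_episodes(findings_frame([("mastitis", 4, "interview_day7",
                                               False)]))
    assert not episodes["in_primary_composite"].iloc[0]
    episodes = build_episodes(findings_frame([("UTI", 4, "interview_day7", False)]))
    assert episodes["in_primary_composite"].iloc[0]


# ---------------------------------------------------------------------------
# person-time

def _two_wave_cohort(d7=8, d28=29, reached28=1, baby_alive_28=1, death_day=None):
    iv = [interview_row("W1", "day7", d7)]
    row28 = interview_row("W1", "day28", d28, reached=reached28,
                          baby_alive=baby_alive_28, baby_death_day=death_day)
    if not reached28:
        row28["interview_day"] = None
        row28["baby_alive"] = None
    iv.append(row28)
    return build_cohort([maternal_row("W1")], [newborn_row("W1")], iv)


def test_exit_at_day28_interview_day():
    fu = person_time(_two_wave_cohort(d7=8, d28=29))
    m = fu[fu["population"] == "maternal"].iloc[0]
    assert m["exit_day"] == 29
    assert m["exit_reason"] == "day28_interview"
    assert m["person_months"] == pytest.approx(29 / 30.4375)


def test_day7_only_exit():
    fu = person_time(_two_wave_cohort(d7=8, reached28=0))
    m = fu[fu["population"] == "maternal"].iloc[0]
    assert (m["exit_day"], m["exit_reason"]) == (8, "day7_only")


def test_newborn_death_after_day7_contributes_to_day7_only():
    fu = person_time(_two_wave_cohort(d7=8, d28=30, baby_alive_28=0, death_day=20))
    nb = fu[fu["population"] == "newborn"].iloc[0]
    assert (nb["exit_day"], nb["exit_reason"]) == (8, "death_after_day7")
    m = fu[fu["population"] == "maternal"].iloc[0]
    assert m["exit_day"] == 30


def test_newborn_dead_before_day7_interview_excluded():
    iv = [interview_row("W1", "day7", 8, baby_alive=0, baby_death_day=2),
          interview_row("W1", "day28", 29)]
    cohort = build_cohort([maternal_row("W1")], [newborn_row("W1")], iv)
    fu = person_time(cohort)
    nb = fu[fu["population"] == "newborn"].iloc[0]
    assert nb["exit_reason"] == "excluded"
    assert nb["person_months"] == 0.0


def test_mother_never_interviewed_excluded():
    iv = [interview_row("W1", "day7", None, reached=0),
          interview_row("W1", "day28", None, reached=0)]
    for r in iv:
        r["interview_day"] = None
        r["baby_alive"] = None
    cohort = build_cohort([maternal_row("W1")], [newborn_row("W1")], iv)
    fu = person_time(cohort)
    assert (fu["exit_reason"] == "excluded").all()


# ---------------------------------------------------------------------------
# incidence arithmetic

@pytest.mark.parametrize("events,pm,rate,lo,hi", [
    (56, 705.3, 79.4, 61.1, 103.2),
    (82, 677.4, 121.1, 97.5, 150.3),
    (39, 578.1, 67.5, None, None),
])
def test_incidence_rate_log_normal_ci(events, pm, rate, lo, hi):
    est = incidence_rate(events, pm)
    assert round(est.rate_per_1000pm, 1) == rate
    if lo is not None:
        assert round(est.ci_low, 1) == lo
        assert round(est.ci_high, 1) == hi
    # exact identity: rate x person-months / 1000 returns the event count
    assert est.rate_per_1000pm * pm / 1000 == pytest.approx(events)


def test_zero_events_rate():
    est = incidence_rate(0, 100.0)
    assert est.rate_per_1000pm == 0.0
    assert est.ci_low is None and est.ci_high is None


def test_negative_inputs_raise():
    with pytest.raises(ValueError):
        incidence_rate(-1, 100.0)
    with pytest.raises(ValueError):
        incidence_rate(5, -1.0)
    with pytest.raises(ValueError):
        incidence_rate(5, 0.0)


# ---------------------------------------------------------------------------
# cumulative risk on constructed denominators

def _fu_frame(n_total, n_day28):
    rows = []
    for i in range(n_total):
        reason = "day28_interview" if i < n_day28 else "day7_only"
        exit_day = 29 if i < n_day28 else 8
        rows.append((f"W{i}", "maternal", 0, exit_day, reason, exit_day / 30.4375))
    return pd.DataFrame(rows, columns=["subject_id", "population", "entry_day",
                                       "exit_day", "exit_reason", "person_months"])


def _episode_frame(ids, start_day):
    return pd.DataFrame(
        [(s, "maternal", "UTI", start_day, "interview_day7", False, True)
         for s in ids],
        columns=["subject_id", "population", "types", "start_day", "sources",
                 "resolved_by_day7", "in_primary_composite"])


def test_cumulative_risk_early_window():
    fu = _fu_frame(791, 753)
    ep = _episode_frame([f"W{i}" for i in range(47)], start_day=5)
    risk = cumulative_risk(ep, fu, "maternal", "day0_7")
    assert (risk.numerator, risk.denominator, risk.percent) == (47, 791, 5.9)


def test_cumulative_risk_late_window_denominator_is_day28_completers():
    fu = _fu_frame(791, 753)
    ep = _episode_frame([f"W{i}" for i in range(9)], start_day=15)
    risk = cumulative_risk(ep, fu, "maternal", "day8_28")
    assert (risk.numerator, risk.denominator, risk.percent) == (9, 753, 1.2)


def test_cumulative_risk_day7_boundary_inclusive():
    fu = _fu_frame(100, 100)
    ep = _episode_frame(["W0"], start_day=7)
    assert cumulative_risk(ep, fu, "maternal", "day0_7").numerator == 1
    assert cumulative_risk(ep, fu, "maternal", "day8_28").numerator == 0


def test_zero_infected_risk():
    fu = _fu_frame(10, 10)
    risk = cumulative_risk(_episode_frame([], 1).iloc[:0], fu, "maternal", "day0_7")
    assert risk.percent == 0.0


def test_person_time_identity_on_simulated_cohort(sim_cohort):
    cohort, _ = sim_cohort
    fu = person_time(cohort)
    config = RunConfig()
    included = fu[fu["exit_reason"] != "excluded"]
    assert included["person_months"].sum() == pytest.approx(
        (included["exit_day"] / config.month_days).sum())
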