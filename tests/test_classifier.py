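"""Rule-engine tests: worked examples, exhaustive truth-table oracle,
monotonicity and the inter-definition dependency rules."""

from __future__ import annotations

from itertools import combinations

import pytest

from pnsurv.classify import (SymptomInputError, casenote_findings,
                             classify_maternal, classify_newborn)
from pnsurv.cohort import (CS_SITE_SYMPTOMS, PERINEAL_SYMPTOMS,
                           PSBI_SYMPTOMS, CORD_SYMPTOMS)
from tests.conftest import build_cohort, maternal_row, newborn_row

# ---------------------------------------------------------------------------
# independent brute-force oracle: direct boolean re-statement of each
# definition, sharing no code with the engine


def oracle_maternal(present: set[str], mode: str) -> set[str]:
    out = set()
    uti_items = ["dysuria", "urinary_frequency", "urinary_urgency", "fever",
                 "abdominal_pain"]
    uti = ({"dysuria", "urinary_frequency"} <= present
           or sum(s in present for s in uti_items) >= 3)
    if uti:
        out.add("UTI")
    perineal = False
    if mode == "vaginal":
        perineal = ("perineal_pus" in present
                    or ("perineal_breakdown" in present
                        and ("perineal_pain" in present
                             or "perineal_swelling" in present)))
        if perineal:
            out.add("perineal_wound")
    endo_count = (("fever" in present)
                  + ("abdominal_pain" in present and not uti)
                  + ("foul_discharge" in present and not perineal))
    endo = endo_count >= 2
    if mode == "caesarean":
        site = ("cs_pus" in present
                or ("cs_wound_breakdown" in present
                    and any(s in present for s in ("cs_pain", "cs_swelling",
                                                   "cs_redness"))))
        general = sum(s in present for s in ("fever", "abdominal_pain",
                                             "foul_discharge")) >= 2
        if site or general or endo:
            out.add("SSI")
    elif endo:
        out.add("endometritis")
    if ("breast_hard_swollen" in present
            or {"breast_painful_red", "fever"} <= present):
        out.add("mastitis")
    return out


def oracle_newborn(present: set[str]) -> set[str]:
    out = set()
    if any(s in present for s in PSBI_SYMPTOMS):
        out.add("pSBI")
    if any(s in present for s in CORD_SYMPTOMS):
        out.add("umbilical_cord")
    return out


CAESAREAN_UNIVERSE = CS_SITE_SYMPTOMS + (
    "fever", "abdominal_pain", "foul_discharge",
    "dysuria", "urinary_frequency", "urinary_urgency",
    "breast_hard_swollen", "breast_painful_red")
VAGINAL_UNIVERSE = PERINEAL_SYMPTOMS + (
    "fever", "abdominal_pain", "foul_discharge",
    "dysuria", "urinary_frequency", "urinary_urgency",
    "breast_hard_swollen", "breast_painful_red")


def _subsets(universe):
    for mask in range(2 ** len(universe)):
        yield frozenset(s for i, s in enumerate(universe) if mask >> i & 1)


@pytest.mark.parametrize("mode,universe", [("caesarean", CAESAREAN_UNIVERSE),
                                           ("vaginal", VAGINAL_UNIVERSE)])
def test_maternal_engine_matches_truth_table(mode, universe):
    """Exhaustive agreement with the independently coded definitions over
    every symptom combination for each delivery mode."""
    for present in _subsets(universe):
        onsets = {s: 0 for s in present}
        got = {f.infection_type for f in classify_maternal(onsets, mode)}
        assert got == oracle_maternal(set(present), mode), present


def test_newborn_engine_matches_truth_table():
    for present in _subsets(PSBI_SYMPTOMS + CORD_SYMPTOMS):
        onsets = {s: 0 for s in present}
        got = {f.infection_type for f in classify_newborn(onsets)}
        assert got == oracle_newborn(set(present)), present


def test_uti_rule_admits_17_of_32_subsets():
    """(dysuria AND frequency) OR (>=3 of five items): exactly 17 subsets."""
    items = ("dysuria", "urinary_frequency", "urinary_urgency", "fever",
             "abdominal_pain")
    n = 0
    for present in _subsets(items):
        onsets = {s: 0 for s in present}
        if any(f.infection_type == "UTI"
               for f in classify_maternal(onsets, "vaginal")):
            n += 1
    assert n == 17
    # independent count: enumerate the rule arithmetically
    alt = sum(1 for k in range(6) for c in combinations(items, k)
              if {"dysuria", "urinary_frequency"} <= set(c) or len(c) >= 3)
    assert alt == 17


# ---------------------------------------------------------------------------
# worked examples

def test_caesarean_wound_pus_alone_is_ssi():
    found = classify_maternal({"cs_pus": 4}, "caesarean")
    assert [(f.infection_type, f.onset_day) for f in found] == [("SSI", 4)]
    assert not found[0].organ_space_ssi


def test_fever_plus_abdominal_pain_is_endometritis_with_earliest_onset():
    found = classify_maternal({"fever": 2, "abdominal_pain": 3}, "vaginal")
    assert [(f.infection_type, f.onset_day) for f in found] == [("endometritis", 2)]


def test_uti_explains_abdominal_pain_away_from_endometritis():
    """Dysuria+frequency+fever+abdominal pain: UTI only — the pain is
    explained by UTI and fever alone cannot carry endometritis."""
    found = classify_maternal({"dysuria": 1, "urinary_frequency": 1,
                               "fever": 1, "abdominal_pain": 1}, "vaginal")
    assert {f.infection_type for f in found} == {"UTI"}


def test_adding_dysuria_can_flip_endometritis_to_uti_only():
    """The only non-monotonicity the definitions allow."""
    before = {f.infection_type
              for f in classify_maternal({"fever": 1, "abdominal_pain": 1},
                                         "vaginal")}
    after = {f.infection_type
             for f in classify_maternal({"fever": 1, "abdominal_pain": 1,
                                         "dysuria": 1}, "vaginal")}
    assert before == {"endometritis"}
    assert after == {"UTI"}


def test_monotonicity_except_explained_by_rule():
    """Adding one symptom never removes a diagnosis other than endometritis
    (which can only be lost to UTI or perineal wound)."""
    for present in _subsets(VAGINAL_UNIVERSE):
        base = oracle_maternal(set(present), "vaginal")
        for extra in VAGINAL_UNIVERSE:
            if extra in present:
                continue
            bigger = oracle_maternal(set(present) | {extra}, "vaginal")
            lost = base - bigger
            assert lost <= {"endometritis"}
            if lost:
                assert bigger & {"UTI", "perineal_wound"}


def test_caesarean_endometritis_pattern_is_organ_space_ssi():
    found = classify_maternal({"fever": 3, "foul_discharge": 5}, "caesarean")
    assert [(f.infection_type, f.onset_day) for f in found] == [("SSI", 3)]
    assert found[0].organ_space_ssi


def test_no_symptoms_classify_to_nothing():
    assert classify_maternal({}, "vaginal") == []
    assert classify_newborn({}) == []


def test_newborn_examples():
    assert [(f.infection_type, f.onset_day)
            for f in classify_newborn({"chest_indrawing": 5})] == [("pSBI", 5)]
    found = classify_newborn({"cord_pus": 6, "fever": 4})
    assert [(f.infection_type, f.onset_day) for f in found] == \
        [("pSBI", 4), ("umbilical_cord", 6)]


def test_site_symptoms_incompatible_with_mode_raise():
    with pytest.raises(SymptomInputError):
        classify_maternal({"cs_pus": 1}, "vaginal")
    with pytest.raises(SymptomInputError):
        classify_maternal({"perineal_pus": 1}, "caesarean")


# ---------------------------------------------------------------------------
# case-note findings

def test_documented_newborn_sepsis_becomes_casenote_psbi_finding():
    cohort = build_cohort(
        [maternal_row("W1")],
        [newborn_row("W1", documented_sepsis=1, documented_sepsis_day=1)])
    found = casenote_findings(cohort)
    assert len(found) == 1
    row = found.iloc[0]
    assert (row["infection_type"], row["onset_day"], row["source"]) == \
        ("pSBI", 1, "case_note")


def test_casenote_finding_retained_without_any_interview():
    """A documented infection stands even if never reported by telephone."""
    cohort = build_cohort(
        [maternal_row("W1", documented_infection_type="endometritis",
                      documented_infection_day=None)],
        [newborn_row("W1")])
    found = casenote_findings(cohort)
    assert len(found) == 1
    assert found.iloc[0]["onset_day"] == 0      # undated -> delivery day
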