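"""Syndromic classification of maternal and newborn infection.

Seven symptom-based case definitions, evaluated from closed-question
telephone-interview answers (each symptom: present yes/no plus day of
onset) and from infections documented in the hospital case-notes:

Maternal
    * caesarean surgical-site infection (SSI; caesarean deliveries only):
      wound pus discharge, OR wound breakdown with at least one of pain /
      swelling / redness, OR two or more of fever / abdominal pain /
      foul-smelling-or-pus vaginal discharge;
    * urinary tract infection (UTI): dysuria AND frequency, OR at least
      three of dysuria / frequency / urgency / fever / abdominal pain;
    * perineal wound infection (vaginal deliveries only): wound pus, OR
      wound breakdown with pain and/or swelling;
    * endometritis: two or more of fever / abdominal pain / foul discharge,
      where abdominal pain does not count if the full UTI definition is met
      and foul discharge does not count if the full perineal-wound
      definition is met. In a caesarean mother a positive endometritis
      pattern is recorded as an organ-space SSI;
    * mastitis: swollen hard breast area, OR painful red breast with fever.

Newborn
    * possible severe bacterial infection (pSBI): any one of the seven
      clinical signs (fever, hypothermia, fast breathing, chest indrawing,
      convulsions, poor feeding, movement only when stimulated);
    * umbilical cord infection: cord redness and/or cord pus.

The onset day attached to a diagnosis is the earliest onset among the
present symptoms that participate in a satisfied clause of that
definition. Dependencies are evaluated in a fixed order: UTI and perineal
wound first, then endometritis (with its "explained by" exclusions), then
the relabelling of a caesarean endometritis pattern as organ-space SSI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .cohort import (
    CS_SITE_SYMPTOMS, PERINEAL_SYMPTOMS, PSBI_SYMPTOMS, CORD_SYMPTOMS,
    MATERNAL_SYMPTOMS, NEWBORN_SYMPTOMS, Cohort,
)

UTI_ITEMS = ("dysuria", "urinary_frequency", "urinary_urgency", "fever", "abdominal_pain")
ENDO_ITEMS = ("fever", "abdominal_pain", "foul_discharge")

MATERNAL_PRIMARY_TYPES = frozenset({"SSI", "UTI", "perineal_wound", "endometritis"})
NEWBORN_PRIMARY_TYPES = frozenset({"pSBI", "umbilical_cord"})

FINDING_COLUMNS = ("subject_id", "population", "infection_type", "onset_day",
                   "source", "organ_space_ssi", "onset_imputed")


class SymptomInputError(ValueError):
    """Symptom report inconsistent with the delivery mode."""


@dataclass(frozen=True)
class Finding:
    """One classified infection for one subject."""

    infection_type: str
    onset_day: int
    organ_space_ssi: bool = False


def _min_onset(onsets: Mapping[str, int], stems: Iterable[str]) -> int:
    return min(onsets[s] for s in stems)


def classify_maternal(onsets: Mapping[str, int], delivery_mode: str) -> list[Finding]:
    """Classify one woman's symptom report.

    Parameters
    ----------
    onsets:
        Mapping of present symptom stems to onset day (absent symptoms are
        simply not in the mapping).
    delivery_mode:
        ``"vaginal"`` or ``"caesarean"``.
    """
    present = set(onsets)
    unknown = present - set(MATERNAL_SYMPTOMS)
    if unknown:
        raise SymptomInputError(f"unknown maternal symptoms: {sorted(unknown)}")
    if delivery_mode == "vaginal" and present & set(CS_SITE_SYMPTOMS):
        raise SymptomInputError("caesarean-site symptoms reported for a vaginal delivery")
    if delivery_mode == "caesarean" and present & set(PERINEAL_SYMPTOMS):
        raise SymptomInputError("perineal-wound symptoms reported for a caesarean delivery")

    findings: list[Finding] = []

    # --- UTI: (dysuria AND frequency) OR (>=3 of the five urinary items)
    uti_present = present & set(UTI_ITEMS)
    pair = {"dysuria", "urinary_frequency"} <= present
    triple = len(uti_present) >= 3
    uti = pair or triple
    if uti:
        qualifying: set[str] = set()
        if pair:
            qualifying |= {"dysuria", "urinary_frequency"}
        if triple:
            qualifying |= uti_present
        findings.append(Finding("UTI", _min_onset(onsets, qualifying)))

    # --- perineal wound (vaginal only): pus OR (breakdown AND (pain or swelling))
    perineal = False
    if delivery_mode == "vaginal":
        pus = "perineal_pus" in present
        breakdown = ("perineal_breakdown" in present
                     and present & {"perineal_pain", "perineal_swelling"})
        perineal = pus or bool(breakdown)
        if perineal:
            qualifying = set()
            if pus:
                qualifying.add("perineal_pus")
            if breakdown:
                qualifying |= {"perineal_breakdown"} | (
                    present & {"perineal_pain", "perineal_swelling"})
            findings.append(Finding("perineal_wound", _min_onset(onsets, qualifying)))

    # --- endometritis pattern: >=2 of fever / abdominal pain / foul discharge,
    # abdominal pain not counting when the UTI definition explains it, foul
    # discharge not counting when the perineal definition explains it.
    eligible = set()
    if "fever" in present:
        eligible.add("fever")
    if "abdominal_pain" in present and not uti:
        eligible.add("abdominal_pain")
    if "foul_discharge" in present and not perineal:
        eligible.add("foul_discharge")
    endo = len(eligible) >= 2
    endo_onset = _min_onset(onsets, eligible) if endo else None

    if delivery_mode == "caesarean":
        # --- incision-site SSI: pus OR (breakdown AND >=1 of pain/swelling/redness)
        # OR >=2 of fever / abdominal pain / foul discharge.
        qualifying = set()
        if "cs_pus" in present:
            qualifying.add("cs_pus")
        assoc = present & {"cs_pain", "cs_swelling", "cs_redness"}
        if "cs_wound_breakdown" in present and assoc:
            qualifying |= {"cs_wound_breakdown"} | assoc
        general = present & set(ENDO_ITEMS)
        if len(general) >= 2:
            qualifying |= general
        # an endometritis pattern in a caesarean mother counts as organ-space SSI
        if endo:
            qualifying |= eligible
        if qualifying:
            findings.append(Finding("SSI", _min_onset(onsets, qualifying),
                                    organ_space_ssi=endo))
    elif endo:
        findings.append(Finding("endometritis", endo_onset))

    # --- mastitis: hard swollen area OR (painful red breast AND fever)
    hard = "breast_hard_swollen" in present
    red_fever = {"breast_painful_red", "fever"} <= present
    if hard or red_fever:
        qualifying = set()
        if hard:
            qualifying.add("breast_hard_swollen")
        if red_fever:
            qualifying |= {"breast_painful_red", "fever"}
        findings.append(Finding("mastitis", _min_onset(onsets, qualifying)))

    return sorted(findings, key=lambda f: (f.onset_day, f.infection_type))


def classify_newborn(onsets: Mapping[str, int]) -> list[Finding]:
    """Classify one baby's symptom report (pSBI and/or umbilical cord)."""
    present = set(onsets)
    unknown = present - set(NEWBORN_SYMPTOMS)
    if unknown:
        raise SymptomInputError(f"unknown newborn symptoms: {sorted(unknown)}")
    findings = []
    psbi = present & set(PSBI_SYMPTOMS)
    if psbi:
        findings.append(Finding("pSBI", _min_onset(onsets, psbi)))
    cord = present & set(CORD_SYMPTOMS)
    if cord:
        findings.append(Finding("umbilical_cord", _min_onset(onsets, cord)))
    return sorted(findings, key=lambda f: (f.onset_day, f.infection_type))


# ---------------------------------------------------------------------------
# cohort-level drivers

def _extract_onsets(row: pd.Series, prefix: str, stems: Iterable[str],
                    interview_day) -> tuple[dict[str, int], bool]:
    """Pull present symptoms from one interview row.

    A symptom reported present but with no onset day is assigned the
    interview day as a conservative onset and flagged.
    """
    onsets: dict[str, int] = {}
    imputed = False
    for s in stems:
        val = row.get(f"{prefix}{s}")
        if pd.notna(val) and val == 1:
            onset = row.get(f"{prefix}{s}_onset")
            if pd.isna(onset):
                onset = interview_day
                imputed = True
            onsets[s] = int(onset)
    return onsets, imputed


def classify_interviews(cohort: Cohort) -> pd.DataFrame:
    """Classify every reached interview row; returns the findings table.

    Columns: subject_id, population ("maternal"/"newborn"), infection_type,
    onset_day, source ("interview_day7"/"interview_day28"), organ_space_ssi,
    onset_imputed.
    """
    mode = cohort.maternal.set_index("subject_id")["delivery_mode"]
    records = []
    reached = cohort.interviews[cohort.interviews["reached"] == 1]
    for _, row in reached.iterrows():
        sid = row["subject_id"]
        source = f"interview_{row['wave']}"
        day = row["interview_day"]
        m_onsets, m_imp = _extract_onsets(row, "m_", MATERNAL_SYMPTOMS, day)
        for f in classify_maternal(m_onsets, mode[sid]):
            records.append((sid, "maternal", f.infection_type, f.onset_day,
                            source, f.organ_space_ssi, m_imp))
        n_onsets, n_imp = _extract_onsets(row, "n_", NEWBORN_SYMPTOMS, day)
        for f in classify_newborn(n_onsets):
            records.append((sid, "newborn", f.infection_type, f.onset_day,
                            source, False, n_imp))
    return pd.DataFrame(records, columns=FINDING_COLUMNS)


def casenote_findings(cohort: Cohort) -> pd.DataFrame:
    """Findings documented in hospital case-notes around the time of birth.

    A documented maternal infection or newborn sepsis is retained even when
    no symptoms were ever reported by telephone; an undated diagnosis is
    assigned day 0 (delivery day).
    """
    records = []
    avail = cohort.maternal[cohort.maternal["case_note_available"] == 1]
    doc = avail[avail["documented_infection_type"].notna()]
    for _, row in doc.iterrows():
        day = row["documented_infection_day"]
        records.append((row["subject_id"], "maternal", row["documented_infection_type"],
                        int(day) if pd.notna(day) else 0, "case_note", False, False))
    sep = cohort.newborn[cohort.newborn["documented_sepsis"] == 1]
    for _, row in sep.iterrows():
        day = row["documented_sepsis_day"]
        records.append((row["subject_id"], "newborn", "pSBI",
                        int(day) if pd.notna(day) else 0, "case_note", False, False))
    return pd.DataFrame(records, columns=FINDING_COLUMNS)


def classify_cohort(cohort: Cohort) -> pd.DataFrame:
    """All findings: telephone interviews plus case-note documentation."""
    parts = [classify_interviews(cohort), casenote_findings(cohort)]
    out = pd.concat([p for p in parts if len(p)], ignore_index=True) \
        if any(len(p) for p in parts) else pd.DataFrame(columns=FINDING_COLUMNS)
    return out.sort_values(["subject_id", "population", "onset_day"],
                           kind="stable").reset_index(drop=True)
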