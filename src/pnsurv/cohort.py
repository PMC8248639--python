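"""Cohort data model, CSV input/output and validation.

The cohort consists of three linked tables keyed by ``subject_id`` (the
mother; the study analysed one — the first-born — baby per mother):

``maternal_case_notes``
    One row per recruited woman, extracted from the hospital case-notes at
    the time of birth: demographics, pregnancy factors, delivery mode,
    antibiotic prescribing and any infection documented in hospital.
``newborn_case_notes``
    One row per (first) baby: liveborn flag, Apgar score, bag-and-mask
    resuscitation, admission and documented sepsis.
``interviews``
    Up to two rows per woman: the day-7 and day-28 telephone interview
    waves, carrying per-symptom presence/onset-day answers for mother and
    baby, symptom-resolution flags, care-seeking, readmission, infant vital
    status and (day-28 only) depression and maternal-function items.

Missing values are empty CSV fields throughout. Flags are encoded 0/1 and
held in nullable integer columns so that "unknown" survives a round trip.
Day 0 is the day of delivery; every onset/interview day is an integer count
of days since delivery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import RunConfig

HOSPITALS = ("Amana", "Temeke")
DELIVERY_MODES = ("vaginal", "caesarean")
PARITY_LEVELS = ("0", "1", "2", "3plus")
WAVES = ("day7", "day28")
CARE_LEVELS = ("none", "lower_facility", "other_hospital", "delivery_hospital")
ABX_LABOUR_REASONS = ("cs_prophylaxis", "prom", "uti", "other", "none", "unknown")
ABX_PP_REASONS = (
    "cs_prophylaxis", "prom", "perineal_suture", "uti", "routine", "iud", "unknown",
)
INFECTION_TYPES = (
    "SSI", "UTI", "perineal_wound", "endometritis", "mastitis",
    "pSBI", "umbilical_cord",
)

# Maternal symptom stems, grouped as they are asked on the questionnaire.
CS_SITE_SYMPTOMS = ("cs_pus", "cs_pain", "cs_swelling", "cs_redness", "cs_wound_breakdown")
GENERAL_SYMPTOMS = ("fever", "abdominal_pain", "foul_discharge")
URINARY_SYMPTOMS = ("dysuria", "urinary_frequency", "urinary_urgency")
PERINEAL_SYMPTOMS = ("perineal_pus", "perineal_pain", "perineal_swelling", "perineal_breakdown")
BREAST_SYMPTOMS = ("breast_hard_swollen", "breast_painful_red")
MATERNAL_SYMPTOMS = (
    CS_SITE_SYMPTOMS + GENERAL_SYMPTOMS + URINARY_SYMPTOMS
    + PERINEAL_SYMPTOMS + BREAST_SYMPTOMS
)

# Newborn symptom stems: the seven pSBI clinical signs plus the two
# umbilical-cord signs.
PSBI_SYMPTOMS = (
    "fever", "hypothermia", "fast_breathing", "chest_indrawing",
    "convulsions", "poor_feeding", "movement_only_stimulated",
)
CORD_SYMPTOMS = ("cord_redness", "cord_pus")
NEWBORN_SYMPTOMS = PSBI_SYMPTOMS + CORD_SYMPTOMS

SYMPTOM_GROUPS = {
    "cs_site": CS_SITE_SYMPTOMS,
    "general": GENERAL_SYMPTOMS,
    "urinary": URINARY_SYMPTOMS,
    "perineal": PERINEAL_SYMPTOMS,
    "breast": BREAST_SYMPTOMS,
    "newborn_psbi": PSBI_SYMPTOMS,
    "newborn_cord": CORD_SYMPTOMS,
}
RESOLVED_COLUMNS = tuple(f"resolved_{g}" for g in SYMPTOM_GROUPS)

EPDS_ITEMS = tuple(f"epds_{i}" for i in range(1, 6))
FUNCTION_ITEMS = (
    "difficulty_washing", "difficulty_housework",
    "difficulty_carrying_baby", "difficulty_caring_for_baby",
)

MATERNAL_COLUMNS = (
    "subject_id", "hospital", "age_years", "parity", "gestation_weeks",
    "hypertensive_disorder", "hiv", "prom", "delivery_mode",
    "episiotomy", "perineal_tear", "pph",
    "antibiotics_labour", "antibiotics_labour_reason",
    "antibiotics_postpartum", "antibiotics_postpartum_reason",
    "documented_infection_type", "documented_infection_day",
    "case_note_available",
)
NEWBORN_COLUMNS = (
    "subject_id", "liveborn", "apgar5", "resuscitation_bag_mask",
    "admission", "documented_sepsis", "documented_sepsis_day",
)


def _symptom_columns(prefix: str, stems: tuple[str, ...]) -> tuple[str, ...]:
    cols: list[str] = []
    for s in stems:
        cols.append(f"{prefix}{s}")
        cols.append(f"{prefix}{s}_onset")
    return tuple(cols)


M_SYMPTOM_COLUMNS = _symptom_columns("m_", MATERNAL_SYMPTOMS)
N_SYMPTOM_COLUMNS = _symptom_columns("n_", NEWBORN_SYMPTOMS)

INTERVIEW_COLUMNS = (
    ("subject_id", "wave", "reached", "interview_day")
    + M_SYMPTOM_COLUMNS + N_SYMPTOM_COLUMNS + RESOLVED_COLUMNS
    + ("care_level_mother", "care_level_baby",
       "readmitted_mother", "readmitted_baby",
       "baby_alive", "baby_death_day")
    + EPDS_ITEMS + FUNCTION_ITEMS + ("exclusive_breastfeeding",)
)

_MATERNAL_FLAGS = (
    "hypertensive_disorder", "hiv", "prom", "episiotomy", "perineal_tear",
    "pph", "antibiotics_labour", "antibiotics_postpartum", "case_note_available",
)
_NEWBORN_FLAGS = ("liveborn", "resuscitation_bag_mask", "admission", "documented_sepsis")
_INTERVIEW_FLAGS = (
    ("reached", "readmitted_mother", "readmitted_baby", "baby_alive",
     "exclusive_breastfeeding")
    + RESOLVED_COLUMNS + FUNCTION_ITEMS
    + tuple(c for c in M_SYMPTOM_COLUMNS if not c.endswith("_onset"))
    + tuple(c for c in N_SYMPTOM_COLUMNS if not c.endswith("_onset"))
)
_INTERVIEW_INTS = (
    ("interview_day", "baby_death_day")
    + EPDS_ITEMS
    + tuple(c for c in M_SYMPTOM_COLUMNS if c.endswith("_onset"))
    + tuple(c for c in N_SYMPTOM_COLUMNS if c.endswith("_onset"))
)


@dataclass
class ValidationIssue:
    """One named validation finding attached to specific rows."""

    severity: str          # "error" | "warning"
    rule: str              # short machine-readable rule name
    table: str
    subject_ids: list[str]
    message: str

    def to_dict(self) -> dict:
        return {
            "severity": self.severity, "rule": self.rule, "table": self.table,
            "subject_ids": list(self.subject_ids), "message": self.message,
        }


@dataclass
class ValidationReport:
    """Issues plus per-variable missingness counts (the Table-2-style audit)."""

    issues: list[ValidationIssue] = field(default_factory=list)
    missing_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def to_dict(self) -> dict:
        return {
            "n_errors": len(self.errors),
            "n_warnings": len(self.warnings),
            "issues": [i.to_dict() for i in self.issues],
            "missing_counts": self.missing_counts,
        }


class CohortValidationError(ValueError):
    """Raised when a cohort fails validation; carries the full report."""

    def __init__(self, report: ValidationReport):
        self.report = report
        lines = [f"{i.rule} [{i.table}] {i.message} (subjects: {i.subject_ids[:5]})"
                 for i in report.errors]
        super().__init__("cohort validation failed:\n" + "\n".join(lines))


@dataclass
class Cohort:
    """The three validated, linked tables plus the validation report."""

    maternal: pd.DataFrame
    newborn: pd.DataFrame
    interviews: pd.DataFrame
    report: ValidationReport = field(default_factory=ValidationReport)


# ---------------------------------------------------------------------------
# typing helpers

def _coerce(df: pd.DataFrame, int_cols=(), float_cols=(), flag_cols=()) -> pd.DataFrame:
    df = df.copy()
    for c in flag_cols:
        if c in df:
            df[c] = pd.to_numeric(df[c], errors="coerce").astype("Int64")
    for c in int_cols:
        if c in df:
            df[c] = pd.to_numeric(df[c], errors="coerce").round().astype("Int64")
    for c in float_cols:
        if c in df:
            df[c] = pd.to_numeric(df[c], errors="coerce").astype("Float64")
    for c in df.columns:
        if df[c].dtype == object:
            df[c] = df[c].where(pd.notna(df[c]), None)
    return df


def coerce_maternal(df: pd.DataFrame) -> pd.DataFrame:
    df = _coerce(
        df,
        int_cols=("age_years", "documented_infection_day"),
        float_cols=("gestation_weeks",),
        flag_cols=_MATERNAL_FLAGS,
    )
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def coerce_newborn(df: pd.DataFrame) -> pd.DataFrame:
    df = _coerce(df, int_cols=("apgar5", "documented_sepsis_day"), flag_cols=_NEWBORN_FLAGS)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def coerce_interviews(df: pd.DataFrame) -> pd.DataFrame:
    df = _coerce(df, int_cols=_INTERVIEW_INTS, flag_cols=_INTERVIEW_FLAGS)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


# ---------------------------------------------------------------------------
# validation

def _add(report, severity, rule, table, ids, message):
    report.issues.append(ValidationIssue(severity, rule, table, [str(s) for s in ids], message))


def validate_cohort(maternal: pd.DataFrame, newborn: pd.DataFrame,
                    interviews: pd.DataFrame) -> ValidationReport:
    """Validate the three tables; every offending row is attached to a named
    issue (no silent drops)."""
    report = ValidationReport()

    for name, df, expected in (
        ("maternal_case_notes", maternal, MATERNAL_COLUMNS),
        ("newborn_case_notes", newborn, NEWBORN_COLUMNS),
        ("interviews", interviews, INTERVIEW_COLUMNS),
    ):
        unknown = sorted(set(df.columns) - set(expected))
        if unknown:
            _add(report, "error", "unknown_columns", name, [],
                 f"unexpected columns: {unknown}")
        missing_cols = sorted(set(expected) - set(df.columns))
        if missing_cols:
            _add(report, "error", "missing_columns", name, [],
                 f"required columns absent: {missing_cols}")
    if report.errors:
        return report

    dup = maternal.loc[maternal["subject_id"].duplicated(), "subject_id"]
    if len(dup):
        _add(report, "error", "duplicate_subject_id", "maternal_case_notes",
             dup.unique().tolist(), "duplicate ID numbers")
    dup_n = newborn.loc[newborn["subject_id"].duplicated(), "subject_id"]
    if len(dup_n):
        _add(report, "error", "duplicate_subject_id", "newborn_case_notes",
             dup_n.unique().tolist(),
             "more than one newborn record per mother (singleton analysis only)")

    underage = maternal.loc[maternal["age_years"].notna() & (maternal["age_years"] < 18)]
    if len(underage):
        _add(report, "error", "eligibility_age", "maternal_case_notes",
             underage["subject_id"].tolist(),
             "eligibility requires women aged 18 years or older")

    bad_mode = maternal.loc[~maternal["delivery_mode"].isin(DELIVERY_MODES)]
    if len(bad_mode):
        _add(report, "error", "delivery_mode_invalid", "maternal_case_notes",
             bad_mode["subject_id"].tolist(), f"delivery_mode must be one of {DELIVERY_MODES}")

    bad_hosp = maternal.loc[~maternal["hospital"].isin(HOSPITALS)]
    if len(bad_hosp):
        _add(report, "error", "hospital_invalid", "maternal_case_notes",
             bad_hosp["subject_id"].tolist(), f"hospital must be one of {HOSPITALS}")

    cs = maternal["delivery_mode"] == "caesarean"
    peri_on_cs = maternal.loc[cs & (maternal["episiotomy"].notna() | maternal["perineal_tear"].notna())]
    if len(peri_on_cs):
        _add(report, "error", "perineal_fields_caesarean", "maternal_case_notes",
             peri_on_cs["subject_id"].tolist(),
             "episiotomy/perineal_tear only apply to vaginal deliveries")

    over_term = maternal.loc[maternal["gestation_weeks"].notna() & (maternal["gestation_weeks"] > 42)]
    if len(over_term):
        _add(report, "warning", "gestation_over_term", "maternal_case_notes",
             over_term["subject_id"].tolist(),
             "gestational age above the stated term range (37-42 weeks)")

    bad_apgar = newborn.loc[newborn["apgar5"].notna()
                            & (~newborn["apgar5"].between(0, 10))]
    if len(bad_apgar):
        _add(report, "error", "apgar_range", "newborn_case_notes",
             bad_apgar["subject_id"].tolist(), "apgar5 must lie in 0-10")

    orphan = newborn.loc[~newborn["subject_id"].isin(maternal["subject_id"])]
    if len(orphan):
        _add(report, "error", "unlinked_newborn", "newborn_case_notes",
             orphan["subject_id"].tolist(), "newborn record without maternal record")

    # interview-level checks
    iv = interviews
    bad_wave = iv.loc[~iv["wave"].isin(WAVES)]
    if len(bad_wave):
        _add(report, "error", "wave_invalid", "interviews",
             bad_wave["subject_id"].tolist(), f"wave must be one of {WAVES}")
    dup_wave = iv.loc[iv.duplicated(subset=["subject_id", "wave"])]
    if len(dup_wave):
        _add(report, "error", "duplicate_wave", "interviews",
             dup_wave["subject_id"].unique().tolist(), "one row per subject and wave")
    orphan_iv = iv.loc[~iv["subject_id"].isin(maternal["subject_id"])]
    if len(orphan_iv):
        _add(report, "error", "unlinked_interview", "interviews",
             orphan_iv["subject_id"].unique().tolist(), "interview without maternal record")

    reached = iv["reached"] == 1
    d7 = reached & (iv["wave"] == "day7")
    d28 = reached & (iv["wave"] == "day28")
    bad_d7 = iv.loc[d7 & ~iv["interview_day"].between(7, 14)]
    if len(bad_d7):
        _add(report, "error", "interview_day_range", "interviews",
             bad_d7["subject_id"].tolist(),
             "day-7 interview day must lie in 7-14 (four call attempts over seven days)")
    bad_d28 = iv.loc[d28 & ~iv["interview_day"].between(7, 43)]
    if len(bad_d28):
        _add(report, "error", "interview_day_range", "interviews",
             bad_d28["subject_id"].tolist(), "day-28 interview day must lie in 7-43")

    mode = maternal.drop_duplicates("subject_id").set_index("subject_id")["delivery_mode"]
    iv_mode = iv["subject_id"].map(mode)
    for prefix, stems in (("m_", MATERNAL_SYMPTOMS), ("n_", NEWBORN_SYMPTOMS)):
        for s in stems:
            col, onset = f"{prefix}{s}", f"{prefix}{s}_onset"
            present = iv[col] == 1
            mismatch = iv.loc[present & iv[onset].isna() | (~present.fillna(False) & iv[onset].notna())]
            if len(mismatch):
                _add(report, "error", "onset_presence_mismatch", "interviews",
                     mismatch["subject_id"].tolist(),
                     f"{s}: onset day present iff symptom present")
            late = iv.loc[present & iv[onset].notna() & iv["interview_day"].notna()
                          & (iv[onset] > iv["interview_day"])]
            if len(late):
                _add(report, "error", "onset_after_interview", "interviews",
                     late["subject_id"].tolist(), f"{s}: onset day after interview day")
    cs_cols = [f"m_{s}" for s in CS_SITE_SYMPTOMS]
    cs_on_vaginal = iv.loc[(iv_mode == "vaginal") & (iv[cs_cols] == 1).any(axis=1)]
    if len(cs_on_vaginal):
        _add(report, "error", "cs_symptoms_vaginal", "interviews",
             cs_on_vaginal["subject_id"].tolist(),
             "caesarean-site symptoms reported for a vaginal delivery")
    peri_cols = [f"m_{s}" for s in PERINEAL_SYMPTOMS]
    peri_on_cs_iv = iv.loc[(iv_mode == "caesarean") & (iv[peri_cols] == 1).any(axis=1)]
    if len(peri_on_cs_iv):
        _add(report, "error", "perineal_symptoms_caesarean", "interviews",
             peri_on_cs_iv["subject_id"].tolist(),
             "perineal-wound symptoms reported for a caesarean delivery")

    bad_epds = iv.loc[d28 & iv[list(EPDS_ITEMS)].notna().any(axis=1)
                      & ((iv[list(EPDS_ITEMS)] < 0).any(axis=1))]
    if len(bad_epds):
        _add(report, "error", "epds_item_range", "interviews",
             bad_epds["subject_id"].tolist(), "depression items must be non-negative")

    # missingness audit (counts of empty fields per variable)
    audit_vars = {
        "maternal_case_notes": ("age_years", "parity", "gestation_weeks",
                                "hypertensive_disorder", "hiv", "prom", "episiotomy",
                                "perineal_tear", "pph", "antibiotics_labour",
                                "antibiotics_postpartum"),
        "newborn_case_notes": ("apgar5", "resuscitation_bag_mask", "admission"),
    }
    for name, df in (("maternal_case_notes", maternal), ("newborn_case_notes", newborn)):
        report.missing_counts[name] = {
            v: int(df[v].isna().sum()) for v in audit_vars[name] if v in df
        }
    return report


# ---------------------------------------------------------------------------
# read / write

def read_cohort(maternal_path: str | Path, newborn_path: str | Path,
                interviews_path: str | Path, config: RunConfig | None = None,
                strict: bool = True) -> Cohort:
    """Read and validate the three cohort tables.

    Raises :class:`CohortValidationError` when ``strict`` and any error-level
    issue is found; warnings never block.
    """
    maternal = coerce_maternal(pd.read_csv(maternal_path, dtype=str))
    newborn = coerce_newborn(pd.read_csv(newborn_path, dtype=str))
    interviews = coerce_interviews(pd.read_csv(interviews_path, dtype=str))
    report = validate_cohort(maternal, newborn, interviews)
    if strict and report.errors:
        raise CohortValidationError(report)
    return Cohort(maternal, newborn, interviews, report)


def read_cohort_dir(directory: str | Path, config: RunConfig | None = None,
                    strict: bool = True) -> Cohort:
    d = Path(directory)
    return read_cohort(d / "maternal_case_notes.csv", d / "newborn_case_notes.csv",
                       d / "interviews.csv", config, strict)


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write the three tables as CSV with empty fields for missing values."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.maternal.to_csv(d / "maternal_case_notes.csv", index=False)
    cohort.newborn.to_csv(d / "newborn_case_notes.csv", index=False)
    cohort.interviews.to_csv(d / "interviews.csv", index=False)


# ---------------------------------------------------------------------------
# derived covariates

AGE_GROUPS = ("18-24", "25-29", "30plus")


def grouping(maternal: pd.DataFrame) -> pd.DataFrame:
    """Derive the grouped analysis covariates from the raw case-note fields.

    Age is grouped 18-24 / 25-29 / 30+; gestational age becomes a preterm
    flag (<37 weeks, missing propagated); parity keeps its four levels.
    """
    out = pd.DataFrame({"subject_id": maternal["subject_id"]})
    age = maternal["age_years"]
    out["age_group"] = pd.Series(
        pd.cut(age.astype("float"), bins=[17.5, 24.5, 29.5, 200],
               labels=AGE_GROUPS).astype(object),
        index=maternal.index,
    )
    gest = maternal["gestation_weeks"]
    preterm = pd.Series(pd.NA, index=maternal.index, dtype="Int64")
    preterm[gest.notna()] = (gest[gest.notna()] < 37).astype(int)
    out["preterm"] = preterm
    out["parity_group"] = maternal["parity"]
    return out
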