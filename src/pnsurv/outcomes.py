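"""Care-seeking, readmission, depression and maternal-function outcomes.

Covers the secondary analyses of the surveillance round: the highest level
of care sought per infection episode, readmission percentages by infection
status, the five-item depression score (grouped as no depression 0-5
versus possible depression 6-30), item-wise maternal-function difficulty,
and simple 2x2 associations (Pearson chi-squared, Wald odds ratio, or an
adjusted logistic odds ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CARE_LEVELS, EPDS_ITEMS, FUNCTION_ITEMS, Cohort
from .config import RunConfig

_CARE_ORDER = {lev: i for i, lev in enumerate(CARE_LEVELS)}  # none < ... < delivery


def _pct(n: int, N: int) -> float | None:
    """Percentage at reporting precision: integer from 10% up, 1 dp below."""
    if N == 0:
        return None
    x = n / N * 100
    return float(round(x)) if x >= 10 else round(x, 1)


@dataclass
class EpdsResult:
    subject_id: str
    total_score: int
    category: str           # "none" | "possible"


@dataclass
class TwoByTwo:
    """Counts a,b,c,d: rows = exposure (yes/no), columns = outcome (yes/no)."""

    a: int
    b: int
    c: int
    d: int
    row_label: str = "exposure"
    col_label: str = "outcome"

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class AssociationResult:
    method: str
    statistic: float | None
    or_estimate: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None
    flags: list[str]


def epds_classify(items: list[int], threshold: int = 6,
                  item_max: int = 6, subject_id: str = "") -> EpdsResult:
    """Sum the five depression items and apply the threshold grouping."""
    if len(items) != 5:
        raise ValueError("the depression scale has exactly five items")
    for x in items:
        if not (0 <= int(x) <= item_max):
            raise ValueError(f"item value {x} outside 0-{item_max}")
    total = int(sum(items))
    category = "possible" if total >= threshold else "none"
    return EpdsResult(subject_id, total, category)


def epds_table(cohort: Cohort, config: RunConfig | None = None) -> pd.DataFrame:
    """Depression classification for every completed day-28 interview."""
    config = config or RunConfig()
    iv = cohort.interviews
    d28 = iv[(iv["wave"] == "day28") & (iv["reached"] == 1)]
    rows = []
    for _, r in d28.iterrows():
        items = [r[c] for c in EPDS_ITEMS]
        if any(pd.isna(x) for x in items):
            continue
        res = epds_classify([int(x) for x in items], config.epds_threshold,
                            config.epds_item_max, r["subject_id"])
        rows.append((res.subject_id, res.total_score, res.category))
    return pd.DataFrame(rows, columns=["subject_id", "total_score", "category"])


# ---------------------------------------------------------------------------
# care-seeking and readmission

def care_seeking_summary(episodes: pd.DataFrame, interviews: pd.DataFrame,
                         population: str) -> dict:
    """Distribution of the highest care level sought per composite episode.

    Each episode is linked to the interview wave(s) that reported it;
    case-note-only episodes form their own stratum. Percentages are
    rounded to integers.
    """
    care_col = "care_level_mother" if population == "maternal" else "care_level_baby"
    ep = episodes[(episodes["population"] == population)
                  & episodes["in_primary_composite"]] if len(episodes) else episodes
    if not len(ep):
        return {"n_episodes": 0, "levels": {}, "facility_pct": None,
                "case_note_only": 0}
    iv = interviews[interviews["reached"] == 1]
    care = iv.pivot_table(index="subject_id", columns="wave", values=care_col,
                          aggfunc="first", observed=True)
    counts: dict[str, int] = {lev: 0 for lev in CARE_LEVELS}
    case_note_only = 0
    for _, r in ep.iterrows():
        waves = [s.removeprefix("interview_") for s in r["sources"].split("|")
                 if s.startswith("interview_")]
        if not waves:
            case_note_only += 1
            continue
        levels = []
        for w in waves:
            if r["subject_id"] in care.index and w in care.columns:
                lev = care.at[r["subject_id"], w]
                if pd.notna(lev):
                    levels.append(lev)
        best = max(levels, key=_CARE_ORDER.get) if levels else "none"
        counts[best] += 1
    n = sum(counts.values())
    facility = n - counts["none"]
    return {
        "n_episodes": n,
        "levels": {lev: {"n": c, "pct": round(c / n * 100) if n else None}
                   for lev, c in counts.items()},
        "facility_n": facility,
        "facility_pct": round(facility / n * 100) if n else None,
        "case_note_only": case_note_only,
    }


def readmission_summary(episodes: pd.DataFrame, cohort: Cohort,
                        config: RunConfig | None = None) -> dict:
    """Readmission percentage by early-infection status, per population.

    Uses the day-7 interview: subjects with a composite episode starting in
    the early window versus those without.
    """
    config = config or RunConfig()
    iv = cohort.interviews
    d7 = iv[(iv["wave"] == "day7") & (iv["reached"] == 1)].set_index("subject_id")
    out = {}
    for population, readm_col, alive_filter in (
        ("maternal", "readmitted_mother", False),
        ("newborn", "readmitted_baby", True),
    ):
        base = d7
        if alive_filter:
            base = d7[d7["baby_alive"] == 1]
        ep = episodes[(episodes["population"] == population)
                      & episodes["in_primary_composite"]
                      & (episodes["start_day"] <= config.early_window_end)] \
            if len(episodes) else episodes
        infected = set(ep["subject_id"]) if len(ep) else set()
        strata = {}
        for label, ids in (("with_infection", base.index.isin(infected)),
                           ("without_infection", ~base.index.isin(infected))):
            sub = base[ids]
            n, N = int((sub[readm_col] == 1).sum()), int(sub[readm_col].notna().sum())
            strata[label] = {"readmitted": n, "total": N, "pct": _pct(n, N)}
        out[population] = strata
    return out


# ---------------------------------------------------------------------------
# 2x2 associations

def association_2x2(table: TwoByTwo, method: str = "chi_squared",
                    alpha: float = 0.05, continuity_or: bool = True,
                    yates: bool = False) -> AssociationResult:
    """Association in a 2x2 table.

    ``chi_squared``: Pearson test (no continuity correction by default);
    ``or_wald``: odds ratio with a Wald log-scale CI (0.5 added to every
    cell when one is zero, flagged).
    """
    flags: list[str] = []
    t = table.table
    if method == "chi_squared":
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            return AssociationResult(method, None, None, None, None, None,
                                     ["zero_margin"])
        stat, p, _, _ = stats.chi2_contingency(t, correction=yates)
        return AssociationResult(method, float(stat), None, None, None, float(p), flags)
    if method == "or_wald":
        a, b, c, d = table.a, table.b, table.c, table.d
        if min(a, b, c, d) == 0:
            if not continuity_or:
                return AssociationResult(method, None, None, None, None, None,
                                         ["zero_cell"])
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            flags.append("continuity_0.5")
        or_ = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = stats.norm.ppf(1 - alpha / 2)
        zstat = np.log(or_) / se
        p = float(2 * stats.norm.sf(abs(zstat)))
        return AssociationResult(method, float(zstat), float(or_),
                                 float(np.exp(np.log(or_) - z * se)),
                                 float(np.exp(np.log(or_) + z * se)), p, flags)
    raise ValueError(f"unknown method {method!r}")


def logistic_adjusted_or(outcome: pd.Series, exposure: pd.Series,
                         adjust: pd.Series, alpha: float = 0.05) -> AssociationResult:
    """Exposure odds ratio adjusted for one binary covariate via logistic
    regression on subject-level rows."""
    df = pd.DataFrame({"y": outcome, "x": exposure, "z": adjust}).dropna().astype(float)
    X = sm.add_constant(df[["x", "z"]])
    fit = sm.GLM(df["y"], X, family=sm.families.Binomial()).fit()
    b, se = fit.params["x"], fit.bse["x"]
    z = stats.norm.ppf(1 - alpha / 2)
    return AssociationResult("logistic_adjusted", float(b / se), float(np.exp(b)),
                             float(np.exp(b - z * se)), float(np.exp(b + z * se)),
                             float(fit.pvalues["x"]), [])


def function_summary(cohort: Cohort, episodes: pd.DataFrame,
                     config: RunConfig | None = None) -> dict:
    """Item-wise difficulty percentages by early maternal infection, with a
    chi-squared p per item."""
    config = config or RunConfig()
    iv = cohort.interviews
    d28 = iv[(iv["wave"] == "day28") & (iv["reached"] == 1)].set_index("subject_id")
    ep = episodes[(episodes["population"] == "maternal")
                  & episodes["in_primary_composite"]
                  & (episodes["start_day"] <= config.early_window_end)] \
        if len(episodes) else episodes
    infected = set(ep["subject_id"]) if len(ep) else set()
    out = {}
    for item in FUNCTION_ITEMS:
        col = d28[item]
        rows = {}
        cells = {}
        for label, mask in (("yes", d28.index.isin(infected)),
                            ("no", ~d28.index.isin(infected))):
            sub = col[mask].dropna()
            rows[label] = {"n": int((sub == 1).sum()), "N": int(len(sub)),
                           "pct": round((sub == 1).mean() * 100, 1) if len(sub) else None}
            cells[label] = (int((sub == 1).sum()), int((sub == 0).sum()))
        tab = TwoByTwo(cells["yes"][0], cells["yes"][1], cells["no"][0], cells["no"][1])
        res = association_2x2(tab, "chi_squared")
        out[item] = {"infection": rows, "chi2_p": res.p}
    return out
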