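"""Risk-factor analysis front end.

Assembles the analysis covariates from the case-note tables, runs the
crude (one-factor) recurrent-event Cox fits, screens factors into the
adjusted model (a-priori confounders plus crude Wald p below the
threshold, capped at one parameter per ten events), imputes missing
covariates by chained equations and pools the adjusted fits with Rubin's
rules. Women whose case-notes were not located are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort, grouping
from .config import RunConfig
from .cox import CoxFit, ModelSpec, fit_recurrent_cox, schoenfeld_ph_test, screen_and_adjust
from .episodes import rates_by_factor
from .impute import MiceResult, PooledFit, mice_impute, pool_rubin

MATERNAL_FACTORS = ("delivery_mode", "age_group", "hospital", "parity_group",
                    "preterm", "antibiotics_labour", "antibiotics_postpartum")
NEWBORN_FACTORS = ("resuscitation_bag_mask", "antibiotics_labour", "delivery_mode",
                   "prom", "age_group", "hospital", "preterm",
                   "antibiotics_postpartum")
DEFAULT_A_PRIORI = {"maternal": ("age_group", "hospital"), "newborn": ()}
DEFAULT_REFERENCES = {"delivery_mode": "vaginal"}
NOT_IMPUTED_NOTE = "excluded from imputation (missing fraction above threshold)"


def analysis_covariates(cohort: Cohort) -> pd.DataFrame:
    """Subject-level categorical covariates (strings, NA for missing),
    indexed by subject_id; restricted to located case-notes."""
    m = cohort.maternal[cohort.maternal["case_note_available"] == 1]
    g = grouping(m).set_index("subject_id")
    m = m.set_index("subject_id")
    nb = cohort.newborn.set_index("subject_id")
    out = pd.DataFrame(index=m.index)
    out["delivery_mode"] = m["delivery_mode"]
    out["hospital"] = m["hospital"]
    out["age_group"] = g["age_group"]
    out["parity_group"] = m["parity"]
    for col in ("preterm",):
        out[col] = g[col].map({0: "0", 1: "1"})
    for col in ("antibiotics_labour", "antibiotics_postpartum", "prom", "hiv",
                "hypertensive_disorder", "pph"):
        out[col] = m[col].map({0: "0", 1: "1"})
    for col in ("resuscitation_bag_mask",):
        out[col] = nb.reindex(out.index)[col].map({0: "0", 1: "1"})
    return out.astype("object").where(out.notna(), pd.NA)


@dataclass
class RiskFactorResult:
    """Everything the risk-factor table needs."""

    population: str
    n_subjects: int
    n_events: int
    crude: dict[str, CoxFit]
    rates: dict[str, dict]
    spec: ModelSpec
    adjusted: PooledFit | CoxFit | None
    ph_test: dict[str, float] | None
    mice: MiceResult | None
    notes: list[str]


def risk_factor_analysis(cohort: Cohort, episodes: pd.DataFrame,
                         follow_up: pd.DataFrame, population: str,
                         config: RunConfig | None = None,
                         factors: tuple[str, ...] | None = None,
                         a_priori: tuple[str, ...] | None = None,
                         ties: str = "breslow") -> RiskFactorResult:
    """Run the crude, screened and imputation-adjusted analyses."""
    config = config or RunConfig()
    factors = tuple(factors if factors is not None else
                    (MATERNAL_FACTORS if population == "maternal" else NEWBORN_FACTORS))
    a_priori = tuple(a_priori if a_priori is not None
                     else DEFAULT_A_PRIORI[population])
    cov = analysis_covariates(cohort)
    fu = follow_up[follow_up["subject_id"].isin(cov.index)]
    ep = episodes[episodes["subject_id"].isin(cov.index)] if len(episodes) else episodes
    notes: list[str] = []

    crude: dict[str, CoxFit] = {}
    rates: dict[str, dict] = {}
    for fac in factors:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                crude[fac] = fit_recurrent_cox(
                    ep, fu, cov, [fac], population, ties=ties,
                    alpha=config.ci_alpha, references=DEFAULT_REFERENCES)
        except ValueError as exc:
            notes.append(f"crude fit failed for {fac}: {exc}")
            continue
        rates[fac] = {lev: r.to_dict() for lev, r in
                      rates_by_factor(ep, fu, population, cov[fac].dropna(),
                                      config).items()}

    n_events = max((f.n_events for f in crude.values()), default=0)
    crude_p = {fac: fit.factor_p[fac] for fac, fit in crude.items()}
    params = {fac: len(fit.terms) for fac, fit in crude.items()}
    spec = screen_and_adjust(crude_p, params, [f for f in a_priori if f in crude],
                             n_events, config)

    adjusted: PooledFit | CoxFit | None = None
    ph: dict[str, float] | None = None
    mice_result: MiceResult | None = None
    if spec.retained:
        table = cov[list(dict.fromkeys(list(spec.retained)
                                       + ["delivery_mode", "hospital"]))].copy()
        missing_frac = table.isna().mean()
        to_impute = [f for f in spec.retained if table[f].isna().any()]
        not_imputable = [f for f in to_impute
                         if missing_frac[f] > config.mice_max_missing_fraction]
        for f in not_imputable:
            notes.append(f"{f}: {NOT_IMPUTED_NOTE}")
        to_impute = [f for f in to_impute if f not in not_imputable]
        fit_kwargs = dict(ties=ties, alpha=config.ci_alpha,
                          references=DEFAULT_REFERENCES)
        if to_impute:
            mice_result = mice_impute(
                table, m=config.mice_m, cycles=config.mice_cycles,
                auxiliaries=["delivery_mode", "hospital"],
                max_missing_fraction=config.mice_max_missing_fraction,
                seed=config.random_seed, variables=to_impute)
            fits = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for completed in mice_result.datasets:
                    fits.append(fit_recurrent_cox(
                        ep, fu, completed, list(spec.retained), population,
                        **fit_kwargs))
            adjusted = pool_rubin(fits, alpha=config.ci_alpha)
            ph = schoenfeld_ph_test(fits[0])
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                adjusted = fit_recurrent_cox(ep, fu, table, list(spec.retained),
                                             population, **fit_kwargs)
            ph = schoenfeld_ph_test(adjusted)

    return RiskFactorResult(
        population=population, n_subjects=int(fu["subject_id"].nunique()),
        n_events=n_events, crude=crude, rates=rates, spec=spec,
        adjusted=adjusted, ph_test=ph, mice=mice_result, notes=notes)


def result_table(result: RiskFactorResult) -> dict:
    """JSON-friendly rendering mirroring the published risk-factor tables."""
    out = {
        "population": result.population,
        "n_subjects": result.n_subjects,
        "n_events": result.n_events,
        "parameter_cap": result.spec.parameter_cap,
        "factors": {},
        "notes": result.notes,
    }
    adj_terms = {}
    if result.adjusted is not None:
        for t in result.adjusted.terms:
            if hasattr(t, "estimate"):
                adj_terms[(t.factor, t.level)] = (t.hr, t.ci_low, t.ci_high)
            else:
                adj_terms[(t.factor, t.level)] = (t.hr, t.ci_low, t.ci_high)
    for fac, fit in result.crude.items():
        entry = {
            "crude_p": result.spec.crude_p.get(fac),
            "rates": result.rates.get(fac, {}),
            "levels": {},
            "in_adjusted": fac in result.spec.retained,
        }
        for t in fit.terms:
            lev = {"crude_hr": round(t.hr, 2),
                   "crude_ci": [round(t.ci_low, 2), round(t.ci_high, 2)]}
            if (fac, t.level) in adj_terms:
                hr, lo, hi = adj_terms[(fac, t.level)]
                lev["adjusted_hr"] = round(hr, 2)
                lev["adjusted_ci"] = [round(lo, 2), round(hi, 2)]
            entry["levels"][t.level] = lev
        if result.adjusted is not None and fac in result.spec.retained:
            entry["adjusted_p"] = result.adjusted.factor_p.get(fac)
        out["factors"][fac] = entry
    if result.ph_test is not None:
        out["ph_test"] = result.ph_test
    return out
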