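"""Recurrent-event proportional-hazards regression with clustered variance.

The model is an Andersen–Gill counting-process Cox regression: each
subject contributes one or more ``(start, stop]`` at-risk intervals, events
may recur within a subject, and the variance of the partial-likelihood
estimate is made robust to within-subject correlation with a sandwich
estimator clustered on the subject. Ties are handled with the Breslow
approximation by default (Efron available).

Also here: the Grambsch–Therneau test of the proportional-hazards
assumption based on scaled Schoenfeld residuals, and the covariate
screening rule used to build the adjusted model (a-priori confounders plus
factors with crude Wald p below a threshold, capped at a fixed fraction of
the event count).

Event days are integers (days since delivery); internally an event on day
``d`` is placed at time ``d + 0.5`` so that day-0 events fall strictly
inside the first at-risk interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig


@dataclass
class CoxTerm:
    """One non-reference covariate level in a fitted model."""

    factor: str
    level: str
    log_hr: float
    robust_se: float
    hr: float
    ci_low: float
    ci_high: float


@dataclass
class CoxFit:
    """A fitted counting-process Cox model."""

    terms: list[CoxTerm]
    factor_p: dict[str, float]          # robust Wald p per factor
    ties: str
    cluster: str
    n_subjects: int
    n_events: int
    beta: np.ndarray = field(repr=False)
    robust_cov: np.ndarray = field(repr=False)
    naive_cov: np.ndarray = field(repr=False)
    names: list[str] = field(default_factory=list)
    loglik: float = 0.0
    # internals needed by the PH test
    _schoenfeld: np.ndarray | None = field(default=None, repr=False)
    _event_times: np.ndarray | None = field(default=None, repr=False)
    _information: np.ndarray | None = field(default=None, repr=False)

    def term(self, factor: str, level: str) -> CoxTerm:
        for t in self.terms:
            if t.factor == factor and t.level == level:
                return t
        raise KeyError((factor, level))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.factor, t.level, t.hr, t.ci_low, t.ci_high, t.log_hr, t.robust_se)
             for t in self.terms],
            columns=["factor", "level", "hr", "ci_low", "ci_high",
                     "log_hr", "robust_se"],
        )


# ---------------------------------------------------------------------------
# core partial-likelihood machinery

def _loglik_derivs(beta, X, risk_mask, event_mask, d, ties):
    """Log partial likelihood, gradient and information (negative Hessian).

    ``risk_mask``/``event_mask`` are K x n boolean matrices over distinct
    event times; ``d`` the tie counts per event time.
    """
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X
    K, p = risk_mask.shape[0], X.shape[1]

    S0 = risk_mask @ w                       # (K,)
    S1 = risk_mask @ wx                      # (K, p)
    # S2 as K x p x p
    S2 = np.einsum("ki,i,ij,il->kjl", risk_mask, w, X, X, optimize=True)

    ev_x_sum = event_mask @ X                # (K, p)
    ll = float(np.sum(event_mask @ eta))
    grad = ev_x_sum.sum(axis=0)
    info = np.zeros((p, p))

    if ties == "breslow":
        ll -= float(np.sum(d * np.log(S0)))
        xbar = S1 / S0[:, None]
        grad -= (d[:, None] * xbar).sum(axis=0)
        V = S2 / S0[:, None, None] - np.einsum("kj,kl->kjl", xbar, xbar)
        info = np.einsum("k,kjl->jl", d, V)
    elif ties == "efron":
        S0D = event_mask @ w
        S1D = event_mask @ wx
        S2D = np.einsum("ki,i,ij,il->kjl", event_mask, w, X, X, optimize=True)
        for k in range(K):
            dk = int(d[k])
            fr = np.arange(dk) / dk
            s0 = S0[k] - fr * S0D[k]                      # (dk,)
            s1 = S1[k][None, :] - fr[:, None] * S1D[k]    # (dk, p)
            s2 = S2[k][None] - fr[:, None, None] * S2D[k]
            ll -= float(np.sum(np.log(s0)))
            xb = s1 / s0[:, None]
            grad -= xb.sum(axis=0)
            info += np.einsum("mjl->jl", s2 / s0[:, None, None]) \
                - np.einsum("mj,ml->jl", xb, xb)
    else:
        raise ValueError(f"unknown ties method {ties!r}")
    return ll, grad, info


def _newton(X, risk_mask, event_mask, d, ties, tol=1e-9, max_iter=50):
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _loglik_derivs(beta, X, risk_mask, event_mask, d, ties)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        new_beta = beta + step
        new_ll, new_grad, new_info = _loglik_derivs(new_beta, X, risk_mask,
                                                    event_mask, d, ties)
        halves = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _loglik_derivs(new_beta, X, risk_mask,
                                                        event_mask, d, ties)
            halves += 1
            if halves > 30:
                break
        converged = abs(new_ll - ll) < tol and np.max(np.abs(new_grad)) < 1e-6
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if converged:
            break
    return beta, ll, grad, info


def fit_cox(data: pd.DataFrame, covariate_cols: list[str],
            start_col: str = "start", stop_col: str = "stop",
            event_col: str = "event", cluster_col: str = "subject_id",
            ties: str = "breslow", alpha: float = 0.05,
            factor_of: dict[str, str] | None = None,
            level_of: dict[str, str] | None = None) -> CoxFit:
    """Fit the counting-process Cox model on prepared rows.

    ``data`` holds one row per at-risk interval with numeric covariate
    columns (dummy-coded); ``factor_of``/``level_of`` map a column name to
    the factor and level it encodes (defaults to the column name itself).
    """
    if (data[event_col] == 1).sum() < 1:
        raise ValueError("at least one event is required")
    X = data[covariate_cols].to_numpy(float)
    start = data[start_col].to_numpy(float)
    stop = data[stop_col].to_numpy(float)
    event = data[event_col].to_numpy(int)
    clusters = data[cluster_col].to_numpy()

    times = np.unique(stop[event == 1])
    risk_mask = (start[None, :] < times[:, None]) & (times[:, None] <= stop[None, :])
    event_mask = (stop[None, :] == times[:, None]) & (event[None, :] == 1)
    d = event_mask.sum(axis=1).astype(float)

    beta, ll, grad, info = _newton(X, risk_mask, event_mask, d, ties)
    naive_cov = np.linalg.inv(info)

    # score residuals (Breslow form) for the clustered sandwich
    w = np.exp(np.clip(X @ beta, -500, 500))
    S0 = risk_mask @ w
    S1 = risk_mask @ (w[:, None] * X)
    xbar = S1 / S0[:, None]                                   # (K, p)
    U = np.zeros_like(X)
    # delta_i * (x_i - xbar(t_i))
    for k in range(len(times)):
        rows = np.nonzero(event_mask[k])[0]
        U[rows] += X[rows] - xbar[k]
    # minus the at-risk correction
    A = (risk_mask * (d / S0)[:, None]).T                      # (n, K)
    U -= w[:, None] * (A.sum(axis=1)[:, None] * X - A @ xbar)

    order = pd.factorize(clusters)[0]
    G = np.zeros((order.max() + 1, X.shape[1]))
    np.add.at(G, order, U)
    B = G.T @ G
    robust_cov = naive_cov @ B @ naive_cov

    # Schoenfeld residuals, one row per event (Breslow-style averages)
    sch_rows = []
    sch_times = []
    for k in range(len(times)):
        for i in np.nonzero(event_mask[k])[0]:
            sch_rows.append(X[i] - xbar[k])
            sch_times.append(times[k])
    schoenfeld = np.array(sch_rows)
    event_times = np.array(sch_times)

    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(np.diag(robust_cov))
    factor_of = factor_of or {c: c for c in covariate_cols}
    level_of = level_of or {c: c for c in covariate_cols}
    terms = [
        CoxTerm(factor_of[c], level_of[c], float(b), float(s),
                float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s)))
        for c, b, s in zip(covariate_cols, beta, se)
    ]
    # robust Wald test per factor (joint across its levels)
    factor_p: dict[str, float] = {}
    for fac in dict.fromkeys(factor_of.values()):
        idx = [i for i, c in enumerate(covariate_cols) if factor_of[c] == fac]
        b = beta[idx]
        V = robust_cov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        factor_p[fac] = float(stats.chi2.sf(stat, len(idx)))

    return CoxFit(
        terms=terms, factor_p=factor_p, ties=ties, cluster=cluster_col,
        n_subjects=int(pd.unique(clusters).size), n_events=int(event.sum()),
        beta=beta, robust_cov=robust_cov, naive_cov=naive_cov,
        names=list(covariate_cols), loglik=ll,
        _schoenfeld=schoenfeld, _event_times=event_times, _information=info,
    )


# ---------------------------------------------------------------------------
# counting-process construction and the factor-level front end

def counting_process_rows(episodes: pd.DataFrame, follow_up: pd.DataFrame,
                          population: str) -> pd.DataFrame:
    """Split each subject's follow-up at event days.

    Subjects remain at risk through their full follow-up regardless of
    episodes; an event on day ``d`` occurs at time ``d + 0.5``.
    """
    fu = follow_up[(follow_up["population"] == population)
                   & (follow_up["exit_reason"] != "excluded")]
    ep = episodes[(episodes["population"] == population)
                  & episodes["in_primary_composite"]] if len(episodes) else episodes
    ev_by_subject: dict[str, list[float]] = {}
    if len(ep):
        for sid, grp in ep.groupby("subject_id"):
            ev_by_subject[sid] = sorted(grp["start_day"] + 0.5)
    rows = []
    for _, r in fu.iterrows():
        sid, exit_day = r["subject_id"], float(r["exit_day"])
        if exit_day <= 0:
            continue
        prev = 0.0
        for t in ev_by_subject.get(sid, []):
            t = min(t, exit_day)          # onset on the exit day itself
            if t <= prev:
                t = prev + 1e-6
            rows.append((sid, prev, t, 1))
            prev = t
        if prev < exit_day:
            rows.append((sid, prev, exit_day, 0))
    return pd.DataFrame(rows, columns=["subject_id", "start", "stop", "event"])


def fit_recurrent_cox(episodes: pd.DataFrame, follow_up: pd.DataFrame,
                      covariates: pd.DataFrame, factors: list[str],
                      population: str, ties: str = "breslow",
                      alpha: float = 0.05, cluster_col: str = "subject_id",
                      min_events_per_level: int = 0,
                      references: dict[str, str] | None = None) -> CoxFit:
    """Fit the recurrent-event model for a set of categorical factors.

    ``covariates`` is indexed by subject_id with one categorical column per
    factor; the first level in sort order is the reference unless
    ``references`` names one. Subjects with a missing value on any requested
    factor are dropped (complete-case); non-reference levels with no events
    are dropped with a warning.
    """
    references = references or {}
    rows = counting_process_rows(episodes, follow_up, population)
    df = rows.join(covariates[factors], on="subject_id")
    df = df.dropna(subset=factors)

    cols, factor_of, level_of = [], {}, {}
    for fac in factors:
        levels = sorted(pd.unique(df[fac].astype(str)))
        if fac in references:
            ref = str(references[fac])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent for {fac!r}")
            levels = [ref] + [lev for lev in levels if lev != ref]
        events_per_level = df[df["event"] == 1].groupby(df[fac].astype(str)).size()
        for lev in levels[1:]:
            n_ev = int(events_per_level.get(lev, 0))
            if n_ev <= min_events_per_level:
                warnings.warn(
                    f"dropping level {fac}={lev}: {n_ev} events", stacklevel=2)
                df = df[df[fac].astype(str) != lev]
                continue
            col = f"{fac}::{lev}"
            df[col] = (df[fac].astype(str) == lev).astype(float)
            cols.append(col)
            factor_of[col], level_of[col] = fac, lev
    if not cols:
        raise ValueError("no estimable covariate levels")
    return fit_cox(df, cols, cluster_col=cluster_col, ties=ties, alpha=alpha,
                   factor_of=factor_of, level_of=level_of)


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics

def schoenfeld_ph_test(fit: CoxFit, transform: str = "rank") -> dict[str, float]:
    """Grambsch–Therneau test of proportional hazards.

    Correlates (scaled) Schoenfeld residuals with a transform of event time
    per covariate, plus a global test (key ``"_global"``). Requires >=2
    events; fewer raise ``ValueError``.
    """
    s = fit._schoenfeld
    if s is None or len(s) < 2:
        raise ValueError("PH test requires a fit with at least two events")
    t = fit._event_times
    if transform == "rank":
        g = stats.rankdata(t)
    elif transform == "identity":
        g = t.astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    g = g - g.mean()
    gg = float(np.sum(g ** 2))
    d = len(s)
    Iinv = np.linalg.inv(fit._information)
    zvec = s.T @ g                                    # (p,)
    out: dict[str, float] = {}
    for j, name in enumerate(fit.names):
        num = d * float(Iinv[j] @ zvec)
        chi2 = num ** 2 / (d * Iinv[j, j] * gg)
        out[name] = float(stats.chi2.sf(chi2, 1))
    chi2_g = d / gg * float(zvec @ Iinv @ zvec)
    out["_global"] = float(stats.chi2.sf(chi2_g, len(fit.names)))
    return out


# ---------------------------------------------------------------------------
# covariate screening

@dataclass
class ModelSpec:
    """Adjusted-model specification produced by the screening rule."""

    retained: list[str]
    dropped_for_cap: list[str]
    parameter_cap: int
    n_parameters: int
    crude_p: dict[str, float]


def screen_and_adjust(crude_p: dict[str, float], params_per_factor: dict[str, int],
                      a_priori: list[str], n_events: int,
                      config: RunConfig | None = None) -> ModelSpec:
    """Select the adjusted-model factors.

    Retains the a-priori confounders plus every factor with crude Wald
    p below ``crude_screen_p``; if the total parameter count exceeds
    ``floor(events * params_per_event)``, non-a-priori factors are dropped
    in descending crude-p order (ties broken by factor name) until the cap
    holds. The a-priori set alone exceeding the cap is an error.
    """
    config = config or RunConfig()
    cap = int(np.floor(n_events * config.params_per_event))
    a_priori = sorted(a_priori)
    screened = sorted(f for f, p in crude_p.items()
                      if p < config.crude_screen_p and f not in a_priori)
    if sum(params_per_factor[f] for f in a_priori) > cap:
        raise ValueError(
            f"a-priori confounders alone need more than the cap of {cap} parameters")
    retained = list(a_priori) + screened
    dropped = []
    def n_params(fs):
        return sum(params_per_factor[f] for f in fs)
    # drop weakest screened factors (largest p, ties by name descending order
    # of (p, name) so the retained set never depends on input order)
    droppable = sorted(screened, key=lambda f: (-crude_p[f], f))
    while n_params(retained) > cap and droppable:
        f = droppable.pop(0)
        retained.remove(f)
        dropped.append(f)
    return ModelSpec(retained=retained, dropped_for_cap=dropped,
                     parameter_cap=cap, n_parameters=n_params(retained),
                     crude_p=dict(crude_p))
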