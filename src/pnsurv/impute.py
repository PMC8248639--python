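"""Multiple imputation by chained equations for categorical covariates.

Missing case-note covariates are filled by cycling per-variable
conditional draws: a logistic model for binary variables and a multinomial
(softmax) model for multi-level ones, each conditioning on every other
analysis variable plus the auxiliary variables (delivery mode and
hospital, which are always complete). Parameter uncertainty is propagated
by drawing the conditional-model coefficients from their asymptotic normal
distribution before each predictive draw. Variables missing more than a
configurable fraction are excluded from imputation entirely and left
missing.

The conditional fits use a Newton solver with a small L2 ridge
(lambda = 1e-4) so that quasi-separated categories — common in sparse
cohort strata — cannot produce divergent coefficients.

Per-imputation analyses are combined with Rubin's rules
(total variance = W + (1 + 1/m) B) with Barnard–Rubin small-sample degrees
of freedom; multi-level factors get a pooled multivariate Wald test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxFit

_RIDGE = 1e-4


# ---------------------------------------------------------------------------
# ridge-stabilised softmax regression (binary is the two-category case)

def _softmax_fit(X: np.ndarray, y: np.ndarray, n_cat: int,
                 max_iter: int = 50, tol: float = 1e-8):
    """MLE (with small ridge) of a multinomial logit; returns (B, cov).

    ``y`` holds category codes 0..n_cat-1; category 0 is the reference.
    ``B`` has shape (n_cat-1, p); ``cov`` covers vec(B) row-major.
    """
    n, p = X.shape
    k = n_cat - 1
    B = np.zeros((k, p))
    Y = np.zeros((n, k))
    for j in range(k):
        Y[:, j] = y == j + 1
    for _ in range(max_iter):
        eta = X @ B.T                       # (n, k)
        eta = np.clip(eta, -30, 30)
        expeta = np.exp(eta)
        denom = 1.0 + expeta.sum(axis=1)
        P = expeta / denom[:, None]         # (n, k)
        grad = np.empty(k * p)
        H = np.empty((k * p, k * p))
        for a in range(k):
            grad[a * p:(a + 1) * p] = X.T @ (P[:, a] - Y[:, a]) + _RIDGE * B[a]
            for b in range(k):
                wab = P[:, a] * ((a == b) - P[:, b])
                H[a * p:(a + 1) * p, b * p:(b + 1) * p] = X.T @ (wab[:, None] * X)
            H[a * p:(a + 1) * p, a * p:(a + 1) * p] += _RIDGE * np.eye(p)
        step = np.linalg.solve(H, grad)
        B = B - step.reshape(k, p)
        if np.max(np.abs(step)) < tol:
            break
    cov = np.linalg.inv(H)
    return B, cov


def _softmax_probs(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    eta = np.clip(X @ B.T, -30, 30)
    expeta = np.exp(eta)
    denom = 1.0 + expeta.sum(axis=1)
    probs = np.column_stack([1.0 / denom, expeta / denom[:, None]])
    return probs


# ---------------------------------------------------------------------------
# chained equations

@dataclass
class MiceResult:
    """Completed datasets plus a log of what was (not) imputed."""

    datasets: list[pd.DataFrame]
    imputed_variables: list[str]
    excluded_variables: dict[str, float]   # variable -> missing fraction
    m: int
    cycles: int


def _design(table: pd.DataFrame, predictors: list[str]) -> tuple[np.ndarray, list[str]]:
    """Dummy-code predictors (first sorted level = reference) + intercept."""
    cols = [np.ones(len(table))]
    names = ["_intercept"]
    for v in predictors:
        vals = table[v].astype(str)
        for lev in sorted(vals.unique())[1:]:
            cols.append((vals == lev).to_numpy(float))
            names.append(f"{v}::{lev}")
    return np.column_stack(cols), names


def mice_impute(table: pd.DataFrame, m: int = 10, cycles: int = 10,
                auxiliaries: list[str] | None = None,
                max_missing_fraction: float = 0.35,
                seed: int | np.random.Generator = 0,
                variables: list[str] | None = None) -> MiceResult:
    """Impute missing categorical values by chained equations.

    Parameters
    ----------
    table:
        Categorical columns (strings; missing as NA). Auxiliaries must be
        complete.
    variables:
        Columns eligible for imputation (default: every non-auxiliary
        column with at least one missing value).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    auxiliaries = auxiliaries or []
    for a in auxiliaries:
        if table[a].isna().any():
            raise ValueError(f"auxiliary variable {a!r} has missing values")
    candidates = variables if variables is not None else [
        c for c in table.columns if c not in auxiliaries and table[c].isna().any()
    ]
    frac = {v: float(table[v].isna().mean()) for v in candidates}
    excluded = {v: f for v, f in frac.items() if f > max_missing_fraction}
    to_impute = sorted((v for v in candidates if v not in excluded),
                       key=lambda v: frac[v])
    to_impute = [v for v in to_impute if table[v].isna().any()]

    if not to_impute:
        return MiceResult([table.copy() for _ in range(m)], [], excluded, m, cycles)

    levels = {v: sorted(table[v].dropna().astype(str).unique()) for v in to_impute}
    for v, levs in levels.items():
        if len(levs) < 2:
            raise ValueError(f"variable {v!r} has a single observed level {levs}")
    missing_mask = {v: table[v].isna() for v in to_impute}

    datasets = []
    for _ in range(m):
        work = table.copy()
        # initial fill: draw from the observed marginal
        for v in to_impute:
            obs = work[v].dropna().astype(str).to_numpy()
            idx = missing_mask[v]
            work.loc[idx, v] = rng.choice(obs, size=int(idx.sum()))
        for _cycle in range(cycles):
            for v in to_impute:
                predictors = [c for c in work.columns if c != v]
                X, names = _design(work, predictors)
                obs = ~missing_mask[v]
                # a predictor level present only among rows being imputed
                # cannot be estimated: name it rather than silently treating
                # it as reference
                fit_zero = X[obs.to_numpy()].sum(axis=0) == 0
                if fit_zero.any():
                    bad = [n for n, z in zip(names, fit_zero) if z]
                    raise ValueError(
                        f"levels absent among observed rows of {v!r}: {bad}")
                codes = pd.Categorical(work.loc[obs, v].astype(str),
                                       categories=levels[v]).codes
                B, cov = _softmax_fit(X[obs.to_numpy()], codes, len(levels[v]))
                draw = rng.multivariate_normal(B.ravel(), cov, method="cholesky")
                Bd = draw.reshape(B.shape)
                miss_idx = missing_mask[v].to_numpy()
                probs = _softmax_probs(X[miss_idx], Bd)
                u = rng.random(probs.shape[0])
                cat = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
                work.loc[missing_mask[v], v] = [levels[v][c] for c in cat]
        datasets.append(work)
    return MiceResult(datasets, to_impute, excluded, m, cycles)


# ---------------------------------------------------------------------------
# Rubin pooling

@dataclass
class PooledTerm:
    factor: str
    level: str
    estimate: float          # pooled log-HR
    within_var: float
    between_var: float
    total_var: float
    df: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class PooledFit:
    terms: list[PooledTerm]
    factor_p: dict[str, float]
    m: int
    names: list[str] = field(default_factory=list)

    def term(self, factor: str, level: str) -> PooledTerm:
        for t in self.terms:
            if t.factor == factor and t.level == level:
                return t
        raise KeyError((factor, level))


def _barnard_rubin(m: int, W: float, B: float, nu_com: float) -> float:
    if B <= 0:
        return 1e9
    r = (1 + 1 / m) * B / W if W > 0 else np.inf
    lam = (1 + 1 / m) * B / (W + (1 + 1 / m) * B)
    nu_old = (m - 1) / lam ** 2
    nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
    return 1.0 / (1.0 / nu_old + 1.0 / nu_obs)


def pool_rubin(fits: list[CoxFit], alpha: float = 0.05) -> PooledFit:
    """Pool identically specified per-imputation Cox fits by Rubin's rules."""
    if len(fits) < 2:
        raise ValueError("pooling requires at least two fits")
    m = len(fits)
    names = fits[0].names
    for f in fits[1:]:
        if f.names != names:
            raise ValueError(f"mismatched model terms: {f.names} vs {names}")
    Q = np.array([f.beta for f in fits])                    # (m, p)
    Vars = np.array([np.diag(f.robust_cov) for f in fits])  # (m, p)
    qbar = Q.mean(axis=0)
    W = Vars.mean(axis=0)
    B = Q.var(axis=0, ddof=1)
    T = W + (1 + 1 / m) * B
    nu_com = max(fits[0].n_events - len(names), 1)

    terms = []
    for j, name in enumerate(names):
        t0 = fits[0].terms[j]
        df = _barnard_rubin(m, W[j], B[j], nu_com)
        se = float(np.sqrt(T[j]))
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        p = float(2 * stats.t.sf(abs(qbar[j]) / se, df)) if se > 0 else 0.0
        terms.append(PooledTerm(
            factor=t0.factor, level=t0.level, estimate=float(qbar[j]),
            within_var=float(W[j]), between_var=float(B[j]), total_var=float(T[j]),
            df=float(df), hr=float(np.exp(qbar[j])),
            ci_low=float(np.exp(qbar[j] - tcrit * se)),
            ci_high=float(np.exp(qbar[j] + tcrit * se)), p=p,
        ))

    # multivariate Wald per factor (D1 pooling)
    factor_p: dict[str, float] = {}
    factors = dict.fromkeys(t.factor for t in fits[0].terms)
    for fac in factors:
        idx = [j for j, t in enumerate(fits[0].terms) if t.factor == fac]
        k = len(idx)
        qb = qbar[idx]
        Ubar = np.mean([f.robust_cov[np.ix_(idx, idx)] for f in fits], axis=0)
        Bm = np.cov(Q[:, idx].T, ddof=1).reshape(k, k)
        r1 = (1 + 1 / m) * np.trace(Bm @ np.linalg.inv(Ubar)) / k
        D1 = float(qb @ np.linalg.solve(Ubar, qb)) / (k * (1 + r1))
        t_df = k * (m - 1)
        if t_df > 4:
            df2 = 4 + (t_df - 4) * (1 + (1 - 2 / t_df) / r1) ** 2 if r1 > 0 else 1e9
        else:
            df2 = t_df * (1 + 1 / k) * (1 + 1 / r1) ** 2 / 2 if r1 > 0 else 1e9
        factor_p[fac] = float(stats.f.sf(D1, k, df2))
    return PooledFit(terms=terms, factor_p=factor_p, m=m, names=list(names))
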