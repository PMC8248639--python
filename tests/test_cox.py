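"""Cox fit oracles, clustered variance, PH diagnostics and screening."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from pnsurv.config import RunConfig
from pnsurv.cox import (counting_process_rows, fit_cox, fit_recurrent_cox,
                        schoenfeld_ph_test, screen_and_adjust)


def _single_event_frame(rng, n, beta, censor_scale=2.0):
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1 / np.exp(beta * x))
    c = rng.exponential(censor_scale, n)
    obs = np.minimum(t, c)
    ev = (t <= c).astype(int)
    return pd.DataFrame({"subject_id": np.arange(n), "start": 0.0,
                         "stop": obs, "event": ev, "x": x})


def test_fit_matches_brute_force_partial_likelihood():
    """Single covariate, 20 subjects: the Newton fit agrees to 1e-6 with a
    directly maximised Breslow partial likelihood."""
    rng = np.random.default_rng(0)
    df = _single_event_frame(rng, 20, 0.8)

    def neg_pl(beta):
        ll = 0.0
        for _, row in df[df["event"] == 1].iterrows():
            at_risk = df[df["stop"] >= row["stop"]]
            ll += beta * row["x"] - np.log(np.exp(beta * at_risk["x"]).sum())
        return -ll

    brute = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                            options={"xatol": 1e-10})
    fit = fit_cox(df, ["x"], ties="breslow")
    assert fit.beta[0] == pytest.approx(brute.x, abs=1e-6)


def test_fit_matches_lifelines_with_ties_and_clusters():
    """Efron ties on integer event days, sandwich variance clustered on the
    subject: agreement with the independent implementation."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(3)
    n = 150
    x = rng.integers(0, 2, n).astype(float)
    days = rng.integers(1, 15, n).astype(float)
    ev = rng.integers(0, 2, n)
    df = pd.DataFrame({"subject_id": np.arange(n), "start": 0.0, "stop": days,
                       "event": ev, "x": x})
    fit = fit_cox(df, ["x"], ties="efron")
    cph = lifelines.CoxPHFitter()
    cph.fit(df[["stop", "event", "x", "subject_id"]]
            .rename(columns={"stop": "T", "event": "E"}),
            "T", "E", cluster_col="subject_id")
    assert fit.beta[0] == pytest.approx(cph.params_.iloc[0], abs=1e-6)
    assert np.sqrt(fit.robust_cov[0, 0]) == pytest.approx(
        cph.standard_errors_.iloc[0], rel=0.05)


def test_null_covariate_estimate_near_zero():
    rng = np.random.default_rng(1)
    df = _single_event_frame(rng, 2000, 0.0)
    fit = fit_cox(df, ["x"])
    se = np.sqrt(fit.robust_cov[0, 0])
    assert abs(fit.beta[0]) < 3 * se


def test_robust_and_naive_se_agree_with_independent_subjects():
    """One interval per independent subject: the clustered sandwich should
    track the model-based variance closely."""
    rng = np.random.default_rng(8)
    df = _single_event_frame(rng, 4000, 0.5)
    fit = fit_cox(df, ["x"])
    robust = np.sqrt(fit.robust_cov[0, 0])
    naive = np.sqrt(fit.naive_cov[0, 0])
    assert robust == pytest.approx(naive, rel=0.15)


def test_requires_at_least_one_event():
    df = pd.DataFrame({"subject_id": [1, 2], "start": [0.0, 0.0],
                       "stop": [5.0, 6.0], "event": [0, 0], "x": [0.0, 1.0]})
    with pytest.raises(ValueError):
        fit_cox(df, ["x"])


# ---------------------------------------------------------------------------
# counting-process construction

def _fu(subject_rows):
    return pd.DataFrame(subject_rows, columns=["subject_id", "population",
                                               "entry_day", "exit_day",
                                               "exit_reason", "person_months"])


def _ep(rows):
    return pd.DataFrame(rows, columns=["subject_id", "population", "types",
                                       "start_day", "sources",
                                       "resolved_by_day7",
                                       "in_primary_composite"])


def test_counting_process_splits_at_events_and_keeps_full_followup():
    fu = _fu([("A", "maternal", 0, 29, "day28_interview", 29 / 30.4375)])
    ep = _ep([("A", "maternal", "UTI", 3, "interview_day7", False, True),
              ("A", "maternal", "UTI", 20, "interview_day28", False, True)])
    rows = counting_process_rows(ep, fu, "maternal")
    assert len(rows) == 3
    assert rows["event"].tolist() == [1, 1, 0]
    assert rows["stop"].tolist() == [3.5, 20.5, 29.0]
    assert rows["start"].tolist() == [0.0, 3.5, 20.5]


def test_event_on_exit_day_is_kept():
    fu = _fu([("A", "maternal", 0, 8, "day7_only", 8 / 30.4375)])
    ep = _ep([("A", "maternal", "UTI", 8, "interview_day7", False, True)])
    rows = counting_process_rows(ep, fu, "maternal")
    assert rows["event"].sum() == 1
    assert rows["stop"].max() <= 8.0


def test_recurrent_fit_with_reference_level():
    rng = np.random.default_rng(10)
    n = 400
    mode = np.where(rng.random(n) < 0.3, "caesarean", "vaginal")
    fu = _fu([(f"S{i}", "maternal", 0, 28, "day28_interview", 28 / 30.4375)
              for i in range(n)])
    ep_rows = []
    for i in range(n):
        p = 0.15 * (2.0 if mode[i] == "caesarean" else 1.0)
        if rng.random() < p:
            ep_rows.append((f"S{i}", "maternal", "UTI",
                            int(rng.integers(0, 28)), "interview_day7", False, True))
    cov = pd.DataFrame({"delivery_mode": mode},
                       index=pd.Index([f"S{i}" for i in range(n)],
                                      name="subject_id"))
    fit = fit_recurrent_cox(_ep(ep_rows), fu, cov, ["delivery_mode"], "maternal",
                            references={"delivery_mode": "vaginal"})
    term = fit.term("delivery_mode", "caesarean")
    assert term.hr > 1.0                      # vaginal is the reference
    assert term.hr == pytest.approx(np.exp(term.log_hr))
    assert term.ci_low < term.hr < term.ci_high


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics

def test_ph_test_returns_probabilities_on_trivial_fixture():
    rng = np.random.default_rng(2)
    df = _single_event_frame(rng, 60, 0.3)
    fit = fit_cox(df, ["x"])
    p = schoenfeld_ph_test(fit)
    assert 0.0 <= p["x"] <= 1.0
    assert 0.0 <= p["_global"] <= 1.0


def test_ph_test_requires_two_events():
    df = pd.DataFrame({"subject_id": [1, 2], "start": [0.0, 0.0],
                       "stop": [2.0, 5.0], "event": [1, 0], "x": [1.0, 0.0]})
    fit = fit_cox(df, ["x"])
    with pytest.raises(ValueError):
        schoenfeld_ph_test(fit)


def test_ph_test_detects_time_varying_effect():
    """A strongly time-increasing covariate effect is flagged in most
    replicates."""
    rng = np.random.default_rng(6)
    rejected = 0
    reps = 20
    for _ in range(reps):
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        T = np.full(n, np.inf)
        for d in range(1, 31):
            lam = 0.04 * np.exp(x * 0.15 * (d - 15))
            hit = (rng.random(n) < 1 - np.exp(-lam)) & np.isinf(T)
            T[hit] = d
        ev = (~np.isinf(T)).astype(int)
        obs = np.where(np.isinf(T), 30.0, T)
        df = pd.DataFrame({"subject_id": np.arange(n), "start": 0.0,
                           "stop": obs, "event": ev, "x": x})
        fit = fit_cox(df, ["x"])
        rejected += schoenfeld_ph_test(fit)["_global"] < 0.05
    assert rejected / reps > 0.8


# ---------------------------------------------------------------------------
# screening

def test_parameter_cap_is_ten_percent_of_events():
    spec = screen_and_adjust({"a": 0.5}, {"a": 1}, [], 56, RunConfig())
    assert spec.parameter_cap == 5


def test_crude_p_above_threshold_excluded():
    crude = {"delivery_mode": 0.02, "antibiotics_labour": 0.17}
    spec = screen_and_adjust(crude, {"delivery_mode": 1, "antibiotics_labour": 1},
                             [], 56, RunConfig())
    assert "antibiotics_labour" not in spec.retained
    assert "delivery_mode" in spec.retained


def test_a_priori_always_retained():
    crude = {"age_group": 0.6, "hospital": 0.9, "delivery_mode": 0.02}
    spec = screen_and_adjust(crude, {"age_group": 2, "hospital": 1,
                                     "delivery_mode": 1},
                             ["age_group", "hospital"], 56, RunConfig())
    assert set(spec.retained) == {"age_group", "hospital", "delivery_mode"}


def test_cap_drops_weakest_screened_factor():
    crude = {"a": 0.01, "b": 0.05, "c": 0.09}
    spec = screen_and_adjust(crude, {"a": 2, "b": 2, "c": 2}, [], 40, RunConfig())
    # cap 4: c (largest p) dropped
    assert spec.retained == ["a", "b"]
    assert spec.dropped_for_cap == ["c"]


def test_screening_is_order_independent():
    crude = {"b": 0.05, "a": 0.05, "c": 0.01}
    params = {"a": 2, "b": 2, "c": 2}
    s1 = screen_and_adjust(dict(sorted(crude.items())), params, [], 40)
    s2 = screen_and_adjust(dict(sorted(crude.items(), reverse=True)), params,
                           [], 40)
    assert s1.retained == s2.retained
    # p ties broken deterministically by name ('a' dropped first)
    assert s1.retained == ["b", "c"]


def test_a_priori_exceeding_cap_errors():
    with pytest.raises(ValueError):
        screen_and_adjust({"a": 0.5}, {"a": 3}, ["a"], 10, RunConfig())


def test_zero_candidates_crude_only():
    spec = screen_and_adjust({"a": 0.5, "b": 0.9}, {"a": 1, "b": 1}, [], 56)
    assert spec.retained == []
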