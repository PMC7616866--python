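"""Survival primitives against hand-computed oracles, closed forms, and the
independent lifelines implementation."""

import numpy as np
import pandas as pd
import pytest

from ecgpheno.survival import (adjusted_phenogroup_hr, cox_fit, km_estimate,
                               logrank_test)
from ecgpheno.synthetic import simulate_survival


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_no_censoring_matches_hand_product_limit():
    curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
    np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
    np.testing.assert_array_equal(curve.n_risk, [3, 2, 1])


def test_km_with_censoring_matches_hand_risk_sets():
    # times 1, 2+ (censored), 3: S(1) = 2/3; at t=3 the risk set is {3} so
    # S(3) = 2/3 * (1 - 1/1) = 0
    curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
    np.testing.assert_array_equal(curve.times, [1.0, 3.0])
    np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])


def test_km_all_censored_is_identically_one():
    curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
    assert curve.times.size == 0
    assert curve.survival_at(5.0) == 1.0


def test_km_without_censoring_equals_empirical_survival():
    rng = np.random.default_rng(0)
    t = rng.exponential(2.0, 200)
    curve = km_estimate(t, np.ones(200, dtype=int))
    for q in (0.5, 1.0, 2.0):
        np.testing.assert_allclose(curve.survival_at(q), (t > q).mean(),
                                   atol=1e-12)


def test_km_matches_lifelines():
    from lifelines import KaplanMeierFitter
    rng = np.random.default_rng(1)
    t = rng.exponential(3.0, 150)
    e = rng.integers(0, 2, 150)
    t = np.round(t, 1) + 0.1  # force ties, keep times positive
    curve = km_estimate(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    ours = [curve.survival_at(x) for x in curve.times]
    theirs = [float(kmf.predict(x)) for x in curve.times]
    np.testing.assert_allclose(ours, theirs, atol=1e-10)


def test_km_input_validation():
    with pytest.raises(ValueError):
        km_estimate([], [])
    with pytest.raises(ValueError):
        km_estimate([0.0, 1.0], [1, 1])
    with pytest.raises(ValueError):
        km_estimate([1.0], [2])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups_is_null():
    t = [1.0, 2.0, 3.0, 4.0]
    e = [1, 0, 1, 1]
    res = logrank_test(t + t, e + e, ["a"] * 4 + ["b"] * 4)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 1


def _hand_logrank(times, events, groups):
    """Independent O/E computation by explicit risk-table enumeration."""
    times, events = np.asarray(times, float), np.asarray(events)
    groups = np.asarray(groups)
    uniq = sorted(set(groups))
    O = {g: 0.0 for g in uniq}
    E = {g: 0.0 for g in uniq}
    V = np.zeros((len(uniq), len(uniq)))
    for et in sorted(set(times[events == 1])):
        risk = [i for i in range(len(times)) if times[i] >= et]
        dead = [i for i in risk if times[i] == et and events[i] == 1]
        n, d = len(risk), len(dead)
        for a, ga in enumerate(uniq):
            n_a = sum(1 for i in risk if groups[i] == ga)
            O[ga] += sum(1 for i in dead if groups[i] == ga)
            E[ga] += d * n_a / n
            for b, gb in enumerate(uniq):
                n_b = sum(1 for i in risk if groups[i] == gb)
                if n > 1:
                    V[a, b] += (d * (n - d) / (n - 1)
                                * ((n_a / n) * (a == b) - n_a * n_b / n ** 2))
    z = np.array([O[g] - E[g] for g in uniq])[:-1]
    return float(z @ np.linalg.solve(V[:-1, :-1], z))


def test_logrank_three_groups_matches_hand_tables():
    times = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
    events = [1, 1, 0, 1, 1, 0]
    groups = ["a", "b", "c", "a", "c", "b"]
    res = logrank_test(times, events, groups)
    assert res.df == 2
    assert res.statistic == pytest.approx(
        _hand_logrank(times, events, groups), abs=1e-10)


def test_logrank_matches_lifelines():
    from lifelines.statistics import multivariate_logrank_test
    rng = np.random.default_rng(2)
    t = np.round(rng.exponential(2.0, 120), 1) + 0.1
    e = rng.integers(0, 2, 120)
    g = rng.choice(["a", "b", "c"], 120)
    res = logrank_test(t, e, g)
    ref = multivariate_logrank_test(t, g, e)
    assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
    assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_detects_threefold_hazard_ratio():
    """Power check: exponential arms with hazard ratio 3, n=200/arm."""
    hits = 0
    for rep in range(100):
        rng = np.random.default_rng(1000 + rep)
        df = simulate_survival(["A"] * 200 + ["B"] * 200, 0.5,
                               {"A": 1.0, "B": 3.0}, 2.0, rng)
        res = logrank_test(df["time_years"], df["event"],
                           ["A"] * 200 + ["B"] * 200)
        hits += res.p_value < 0.001
    assert hits >= 95


def test_logrank_single_group_rejected():
    with pytest.raises(ValueError):
        logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def _hand_partial_loglik(beta, times, events, x):
    """No-ties partial likelihood, written out the slow way."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def test_cox_matches_grid_search_of_hand_partial_likelihood():
    rng = np.random.default_rng(3)
    n = 40
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / np.exp(0.8 * x))
    t += rng.uniform(0, 1e-6, n)  # ensure no ties
    e = np.ones(n, dtype=int)
    fit = cox_fit(t, e, x)
    grid = np.arange(-3.0, 3.0, 1e-4)
    lls = [_hand_partial_loglik(b, t, e, x) for b in grid]
    beta_grid = grid[int(np.argmax(lls))]
    assert abs(fit.coef[0] - beta_grid) < 1e-4
    assert fit.converged


def test_cox_matches_lifelines_with_ties():
    from lifelines import CoxPHFitter
    rng = np.random.default_rng(4)
    n = 300
    x = np.column_stack([rng.integers(0, 2, n), rng.normal(size=n)])
    t = np.ceil(rng.exponential(2.0 / np.exp(0.7 * x[:, 0] - 0.3 * x[:, 1])))
    e = (t <= 4).astype(int)
    t = np.minimum(t, 4.0)
    fit = cox_fit(t, e, x, ties="efron")
    df = pd.DataFrame({"t": t, "e": e, "x0": x[:, 0], "x1": x[:, 1]})
    ref = CoxPHFitter().fit(df, duration_col="t", event_col="e")
    np.testing.assert_allclose(fit.coef, ref.params_.to_numpy(), atol=1e-5)
    np.testing.assert_allclose(fit.se, ref.standard_errors_.to_numpy(),
                               atol=1e-5)


def test_efron_equals_breslow_without_ties():
    rng = np.random.default_rng(5)
    n = 80
    x = rng.normal(size=(n, 2))
    t = rng.exponential(1.0, n) + rng.uniform(0, 1e-9, n)
    e = rng.integers(0, 2, n)
    e[:5] = 1
    f1 = cox_fit(t, e, x, ties="efron")
    f2 = cox_fit(t, e, x, ties="breslow")
    np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-10)
    np.testing.assert_allclose(f1.log_likelihood, f2.log_likelihood,
                               atol=1e-8)


def test_cox_invariant_to_monotone_time_transform():
    rng = np.random.default_rng(6)
    n = 120
    x = rng.normal(size=(n, 1))
    t = rng.exponential(1.0 / np.exp(0.5 * x[:, 0]))
    e = rng.integers(0, 2, n)
    e[:5] = 1
    f1 = cox_fit(t, e, x)
    f2 = cox_fit(np.exp(t), e, x)      # strictly monotone transform
    np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-8)


def test_cox_null_covariate_within_sampling_error():
    hits = 0
    for rep in range(30):
        rng = np.random.default_rng(2000 + rep)
        x = rng.normal(size=(500, 1))
        t = rng.exponential(1.0, 500)
        e = (t <= 2.0).astype(int)
        fit = cox_fit(np.minimum(t, 2.0), e, x)
        hits += abs(fit.coef[0]) < 3 * fit.se[0]
    assert hits >= 27


def test_cox_hr_and_ci_consistency():
    rng = np.random.default_rng(7)
    x = rng.integers(0, 2, 200).astype(float)
    t = rng.exponential(1.0 / np.exp(1.0 * x))
    fit = cox_fit(t, np.ones(200, int), x)
    assert fit.hr[0] == pytest.approx(np.exp(fit.coef[0]))
    assert fit.ci_lower[0] < fit.hr[0] < fit.ci_upper[0]


def test_cox_flags_monotone_likelihood():
    # perfect separation: all events in x=1 happen before all x=0 times
    t = np.concatenate([np.arange(1, 11), np.arange(20, 30)]).astype(float)
    x = np.concatenate([np.ones(10), np.zeros(10)])
    e = np.ones(20, dtype=int)
    with pytest.warns(RuntimeWarning, match="monotone"):
        fit = cox_fit(t, e, x)
    assert not fit.converged


def test_cox_rejects_constant_covariate_and_bad_times():
    with pytest.raises(ValueError, match="constant"):
        cox_fit([1.0, 2.0], [1, 1], [1.0, 1.0])
    with pytest.raises(ValueError):
        cox_fit([-1.0, 2.0], [1, 1], [0.0, 1.0])


# ---------------------------------------------------------------------------
# adjusted phenogroup hazard ratios
# ---------------------------------------------------------------------------

def _assignment(groups):
    return pd.DataFrame({"subject_id": [f"S{i}" for i in range(len(groups))],
                         "phenogroup": groups})


def test_empty_covariate_spec_equals_plain_indicator_fit():
    rng = np.random.default_rng(8)
    groups = np.array(["A", "B"])[rng.integers(0, 2, 400)]
    surv = simulate_survival(groups, 0.1, {"A": 1.0, "B": 2.0}, 5.0, rng)
    fit = adjusted_phenogroup_hr(surv, _assignment(groups), [])
    plain = cox_fit(surv["time_years"], surv["event"],
                    (groups == "B").astype(float))
    np.testing.assert_allclose(fit.coef, plain.coef, atol=1e-10)


def test_adjustment_with_independent_covariates_changes_little():
    rng = np.random.default_rng(9)
    groups = np.array(["A", "B"])[rng.integers(0, 2, 2000)]
    surv = simulate_survival(groups, 0.05, {"A": 1.0, "B": 2.57}, 5.0, rng)
    surv["age"] = rng.normal(55, 10, 2000)
    surv["sex"] = rng.integers(0, 2, 2000)
    unadj = adjusted_phenogroup_hr(surv, _assignment(groups), [])
    adj = adjusted_phenogroup_hr(surv, _assignment(groups), ["age", "sex"])
    assert abs(adj.coef[0] - unadj.coef[0]) < 3 * unadj.se[0]


def test_adjustment_corrects_age_confounding():
    """Older subjects preferentially in B and age itself hazardous: the
    adjusted hazard ratio lands nearer the generating multiplier."""
    rng = np.random.default_rng(10)
    n = 4000
    groups = np.array(["A", "B"])[rng.integers(0, 2, n)]
    age = rng.normal(55, 8, n) + 10.0 * (groups == "B")
    surv = simulate_survival(groups, 0.04, {"A": 1.0, "B": 2.0}, 5.0, rng,
                             age=age, age_log_hr=0.06)
    surv["age"] = age
    truth = np.log(2.0)
    unadj = adjusted_phenogroup_hr(surv, _assignment(groups), [])
    adj = adjusted_phenogroup_hr(surv, _assignment(groups), ["age"])
    assert abs(adj.coef[0] - truth) < abs(unadj.coef[0] - truth)
    assert abs(adj.coef[0] - truth) < 3 * adj.se[0]


def test_missing_covariates_named_in_error():
    groups = np.array(["A", "B", "A", "B"])
    surv = simulate_survival(groups, 0.1, rng=np.random.default_rng(0))
    with pytest.raises(ValueError, match="bmi"):
        adjusted_phenogroup_hr(surv, _assignment(groups), ["bmi"])
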