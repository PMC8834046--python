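"""Kaplan–Meier, log-rank, Cox, PH check and the maximally selected cutpoint."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from ginscore.survival import (
    MaxstatCutpoint,
    SurvivalError,
    cox_fit,
    dichotomize,
    km_estimate,
    logrank_scores,
    logrank_test,
    maxstat_cutoff,
    ph_assumption_check,
    read_clinical_table,
)


def surv_df(times, events, **covs):
    idx = [f"P{i}" for i in range(len(times))]
    return pd.DataFrame({"time": times, "event": events, **covs}, index=idx)


def naive_logrank_chi2(ta, ea, tb, eb):
    """Independent O-E/V log-rank chi-square from an explicit risk-set table."""
    all_times = sorted({t for t, e in zip(list(ta) + list(tb), list(ea) + list(eb)) if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        n_a = sum(1 for x in ta if x >= t)
        n_b = sum(1 for x in tb if x >= t)
        d_a = sum(1 for x, e in zip(ta, ea) if x == t and e == 1)
        d_b = sum(1 for x, e in zip(tb, eb) if x == t and e == 1)
        n, d = n_a + n_b, d_a + d_b
        if n == 0:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def naive_maxstat(x, time, event, minprop):
    """Exhaustive-scan oracle: per-candidate loops, no shared vectorized code."""
    n = len(x)
    # log-rank scores via a per-subject Nelson-Aalen loop
    scores = []
    for i in range(n):
        h = 0.0
        for t in sorted(set(time)):
            if t > time[i]:
                break
            d = sum(1 for j in range(n) if time[j] == t and event[j] == 1)
            at_risk = sum(1 for j in range(n) if time[j] >= t)
            h += d / at_risk
        scores.append(event[i] - h)
    scores = np.asarray(scores)
    a_bar = scores.mean()
    ssq = sum((s - a_bar) ** 2 for s in scores)
    n_min = int(np.ceil(minprop * n))
    best = None
    distinct = sorted(set(x))
    for lo, hi in zip(distinct, distinct[1:]):
        cut = (lo + hi) / 2.0
        low_idx = [i for i in range(n) if x[i] <= cut]
        k = len(low_idx)
        if k < n_min or n - k < n_min:
            continue
        s = sum(scores[i] for i in low_idx)
        z = (s - k * a_bar) / np.sqrt(k * (n - k) / (n * (n - 1.0)) * ssq)
        if best is None or abs(z) > abs(best[1]) + 1e-12:
            best = (cut, z)
    return best


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate(surv_df([5, 8, 12], [0, 0, 0]))
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_three_events_product_limit(self):
        curve = km_estimate(surv_df([1, 2, 3], [1, 1, 1]))
        assert np.allclose(curve.event_times, [1, 2, 3])
        assert np.allclose(curve.survival_probs, [2 / 3, 1 / 3, 0.0])
        assert np.allclose(curve.at_risk, [3, 2, 1])

    def test_censoring_between_events(self):
        # events at 1, 3, 4; censoring at 2 shrinks the risk set at t=3
        curve = km_estimate(surv_df([1, 2, 3, 4], [1, 0, 1, 1]))
        assert np.allclose(curve.survival_probs, [3 / 4, 3 / 8, 0.0])

    def test_time_scaling_leaves_probabilities(self):
        a = km_estimate(surv_df([1, 2, 3, 4], [1, 0, 1, 1]))
        b = km_estimate(surv_df([10, 20, 30, 40], [1, 0, 1, 1]))
        assert np.allclose(a.survival_probs, b.survival_probs)
        assert np.allclose(b.event_times, a.event_times * 10)

    def test_curve_is_monotone_in_unit_interval(self, rng):
        t = rng.exponential(10, size=50)
        e = rng.integers(0, 2, size=50)
        e[0] = 1
        curve = km_estimate(surv_df(t, e))
        assert np.all(np.diff(curve.survival_probs) <= 1e-12)
        assert np.all((curve.survival_probs >= 0) & (curve.survival_probs <= 1))

    def test_negative_time_rejected(self):
        with pytest.raises(SurvivalError, match="negative"):
            km_estimate(surv_df([-1, 2], [1, 1]))


class TestLogrank:
    def test_identical_groups_null(self):
        a = surv_df([1, 2, 3, 4], [1, 0, 1, 1])
        res = logrank_test(a, a.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_risk_set_computation(self):
        ta, ea = [1.0, 3.0, 5.0], [1, 1, 0]
        tb, eb = [2.0, 4.0, 6.0], [1, 0, 1]
        res = logrank_test(surv_df(ta, ea), surv_df(tb, eb))
        assert res.statistic == pytest.approx(naive_logrank_chi2(ta, ea, tb, eb), rel=1e-9)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(10):
            ta = np.round(rng.exponential(10, 12), 1)
            tb = np.round(rng.exponential(6, 15), 1)
            ea = rng.integers(0, 2, 12)
            eb = rng.integers(0, 2, 15)
            if ea.sum() + eb.sum() == 0:
                continue
            res = logrank_test(surv_df(ta, ea), surv_df(tb, eb))
            assert res.statistic == pytest.approx(
                naive_logrank_chi2(ta, ea, tb, eb), rel=1e-6
            )

    def test_label_swap_invariance(self):
        a = surv_df([1, 2, 5, 7], [1, 1, 0, 1])
        b = surv_df([3, 4, 6], [1, 0, 1])
        assert logrank_test(a, b).p_value == pytest.approx(logrank_test(b, a).p_value)

    def test_zero_events_error(self):
        with pytest.raises(SurvivalError, match="no events"):
            logrank_test(surv_df([1, 2], [0, 0]), surv_df([3], [0]))


# 20-patient fixture with tied event times; reference values computed once
# with R survival::coxph(Surv(time, event) ~ x, ties="efron"), frozen here.
COX_FIXTURE = pd.DataFrame(
    {
        "time": [33, 18, 40, 3, 3, 13, 22, 8, 3, 9, 2, 10, 17, 4, 22, 2, 3, 4, 14, 4],
        "event": [0, 0, 0, 1, 1, 1, 0, 0, 1, 1, 1, 1, 0, 1, 0, 1, 1, 1, 0, 1],
        "x": [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
    },
    index=[f"P{i}" for i in range(20)],
)
R_COXPH_COEF = 0.8273746484
R_COXPH_SE = 0.6242634285
R_COXPH_P = 0.1850513149


class TestCox:
    def test_matches_r_reference_fit(self):
        fit = cox_fit(COX_FIXTURE, ["x"])
        assert fit.coefficients["x"] == pytest.approx(R_COXPH_COEF, abs=1e-6)
        assert fit.p_values["x"] == pytest.approx(R_COXPH_P, abs=1e-6)
        se = (np.log(fit.ci95.loc["x", "upper"]) - fit.coefficients["x"]) / 1.959963985
        assert se == pytest.approx(R_COXPH_SE, abs=1e-6)
        assert fit.n_events == 12

    def test_ci_brackets_hazard_ratio(self):
        fit = cox_fit(COX_FIXTURE, ["x"])
        hr = fit.hazard_ratios["x"]
        assert fit.ci95.loc["x", "lower"] < hr < fit.ci95.loc["x", "upper"]
        assert hr > 0

    def test_categorical_reference_coding(self, rng):
        events = rng.integers(0, 2, 60)
        events[0] = 1
        df = surv_df(
            rng.exponential(10, 60),
            events,
            arm=rng.choice(["13cRA", "RP", "RP+BC"], 60),
        )
        fit = cox_fit(df, ["arm"])
        # 3-level factor -> 2 reference-coded indicators
        assert len(fit.coefficients) == 2
        assert all(name.startswith("arm_") for name in fit.coefficients.index)

    def test_constant_covariate_error(self):
        df = COX_FIXTURE.assign(flat=1.0)
        with pytest.raises(SurvivalError, match="constant"):
            cox_fit(df, ["flat"])

    def test_no_events_error(self):
        df = surv_df([1, 2, 3], [0, 0, 0], x=[0, 1, 0])
        with pytest.raises(SurvivalError, match="event"):
            cox_fit(df, ["x"])

    def test_null_covariate_ci_coverage(self):
        """A covariate independent of outcome: 95% Wald CI covers HR=1 ~95% of the time."""
        rng = np.random.default_rng(2024)
        covered = 0
        n_rep = 300
        for _ in range(n_rep):
            n = 60
            t = rng.exponential(20, n)
            c = rng.uniform(0, 40, n)
            df = surv_df(np.minimum(t, c), (t <= c).astype(int), x=rng.integers(0, 2, n))
            fit = cox_fit(df, ["x"])
            covered += fit.ci95.loc["x", "lower"] <= 1.0 <= fit.ci95.loc["x", "upper"]
        assert covered / n_rep >= 0.93


class TestPhCheck:
    def test_one_result_per_covariate(self, rng):
        df = surv_df(
            rng.exponential(10, 80),
            rng.integers(0, 2, 80),
            x=rng.normal(size=80),
            arm=rng.choice(["a", "b", "c"], 80),
        )
        fit = cox_fit(df, ["x", "arm"])
        results = ph_assumption_check(fit)
        assert set(results) == set(fit.coefficients.index)
        assert all(0 <= r.p_value <= 1 for r in results.values())

    def test_calibrated_under_proportional_hazards(self):
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 100
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(1.0 / (0.05 * np.exp(0.7 * x)))
            c = rng.uniform(0, 40, n)
            df = surv_df(np.minimum(t, c), (t <= c).astype(int), x=x)
            fit = cox_fit(df, ["x"])
            rejections += ph_assumption_check(fit)["x"].p_value < 0.05
        assert rejections / n_rep <= 0.08

    def test_detects_crossing_hazards(self):
        """Effect reversing mid-study should be flagged as non-proportional."""
        rng = np.random.default_rng(78)
        rejections = 0
        n_rep = 60
        for _ in range(n_rep):
            n = 200
            x = rng.integers(0, 2, n).astype(float)
            # group 1: high early hazard that switches off after t0
            t0 = 5.0
            t = np.empty(n)
            for i in range(n):
                if x[i] == 1:
                    t_early = rng.exponential(1 / 0.25)
                    t[i] = t_early if t_early < t0 else t0 + rng.exponential(1 / 0.01)
                else:
                    t[i] = rng.exponential(1 / 0.05)
            c = rng.uniform(10, 60, n)
            df = surv_df(np.minimum(t, c), (t <= c).astype(int), x=x)
            fit = cox_fit(df, ["x"])
            rejections += ph_assumption_check(fit)["x"].p_value < 0.05
        assert rejections / n_rep >= 0.5


class TestMaxstat:
    def test_perfect_separation_cutoff_between_groups(self):
        x = np.arange(1.0, 11.0)
        # high scores fail early, low scores censored late
        time = np.where(x > 5, 2.0, 50.0) + np.arange(10) * 0.1
        event = (x > 5).astype(int)
        df = surv_df(time, event)
        res = maxstat_cutoff(pd.Series(x, index=df.index), df, minprop=0.2, n_perm=99, seed=1)
        assert 5.0 < res.cutoff < 6.0

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(15):
            n = int(rng.integers(20, 51))
            x = np.round(rng.normal(size=n), 2)
            t = np.round(rng.exponential(10, n), 1) + 0.1
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            df = surv_df(t, e)
            try:
                res = maxstat_cutoff(pd.Series(x, index=df.index), df, minprop=0.1, n_perm=9, seed=0)
            except SurvivalError:
                continue  # no admissible cutpoint for this draw
            cut, z = naive_maxstat(list(x), list(t), list(e), 0.1)
            assert res.cutoff == pytest.approx(cut, abs=1e-9)
            assert res.statistic == pytest.approx(z, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_oracle_property_small_instances(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(15, 40))
        x = np.round(r.normal(size=n), 1)
        t = np.round(r.exponential(8, n), 0) + 1.0
        e = r.integers(0, 2, n)
        if e.sum() == 0:
            e[0] = 1
        df = surv_df(t, e)
        try:
            res = maxstat_cutoff(pd.Series(x, index=df.index), df, n_perm=9, seed=0)
        except SurvivalError:
            return
        oracle = naive_maxstat(list(x), list(t), list(e), 0.1)
        assert res.cutoff == pytest.approx(oracle[0], abs=1e-9)
        assert res.statistic == pytest.approx(oracle[1], abs=1e-9)

    def test_logrank_scores_sum_to_zero(self, rng):
        t = rng.exponential(10, 30)
        e = rng.integers(0, 2, 30)
        assert logrank_scores(t, e).sum() == pytest.approx(0.0, abs=1e-9)

    def test_determinism_under_seed(self, rng):
        x = rng.normal(size=40)
        df = surv_df(rng.exponential(10, 40), rng.integers(0, 2, 40) | 1)
        s = pd.Series(x, index=df.index)
        a = maxstat_cutoff(s, df, n_perm=200, seed=42)
        b = maxstat_cutoff(s, df, n_perm=200, seed=42)
        assert (a.cutoff, a.statistic, a.p_value) == (b.cutoff, b.statistic, b.p_value)

    def test_minprop_constraint_error(self):
        x = pd.Series([1.0] * 10, index=[f"P{i}" for i in range(10)])
        df = surv_df(np.arange(1, 11.0), [1] * 10)
        with pytest.raises(SurvivalError, match="cutpoint"):
            maxstat_cutoff(x, df, minprop=0.2, n_perm=9, seed=0)

    def test_bad_minprop_rejected(self):
        df = surv_df([1, 2, 3], [1, 1, 1])
        with pytest.raises(SurvivalError, match="minprop"):
            maxstat_cutoff(np.array([1.0, 2, 3]), df, minprop=0.6)

    def test_estimator_fit_predict(self, rng):
        n = 50
        x = pd.Series(rng.normal(size=n), index=[f"P{i}" for i in range(n)])
        df = surv_df(rng.exponential(10, n), np.ones(n, dtype=int))
        est = MaxstatCutpoint(n_perm=49, random_state=3).fit(x, df)
        labels = est.predict(x)
        assert set(labels) == {"high", "low"}
        assert (labels == "high").sum() == (x > est.cutoff_).sum()
        assert clone(est).get_params()["n_perm"] == 49

    def test_dichotomize_is_strict(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        labels = dichotomize(s, 2.0)
        assert labels.tolist() == ["low", "low", "high"]


def test_read_clinical_round_trip(tmp_path, rng):
    df = surv_df(rng.exponential(10, 5), [1, 0, 1, 1, 0], arm=list("abcab"))
    path = tmp_path / "clin.tsv"
    df.to_csv(path, sep="\t", index_label="sample_id")
    back = read_clinical_table(path)
    assert np.allclose(back["time"], df["time"])
    assert list(back["arm"]) == list(df["arm"])
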