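"""Time-to-event machinery: Kaplan–Meier, log-rank, Cox, PH check, maxstat.

The clinical container is a pandas DataFrame indexed by sample id with
columns ``time`` (months, >= 0) and ``event`` (1 = event observed, 0 =
censored), plus optional covariate columns.  lifelines provides the
Kaplan–Meier estimator, the log-rank test, the Cox model (Efron ties, Wald
CIs) and the scaled-Schoenfeld proportional-hazards check behind this
module's surface.

The maximally selected cutpoint (:func:`maxstat_cutoff`) dichotomizes a
continuous marker at the value with the most significant log-rank
separation.  It uses the linear-rank formulation with Nelson–Aalen log-rank
scores: candidate cutpoints are midpoints between consecutive distinct
marker values whose induced groups both hold at least ``minprop`` of the
samples; at each, the group score-sum is standardized by its conditional
permutation mean and variance.  Inference on the maximum is by a seeded
permutation null rather than an asymptotic bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import proportional_hazard_test as _ll_ph_test
from sklearn.base import BaseEstimator

from .stats import TestResult

logger = logging.getLogger(__name__)

DEFAULT_MINPROP = 0.1
DEFAULT_N_PERM = 1000


class SurvivalError(ValueError):
    pass


def validate_survival(surv: pd.DataFrame) -> pd.DataFrame:
    """Check the time/event contract; returns the table unchanged."""
    for col in ("time", "event"):
        if col not in surv.columns:
            raise SurvivalError(f"survival table lacks a {col!r} column")
    t = surv["time"].to_numpy(dtype=float)
    e = surv["event"].to_numpy(dtype=float)
    if not np.isfinite(t).all() or not np.isfinite(e).all():
        raise SurvivalError("missing time/event values")
    if (t < 0).any():
        raise SurvivalError("negative survival time")
    if not np.isin(e, (0, 1)).all():
        raise SurvivalError("event must be 0 or 1")
    return surv


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV (sample_id, time, event, covariates...)."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return validate_survival(df)


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function lookup, S(t) = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


def km_estimate(surv: pd.DataFrame) -> KMCurve:
    """Kaplan–Meier curve; ties at a time are handled events-first."""
    validate_survival(surv)
    if len(surv) == 0:
        raise SurvivalError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(surv["time"], surv["event"])
    table = kmf.event_table
    has_event = table["observed"] > 0
    times = table.index.to_numpy(dtype=float)[has_event]
    probs = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)[has_event]
    return KMCurve(times, probs, at_risk)


def logrank_test(surv_a: pd.DataFrame, surv_b: pd.DataFrame) -> TestResult:
    """Two-group log-rank test (chi-square, 1 df)."""
    validate_survival(surv_a)
    validate_survival(surv_b)
    if len(surv_a) == 0 or len(surv_b) == 0:
        raise SurvivalError("both groups must be non-empty")
    n_events = int(surv_a["event"].sum() + surv_b["event"].sum())
    if n_events == 0:
        raise SurvivalError("no events in either group: log-rank undefined")
    res = _ll_logrank(
        surv_a["time"], surv_b["time"], surv_a["event"], surv_b["event"]
    )
    return TestResult(
        float(res.test_statistic), float(res.p_value), "log-rank", (len(surv_a), len(surv_b))
    )


@dataclass
class CoxFit:
    """Proportional-hazards fit: log-hazards, HRs, Wald 95% CIs and p-values."""

    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci95: pd.DataFrame  # columns lower, upper (hazard-ratio scale)
    p_values: pd.Series
    n_events: int
    model: CoxPHFitter = field(repr=False)
    design: pd.DataFrame = field(repr=False)


def _expand_covariates(surv: pd.DataFrame, covariate_names: list[str]) -> pd.DataFrame:
    missing = [c for c in covariate_names if c not in surv.columns]
    if missing:
        raise SurvivalError(f"covariate(s) not in table: {missing}")
    X = surv[covariate_names]
    X = pd.get_dummies(X, drop_first=True, dtype=float)  # reference coding
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise SurvivalError(f"covariate {col!r} is constant")
    return X


def cox_fit(
    surv: pd.DataFrame, covariate_names: list[str], max_steps: int = 500
) -> CoxFit:
    """Cox proportional-hazards model (Efron ties, Wald inference).

    Categorical covariates are expanded to reference-coded indicators.
    """
    validate_survival(surv)
    if int(surv["event"].sum()) < 1:
        raise SurvivalError("need at least one event")
    X = _expand_covariates(surv, list(covariate_names))
    design = pd.concat([surv[["time", "event"]], X], axis=1)
    cph = CoxPHFitter()
    try:
        cph.fit(
            design,
            duration_col="time",
            event_col="event",
            fit_options={"max_steps": max_steps, "precision": 1e-12},
        )
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise SurvivalError(f"Cox model did not converge: {exc}") from exc
    summary = cph.summary
    ci = pd.DataFrame(
        {
            "lower": np.exp(summary["coef lower 95%"]),
            "upper": np.exp(summary["coef upper 95%"]),
        }
    )
    return CoxFit(
        coefficients=summary["coef"].copy(),
        hazard_ratios=np.exp(summary["coef"]),
        ci95=ci,
        p_values=summary["p"].copy(),
        n_events=int(surv["event"].sum()),
        model=cph,
        design=design,
    )


def ph_assumption_check(fit: CoxFit) -> dict[str, TestResult]:
    """Scaled Schoenfeld residual test of proportional hazards, per covariate."""
    if fit.n_events < 2:
        raise SurvivalError("need >= 2 events to check proportional hazards")
    res = _ll_ph_test(fit.model, fit.design, time_transform="rank")
    out: dict[str, TestResult] = {}
    summary = res.summary
    for name in fit.coefficients.index:
        row = summary.loc[name]
        # lifelines may return one row per (covariate, transform)
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        out[name] = TestResult(
            float(row["test_statistic"]), float(row["p"]), "schoenfeld (rank time)", (fit.n_events,)
        )
    return out


# ---------------------------------------------------------------------------
# maximally selected rank statistic


@dataclass
class MaxstatResult:
    cutoff: float
    statistic: float  # standardized log-rank statistic at the cutoff (signed)
    scanned_cutpoints: np.ndarray
    p_value: float
    statistics: np.ndarray = field(default=None, repr=False)  # z at each cutpoint


def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Nelson–Aalen log-rank (Savage) scores: a_i = event_i - H(t_i)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    order = np.argsort(time, kind="stable")
    n = time.size
    cumhaz = np.empty(n)
    at_risk = n
    h = 0.0
    i = 0
    t_sorted = time[order]
    e_sorted = event[order]
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        d = e_sorted[i:j].sum()
        h += d / at_risk
        cumhaz[i:j] = h
        at_risk -= j - i
        i = j
    scores = np.empty(n)
    scores[order] = e_sorted - cumhaz
    return scores


def maxstat_cutoff(
    scores,
    surv: pd.DataFrame,
    minprop: float = DEFAULT_MINPROP,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> MaxstatResult:
    """Maximally selected log-rank cutpoint for a continuous marker.

    ``scores`` (a Series indexed by sample id, or an array aligned with
    ``surv``) is scanned over midpoints between consecutive distinct values;
    each split must leave at least ``minprop`` of the samples on both sides.
    The cutoff maximizes the absolute standardized log-rank statistic (ties
    broken toward the lower cutoff); its p-value is the seeded permutation
    tail probability of the maximum.
    """
    validate_survival(surv)
    if not 0 < minprop < 0.5:
        raise SurvivalError("minprop must be in (0, 0.5)")
    if isinstance(scores, pd.Series):
        missing = [s for s in surv.index if s not in scores.index]
        if missing:
            raise SurvivalError(f"scores missing for sample(s): {missing[:5]}")
        x = scores.loc[surv.index].to_numpy(dtype=float)
    else:
        x = np.asarray(scores, dtype=float)
        if x.size != len(surv):
            raise SurvivalError("scores and survival table are not aligned")
    n = x.size
    if int(surv["event"].sum()) < 1:
        raise SurvivalError("need at least one event")

    a = logrank_scores(surv["time"].to_numpy(), surv["event"].to_numpy())
    a_bar = a.mean()
    ssq = ((a - a_bar) ** 2).sum()
    if ssq == 0:
        raise SurvivalError("degenerate log-rank scores (no usable events)")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    n_min = int(np.ceil(minprop * n))
    ks = np.array(
        [
            k
            for k in range(n_min, n - n_min + 1)
            if xs[k] > xs[k - 1]  # split between distinct values only
        ],
        dtype=int,
    )
    if ks.size == 0:
        raise SurvivalError(
            f"no candidate cutpoint leaves >= {minprop:.0%} of samples in both groups"
        )
    cutpoints = (xs[ks - 1] + xs[ks]) / 2.0
    sigma = np.sqrt(ks * (n - ks) / (n * (n - 1.0)) * ssq)

    def standardized(a_vec: np.ndarray) -> np.ndarray:
        s = np.cumsum(a_vec)[ks - 1]
        return (s - ks * a_bar) / sigma

    z = standardized(a[order])
    best = int(np.argmax(np.abs(z) > np.abs(z).max() - 1e-12))  # first (lowest) argmax
    obs_max = float(np.abs(z).max())

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm_z = standardized(rng.permutation(a))
        if np.abs(perm_z).max() >= obs_max - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)

    return MaxstatResult(
        cutoff=float(cutpoints[best]),
        statistic=float(z[best]),
        scanned_cutpoints=cutpoints,
        p_value=p,
        statistics=z,
    )


def dichotomize(scores: pd.Series, cutoff: float) -> pd.Series:
    """Label samples 'high' when score > cutoff (strict), else 'low'."""
    return pd.Series(
        np.where(scores.to_numpy(dtype=float) > cutoff, "high", "low"), index=scores.index
    )


class MaxstatCutpoint(BaseEstimator):
    """sklearn-style estimator for the maximally selected survival cutpoint.

    ``fit(scores, surv)`` learns ``cutoff_``, ``statistic_`` and ``p_value_``;
    ``predict(scores)`` labels samples 'high'/'low' by the learned cutoff.
    """

    def __init__(
        self,
        minprop: float = DEFAULT_MINPROP,
        n_perm: int = DEFAULT_N_PERM,
        random_state: int | None = None,
    ):
        self.minprop = minprop
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, scores, surv: pd.DataFrame) -> "MaxstatCutpoint":
        res = maxstat_cutoff(
            scores, surv, minprop=self.minprop, n_perm=self.n_perm, seed=self.random_state
        )
        self.result_ = res
        self.cutoff_ = res.cutoff
        self.statistic_ = res.statistic
        self.p_value_ = res.p_value
        return self

    def predict(self, scores) -> np.ndarray:
        if isinstance(scores, pd.Series):
            x = scores.to_numpy(dtype=float)
        else:
            x = np.asarray(scores, dtype=float).ravel()
        return np.where(x > self.cutoff_, "high", "low")
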