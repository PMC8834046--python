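"""Two-sided comparison statistics used across the pipeline.

Pearson correlation, Mann–Whitney U, Kruskal–Wallis, Wilcoxon signed-rank
(the paired two-group analogue) and the Friedman test.  All p-values are
two-sided.  scipy backs every test except Friedman, which is computed here
with the tie-corrected chi-square statistic (scipy's version has no tie
correction).

Exact p-values are used for the rank tests on small, tie-free samples
(combined n <= 12 for Mann–Whitney, n <= 15 pairs for the signed-rank test,
both configurable); larger or tied samples use the normal approximation with
tie and continuity corrections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

MANN_WHITNEY_EXACT_LIMIT = 12  # combined sample size for exact enumeration
SIGNED_RANK_EXACT_LIMIT = 15  # number of non-zero pairs for exact enumeration


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(a).all():
        raise ValueError("non-finite values in input")
    return a


def pearson_r(x, y) -> TestResult:
    """Pearson product-moment correlation; p from the t-transform (n-2 df)."""
    x, y = _as_1d(x), _as_1d(y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), "pearson", (x.size,))


def mann_whitney_u(x, y, exact_limit: int = MANN_WHITNEY_EXACT_LIMIT) -> TestResult:
    """Unpaired two-group rank test.

    Exact enumeration when the combined sample is tie-free and no larger than
    ``exact_limit``; otherwise normal approximation with tie and continuity
    corrections.
    """
    x, y = _as_1d(x), _as_1d(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (tie_free and combined.size <= exact_limit) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        f"mann-whitney ({method})",
        (x.size, y.size),
    )


def kruskal_wallis(groups: Sequence) -> TestResult:
    """Tie-corrected Kruskal–Wallis H; p from chi-square with k-1 df.

    All values identical is reported as H = 0, p = 1 (no evidence of any
    difference) rather than an error.
    """
    gs = [_as_1d(g) for g in groups]
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("all groups must be non-empty")
    total = sum(g.size for g in gs)
    if total < 3:
        raise ValueError("need >= 3 observations in total")
    ns = tuple(g.size for g in gs)
    if np.ptp(np.concatenate(gs)) == 0:
        return TestResult(0.0, 1.0, "kruskal-wallis", ns)
    h, p = sps.kruskal(*gs)
    return TestResult(float(h), float(p), "kruskal-wallis", ns)


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic by sign enumeration."""
    n = ranks.size
    # distribution of W+ over all 2^n sign assignments, built incrementally
    dist = {0.0: 1}
    for r in ranks:
        new: dict[float, int] = {}
        for w, c in dist.items():
            new[w] = new.get(w, 0) + c
            new[w + r] = new.get(w + r, 0) + c
        dist = new
    total = 2**n
    lower = sum(c for w, c in dist.items() if w <= w_plus + 1e-9)
    upper = sum(c for w, c in dist.items() if w >= w_plus - 1e-9)
    return min(1.0, 2.0 * min(lower, upper) / total)


def wilcoxon_signed_rank(x, y, exact_limit: int = SIGNED_RANK_EXACT_LIMIT) -> TestResult:
    """Paired two-group rank test (Wilcoxon signed-rank).

    Zero differences are dropped (Wilcoxon's rule, count logged).  The
    reported statistic is the smaller of the two signed-rank sums.  Exact
    enumeration of sign patterns for n <= ``exact_limit`` non-zero pairs
    (valid with tied magnitudes); otherwise normal approximation with
    continuity correction.
    """
    x, y = _as_1d(x), _as_1d(y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length (paired)")
    d = x - y
    nz = d != 0
    n_zero = int((~nz).sum())
    if n_zero:
        logger.info("wilcoxon_signed_rank: dropped %d zero difference(s)", n_zero)
    d = d[nz]
    if d.size == 0:
        raise ValueError("all differences are zero: test undefined")
    ranks = sps.rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if d.size <= exact_limit:
        p = _signed_rank_exact_p(ranks, w_plus)
        method = "exact"
    else:
        res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
        p = float(res.pvalue)
        method = "normal approximation"
    return TestResult(w, min(p, 1.0), f"wilcoxon signed-rank ({method})", (d.size,))


def friedman(blocks) -> TestResult:
    """Tie-corrected Friedman test on a subjects-x-conditions table.

    Within-subject ranks (ties averaged); the chi-square statistic with k-1
    df is divided by the tie-correction factor
    ``1 - sum_i sum_t (t^3 - t) / (n k (k^2 - 1))``.
    """
    B = np.asarray(blocks, dtype=float)
    if B.ndim != 2:
        raise ValueError("blocks must be a 2-D subjects-x-conditions table")
    n, k = B.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    if not np.isfinite(B).all():
        raise ValueError("incomplete block: non-finite value present")
    R = np.apply_along_axis(sps.rankdata, 1, B)
    col_sums = R.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    # tie correction over within-subject tie groups
    tie_term = 0.0
    for row in B:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:
        # every row fully tied: no within-subject ordering information
        return TestResult(0.0, 1.0, "friedman", (n, k))
    stat /= correction
    p = float(sps.chi2.sf(stat, df=k - 1))
    return TestResult(float(stat), p, "friedman", (n, k))
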