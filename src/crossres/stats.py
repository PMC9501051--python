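"""Statistical primitives used throughout the pipeline.

Rank-sum and exact tests delegate to :mod:`scipy.stats`; the Kaplan-Meier
estimate wraps :mod:`lifelines`.  The 2x2 Fisher test and the two-group
log-rank test are implemented directly on top of numpy: both are called
hundreds of thousands of times in property suites and per-feature filter
loops, where per-call overhead of the library wrappers dominates.  Their
outputs are cross-checked against scipy / lifelines in the test suite.

p-values are never truncated here; display rounding ("<0.001") happens in
the reporting layer only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "TestResult",
    "KMCurve",
    "LogRankResult",
    "CorrelationMatrix",
    "wilcoxon_rank_sum",
    "fisher_exact_2x2",
    "kruskal_wallis",
    "km_estimate",
    "log_rank_test",
    "pearson_matrix",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival evaluated at distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_marks: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass(frozen=True)
class CorrelationMatrix:
    feature_ids: tuple
    r: np.ndarray
    p: np.ndarray


# ---------------------------------------------------------------------------
# rank and exact tests

#: combined-sample-size bound below which the rank-sum test is exact
WILCOXON_EXACT_MAX_N = 20


def wilcoxon_rank_sum(x, y, exact_max_n: int = WILCOXON_EXACT_MAX_N) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration is used when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  A statistic that
    sits exactly at the null center yields p = 1 (the two-sided tail
    doubling of a central observation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size) <= exact_max_n and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    p = float(res.pvalue)
    if u == x.size * y.size / 2.0:
        p = 1.0
    return TestResult(u, min(p, 1.0), f"wilcoxon-{method}", (x.size, y.size))


#: relative tolerance when comparing table probabilities (the R convention)
_FISHER_REL_EPS = 1e-7


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test for the table ``[[a, b], [c, d]]``.

    The two-sided p-value is the probability-mass ordering: the sum of
    hypergeometric probabilities of all tables with the same margins whose
    probability does not exceed that of the observed table (within a
    relative tolerance of 1e-7, as in R).  Any zero margin makes the table
    degenerate and returns p = 1.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    odds = np.inf if b * c == 0 else a * d / (b * c)
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return TestResult(odds, 1.0, "fisher-exact", (r1, r2))
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = (
        _log_comb(r1, support)
        + _log_comb(r2, c1 - support)
        - _log_comb(n, c1)
    )
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    observed = pmf[a - lo]
    p = float(pmf[pmf <= observed * (1.0 + _FISHER_REL_EPS)].sum())
    return TestResult(odds, min(p, 1.0), "fisher-exact", (r1, r2))


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across two or more groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two nonempty groups")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:  # scipy raises on all-identical input
        return TestResult(0.0, 1.0, "kruskal-wallis", tuple(g.size for g in groups))
    res = sps.kruskal(*groups)
    return TestResult(
        float(res.statistic), float(res.pvalue), "kruskal-wallis",
        tuple(g.size for g in groups),
    )


# ---------------------------------------------------------------------------
# survival


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Ties between an event and a censoring at the same time are resolved
    event-first (the standard convention).
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0 or times.size != events.size:
        raise ValueError("times and events must be equal-length and nonempty")
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    survival = np.array(
        [float(kmf.survival_function_.loc[t].iloc[0]) for t in event_times]
    )
    censor_marks = table.index.to_numpy(dtype=float)[table["censored"].to_numpy() > 0]
    return KMCurve(event_times, survival, at_risk, censor_marks)


def log_rank_test(times, events, group_labels) -> LogRankResult:
    """Two-group Mantel-Haenszel log-rank test (1 df, two-sided).

    Ties use the standard discrete-time hypergeometric variance.  With no
    variance (e.g. no events) the statistic is 0 and p = 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    g = np.asarray(group_labels)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"need exactly two nonempty groups, got {labels.size}")
    in1 = g == labels[1]

    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    m1 = in1[order].astype(np.int64)

    uniq, first = np.unique(t, return_index=True)
    # events and group-1 events per distinct time
    d = np.add.reduceat(e.astype(np.int64), first)
    d1 = np.add.reduceat((e & (m1 == 1)).astype(np.int64), first)
    # at-risk counts just before each distinct time
    removed = np.add.reduceat(np.ones_like(m1), first)
    removed1 = np.add.reduceat(m1, first)
    n_total = times.size
    n1_total = int(m1.sum())
    at_risk = n_total - np.concatenate([[0], np.cumsum(removed)[:-1]])
    at_risk1 = n1_total - np.concatenate([[0], np.cumsum(removed1)[:-1]])

    mask = (d > 0) & (at_risk > 1)
    nj = at_risk[mask].astype(float)
    n1j = at_risk1[mask].astype(float)
    dj = d[mask].astype(float)
    d1j = d1[mask].astype(float)
    expected = dj * n1j / nj
    var = dj * (n1j / nj) * (1.0 - n1j / nj) * (nj - dj) / (nj - 1.0)
    u = float((d1j - expected).sum())
    v = float(var.sum())
    if v <= 0.0:
        return LogRankResult(0.0, 1, 1.0)
    chi2 = u * u / v
    return LogRankResult(chi2, 1, float(sps.chi2.sf(chi2, df=1)))


# ---------------------------------------------------------------------------
# correlation


def pearson_matrix(values, feature_ids=None) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation matrix with two-sided p-values.

    ``values`` is sample-by-feature (an array, DataFrame or
    :class:`~crossres.cohort.ExpressionMatrix`).  Pairs with fewer than
    three complete samples, or involving a constant feature, are recorded
    as NaN.
    """
    from crossres.cohort import ExpressionMatrix

    if isinstance(values, ExpressionMatrix):
        feature_ids = values.feature_ids if feature_ids is None else feature_ids
        frame = values.to_frame()[list(feature_ids)]
        data = frame.to_numpy(dtype=float)
    else:
        data = np.asarray(values, dtype=float)
        if feature_ids is None:
            feature_ids = tuple(range(data.shape[1]))
        else:
            feature_ids = tuple(feature_ids)
    k = data.shape[1]
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            xi, xj = data[:, i], data[:, j]
            ok = ~(np.isnan(xi) | np.isnan(xj))
            n = int(ok.sum())
            if n < 3 or np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                continue
            if i == j:
                r[i, i] = 1.0
                p[i, i] = 0.0
                continue
            rij = float(np.corrcoef(xi[ok], xj[ok])[0, 1])
            rij = float(np.clip(rij, -1.0, 1.0))
            r[i, j] = r[j, i] = rij
            if abs(rij) >= 1.0:
                pij = 0.0
            else:
                tstat = rij * np.sqrt((n - 2) / (1.0 - rij * rij))
                pij = 2.0 * float(sps.t.sf(abs(tstat), df=n - 2))
            p[i, j] = p[j, i] = min(pij, 1.0)
    np.fill_diagonal(p, np.where(np.isnan(np.diag(r)), np.nan, 0.0))
    return CorrelationMatrix(tuple(feature_ids), r, p)
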