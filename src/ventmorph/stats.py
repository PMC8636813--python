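"""Nonparametric statistics for cohort comparisons.

The comparison layer mirrors standard small-cohort practice: Fisher's exact
test for categorical 2x2 tables, the independent-samples Mann-Whitney U test
between groups, the Wilcoxon signed-rank test for paired timepoints, and
ANOVA-based intraclass correlation coefficients for repeatability.  All tests
are two-sided; significance is assessed at alpha = 0.05 unless overridden.

Exact null distributions are used where they are conventional and cheap:
Mann-Whitney for combined n <= 20 without ties, Wilcoxon for n <= 25 non-zero
tie-free differences, Fisher always.  Beyond those sizes the normal
approximation with tie and continuity corrections is used.  The crossover
thresholds are configurable per call.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import StatisticsError

_REL_TOL_NUM = 10**12  # 1e-12 relative tolerance for likelihood ties, in integers


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n: tuple[int, ...]

    def significant(self, alpha: float = 0.05) -> bool:
        return self.pvalue < alpha


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def hypergeometric_weights(table: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """All table likelihood numerators for the fixed margins of a 2x2 table.

    Returns (values of cell a, integer weights C(r1,a)*C(r2,c1-a), total
    C(N,c1)); weights / total are the hypergeometric probabilities and sum to
    one exactly.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    values = np.arange(lo, hi + 1)
    weights = np.array([comb(r1, int(v)) * comb(r2, int(c1 - v)) for v in values], dtype=object)
    return values, weights, comb(N, c1)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher p: sum of hypergeometric probabilities of all tables
    (fixed margins) no more likely than the observed one.

    Likelihood comparisons carry a 1e-12 relative tolerance so floating-point
    representations of tied tables are treated as ties; the arithmetic here is
    exact integer arithmetic throughout.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise StatisticsError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise StatisticsError("table entries must be nonnegative integers")
    (a, b), (c, d) = t
    if min(a + b, c + d, a + c, b + d) == 0:
        raise StatisticsError("degenerate table: a margin is zero")
    values, weights, total = hypergeometric_weights(t)
    obs = int(weights[list(values).index(a)])
    kept = sum(int(w) for w in weights if int(w) * _REL_TOL_NUM <= obs * (_REL_TOL_NUM + 1))
    pvalue = kept / total
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    return TestResult(statistic=float(odds), pvalue=float(min(1.0, pvalue)),
                      method="fisher-exact", n=(int(a + b), int(c + d)))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _mw_null_counts(m: int, n: int) -> tuple[int, ...]:
    """Exact null counts of the U statistic (Gaussian-binomial coefficients)."""
    size = m * n + 1
    c = np.zeros(size, dtype=np.int64)
    c[0] = 1
    for i in range(1, m + 1):
        nxt = c.copy()
        k = n + i
        if k < size:
            nxt[k:] -= c[: size - k]
        for j in range(i, size):
            nxt[j] += nxt[j - i]
        c = nxt
    return tuple(int(v) for v in c)


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney(x: Sequence[float], y: Sequence[float], *, exact_threshold: int = 20) -> TestResult:
    """Two-sided independent-samples Mann-Whitney U test.

    Exact permutation null when the combined sample size is at most
    ``exact_threshold`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise StatisticsError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    U = float(ranks[:m].sum() - m * (m + 1) / 2.0)
    ties = np.unique(pooled).size < pooled.size
    N = m + n
    if N <= exact_threshold and not ties:
        counts = np.asarray(_mw_null_counts(m, n), dtype=float)
        total = counts.sum()
        u = int(round(U))
        cdf = counts[: u + 1].sum() / total
        sf = counts[u:].sum() / total
        pvalue = min(1.0, 2.0 * min(cdf, sf))
        method = "mann-whitney/exact"
    else:
        mu = m * n / 2.0
        tie = _tie_term(pooled)
        var = m * n / 12.0 * ((N + 1) - tie / (N * (N - 1)))
        if var <= 0:
            return TestResult(U, 1.0, "mann-whitney/normal", (m, n))
        diff = U - mu
        z = 0.0 if diff == 0 else (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
        pvalue = min(1.0, 2.0 * norm.sf(abs(z)))
        method = "mann-whitney/normal"
    return TestResult(statistic=U, pvalue=float(pvalue), method=method, n=(m, n))


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _wilcoxon_null_counts(n: int) -> tuple[int, ...]:
    """Exact null counts of W+ over the 2^n sign patterns of ranks 1..n."""
    size = n * (n + 1) // 2 + 1
    c = np.zeros(size, dtype=np.int64)
    c[0] = 1
    for i in range(1, n + 1):
        c[i:] += c[:-i].copy()
    return tuple(int(v) for v in c)


def wilcoxon_signed_rank(
    pre: Sequence[float],
    post: Sequence[float],
    *,
    exact_threshold: int = 25,
    zero_method: str = "wilcox",
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples (post - pre).

    Zero differences are dropped (Wilcoxon convention); the Pratt variant is
    available via ``zero_method="pratt"``.  Exact null for at most
    ``exact_threshold`` tie-free non-zero differences, else normal
    approximation with tie and continuity corrections.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size == 0:
        raise StatisticsError("paired samples must be non-empty and of equal length")
    d = post - pre
    if np.all(d == 0):
        raise StatisticsError("all differences zero: test undefined")
    if zero_method == "pratt":
        from scipy.stats import wilcoxon as _scipy_wilcoxon

        res = _scipy_wilcoxon(post, pre, zero_method="pratt", correction=True, method="approx")
        return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon/pratt-approx", (pre.size,))
    if zero_method != "wilcox":
        raise StatisticsError(f"unknown zero_method {zero_method!r}")
    d = d[d != 0]
    nz = d.size
    ranks = rankdata(np.abs(d))
    W = float(ranks[d > 0].sum())
    ties = np.unique(np.abs(d)).size < nz
    if nz <= exact_threshold and not ties:
        counts = np.asarray(_wilcoxon_null_counts(nz), dtype=float)
        total = counts.sum()
        w = int(round(W))
        cdf = counts[: w + 1].sum() / total
        sf = counts[w:].sum() / total
        pvalue = min(1.0, 2.0 * min(cdf, sf))
        method = "wilcoxon/exact"
    else:
        mu = nz * (nz + 1) / 4.0
        var = nz * (nz + 1) * (2 * nz + 1) / 24.0 - _tie_term(np.abs(d)) / 48.0
        if var <= 0:
            return TestResult(W, 1.0, "wilcoxon/normal", (pre.size,))
        diff = W - mu
        z = 0.0 if diff == 0 else (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
        pvalue = min(1.0, 2.0 * norm.sf(abs(z)))
        method = "wilcoxon/normal"
    return TestResult(statistic=W, pvalue=float(pvalue), method=method, n=(pre.size,))


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    value: float
    model: str
    msr: float
    msc: float
    mse: float
    n_subjects: int
    n_raters: int


def icc_single(measurements: np.ndarray, *, model: str = "icc2") -> ICCResult:
    """Single-measurement ICC from the two-way ANOVA decomposition.

    ``model="icc2"`` is two-way random effects, absolute agreement (ICC(2,1));
    ``model="icc3"`` is two-way mixed, consistency (ICC(3,1)).
    """
    M = np.asarray(measurements, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise StatisticsError("need at least 2 subjects and 2 repeated measurements")
    if np.any(np.isnan(M)):
        raise StatisticsError("missing values are not supported")
    n, k = M.shape
    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((M - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    scale = max(sst, 1.0)
    if msr <= 1e-12 * scale:
        raise StatisticsError("zero between-subject variance: ICC undefined")
    if model == "icc2":
        value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    elif model == "icc3":
        value = (msr - mse) / (msr + (k - 1) * mse)
    else:
        raise StatisticsError(f"unknown ICC model {model!r}")
    return ICCResult(float(value), model, msr, msc, mse, n, k)


# ---------------------------------------------------------------------------
# comparison tables
# ---------------------------------------------------------------------------


@dataclass
class ComparisonTable:
    """Mean +/- SD per group per measure with pairwise test p-values."""

    table: pd.DataFrame
    tests: dict[tuple[str, str], TestResult]
    grouping: str
    alpha: float = 0.05

    @property
    def n_comparisons(self) -> int:
        return len(self.tests)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=True)

    def to_json(self) -> dict:
        return {
            "grouping": self.grouping,
            "alpha": self.alpha,
            "n_comparisons": self.n_comparisons,
            "table": self.table.to_dict(orient="index"),
            "tests": {
                f"{measure}|{contrast}": {"statistic": r.statistic, "pvalue": r.pvalue, "method": r.method}
                for (measure, contrast), r in self.tests.items()
            },
        }


def _group_values(df: pd.DataFrame, group_col: str, group: str, measure: str) -> np.ndarray:
    vals = df.loc[df[group_col] == group, measure].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise StatisticsError(f"group {group!r} has no values for measure {measure!r}")
    return vals


def build_comparison_table(
    df: pd.DataFrame,
    measures: Sequence[str],
    group_col: str,
    *,
    paired_col: str | None = None,
    timepoints: tuple[str, str] = ("pre", "post"),
    subject_col: str = "subject_id",
    alpha: float = 0.05,
) -> ComparisonTable:
    """Render a group-comparison table from a cohort frame.

    Independent groupings use pairwise Mann-Whitney tests between every pair
    of groups; when ``paired_col`` is given, each group is compared across the
    two ``timepoints`` with the Wilcoxon signed-rank test on subject-matched
    rows.  Significance is flagged at ``alpha`` with a trailing ``*`` on the
    p-value column; no multiple-testing correction is applied (the table
    carries ``n_comparisons`` so callers can apply their own).
    """
    if group_col not in df.columns:
        raise StatisticsError(f"grouping column {group_col!r} not in table")
    groups = list(pd.unique(df[group_col].dropna()))
    if not groups:
        raise StatisticsError("no groups present")
    tests: dict[tuple[str, str], TestResult] = {}
    rows: dict[str, dict[str, object]] = {m: {} for m in measures}

    if paired_col is None:
        for measure in measures:
            for g in groups:
                vals = _group_values(df, group_col, g, measure)
                rows[measure][f"{g} mean"] = vals.mean()
                rows[measure][f"{g} sd"] = vals.std(ddof=1) if vals.size > 1 else 0.0
                rows[measure][f"{g} n"] = vals.size
            for i, g1 in enumerate(groups):
                for g2 in groups[i + 1:]:
                    res = mann_whitney(
                        _group_values(df, group_col, g1, measure),
                        _group_values(df, group_col, g2, measure),
                    )
                    tests[(measure, f"{g1} vs {g2}")] = res
                    star = "*" if res.pvalue < alpha else ""
                    rows[measure][f"p {g1} vs {g2}"] = f"{res.pvalue:.4g}{star}"
    else:
        t0, t1 = timepoints
        for measure in measures:
            for g in groups:
                sub = df[df[group_col] == g]
                wide = sub.pivot(index=subject_col, columns=paired_col, values=measure)
                for tp in (t0, t1):
                    if tp not in wide.columns or wide[tp].dropna().empty:
                        raise StatisticsError(f"group {g!r} lacks timepoint {tp!r} for {measure!r}")
                wide = wide.dropna(subset=[t0, t1])
                rows[measure][f"{g} {t0} mean"] = wide[t0].mean()
                rows[measure][f"{g} {t0} sd"] = wide[t0].std(ddof=1)
                rows[measure][f"{g} {t1} mean"] = wide[t1].mean()
                rows[measure][f"{g} {t1} sd"] = wide[t1].std(ddof=1)
                try:
                    res = wilcoxon_signed_rank(wide[t0].to_numpy(), wide[t1].to_numpy())
                except StatisticsError:
                    rows[measure][f"p {g}"] = "NA (no change)"
                    continue
                tests[(measure, f"{g}: {t0} vs {t1}")] = res
                star = "*" if res.pvalue < alpha else ""
                rows[measure][f"p {g}"] = f"{res.pvalue:.4g}{star}"

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "measure"
    return ComparisonTable(table=table, tests=tests, grouping=group_col, alpha=alpha)


def contingency_fisher(df: pd.DataFrame, row_col: str, col_col: str) -> tuple[pd.DataFrame, TestResult]:
    """2x2 cross-tabulation of two binary columns with Fisher's exact test."""
    ct = pd.crosstab(df[row_col], df[col_col])
    if ct.shape != (2, 2):
        raise StatisticsError(f"{row_col} x {col_col} is {ct.shape}, need 2x2")
    return ct, fisher_exact_2x2(ct.to_numpy())
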