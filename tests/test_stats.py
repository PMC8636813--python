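"""Exact and approximate nonparametric tests against independent oracles."""
import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from ventmorph import (
    build_comparison_table,
    contingency_fisher,
    fisher_exact_2x2,
    icc_single,
    mann_whitney,
    wilcoxon_signed_rank,
)
from ventmorph.errors import StatisticsError
from ventmorph.stats import hypergeometric_weights


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementations under test)
# ---------------------------------------------------------------------------


def mw_pvalue_enumeration(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = scipy_stats.rankdata(pooled)
    m = len(x)
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), m):
        us.append(ranks[list(idx)].sum() - m * (m + 1) / 2)
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


def wilcoxon_pvalue_enumeration(diffs):
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = scipy_stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    lo = np.mean(ws <= w_obs)
    hi = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(lo, hi))


def fisher_pvalue_enumeration(table):
    """Two-sided Fisher p with exact rational hypergeometric probabilities."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    probs = {}
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[aa] = Fraction(comb(r1, aa) * comb(r2, c1 - aa), comb(N, c1))
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


# ---------------------------------------------------------------------------
# frozen examples
# ---------------------------------------------------------------------------


def test_mann_whitney_separated_triples():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0
    assert res.pvalue == pytest.approx(0.100, abs=1e-12)
    assert res.method == "mann-whitney/exact"


def test_mann_whitney_identical_samples_not_significant():
    x = [1.0, 2.0, 2.0, 3.0, 5.0]
    res = mann_whitney(x, list(x))
    assert res.statistic == len(x) ** 2 / 2
    assert res.pvalue >= 0.99


def test_wilcoxon_small_sample_and_errors():
    res = wilcoxon_signed_rank([0, 0, 0], [1, 2, 3])
    assert res.statistic == 6
    assert res.pvalue == pytest.approx(0.250, abs=1e-12)
    with pytest.raises(StatisticsError, match="zero"):
        wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
    flipped = wilcoxon_signed_rank([1, 2, 3], [0, 0, 0])
    assert flipped.pvalue == pytest.approx(res.pvalue, abs=1e-12)


def test_fisher_examples():
    assert fisher_exact_2x2([[4, 5], [5, 7]]).pvalue == pytest.approx(1.0, abs=1e-12)
    assert fisher_exact_2x2([[3, 3], [6, 9]]).pvalue == pytest.approx(1.0, abs=1e-12)
    assert fisher_exact_2x2([[5, 0], [0, 5]]).pvalue == pytest.approx(2 / 252, abs=1e-15)
    with pytest.raises(StatisticsError, match="margin"):
        fisher_exact_2x2([[0, 0], [3, 4]])


def test_fisher_invariances():
    rng = np.random.default_rng(12)
    for _ in range(30):
        t = rng.integers(1, 9, (2, 2))
        p = fisher_exact_2x2(t).pvalue
        assert fisher_exact_2x2(t.T).pvalue == pytest.approx(p, abs=1e-12)
        assert fisher_exact_2x2(t[::-1]).pvalue == pytest.approx(p, abs=1e-12)
        _, w, total = hypergeometric_weights(t)
        assert sum(int(x) for x in w) == total  # probabilities sum to one exactly


# ---------------------------------------------------------------------------
# oracle equivalence and approximation quality
# ---------------------------------------------------------------------------


def test_exact_mann_whitney_matches_enumeration_all_small_sizes():
    rng = np.random.default_rng(5)
    for m in range(1, 7):
        for n in range(1, 9 - m):
            for _ in range(3):
                x = rng.normal(size=m)
                y = rng.normal(size=n)
                assert mann_whitney(x, y).pvalue == pytest.approx(
                    mw_pvalue_enumeration(x, y), abs=1e-12
                )


def test_exact_wilcoxon_matches_enumeration_all_small_sizes():
    rng = np.random.default_rng(6)
    for n in range(2, 9):
        for _ in range(4):
            pre = rng.normal(size=n)
            post = pre + rng.normal(size=n)
            assert wilcoxon_signed_rank(pre, post).pvalue == pytest.approx(
                wilcoxon_pvalue_enumeration(post - pre), abs=1e-12
            )


def test_fisher_matches_enumeration_all_small_tables():
    for a, b, c, d in itertools.product(range(5), repeat=4):
        t = [[a, b], [c, d]]
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        assert fisher_exact_2x2(t).pvalue == pytest.approx(
            fisher_pvalue_enumeration(t), abs=1e-12
        )


def test_normal_approximation_close_to_exact_at_n10():
    rng = np.random.default_rng(8)
    for _ in range(50):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        exact = mann_whitney(x, y, exact_threshold=20).pvalue
        approx = mann_whitney(x, y, exact_threshold=0).pvalue
        assert abs(exact - approx) < 0.02


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


def test_icc_perfect_repeatability_is_one():
    M = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0], [9.0, 9.0]])
    assert icc_single(M).value == pytest.approx(1.0, abs=1e-12)


def test_icc_constant_matrix_undefined():
    with pytest.raises(StatisticsError):
        icc_single(np.full((4, 2), 3.0))


def test_icc_matches_anova_decomposition_and_pingouin():
    M = np.array([[9.0, 2.0, 5.0], [6.0, 1.0, 7.0], [8.0, 4.0, 6.0],
                  [7.0, 1.0, 2.0], [10.0, 5.0, 6.0], [6.0, 2.0, 4.0]])
    n, k = M.shape
    grand = M.mean()
    msr = k * ((M.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((M.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = (((M - grand) ** 2).sum() - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
    expect2 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    expect3 = (msr - mse) / (msr + (k - 1) * mse)
    assert icc_single(M).value == pytest.approx(expect2, abs=1e-9)
    assert icc_single(M, model="icc3").value == pytest.approx(expect3, abs=1e-9)

    pingouin = pytest.importorskip("pingouin")
    df = pd.DataFrame({
        "subject": np.repeat(range(n), k),
        "rater": list(range(k)) * n,
        "value": M.ravel(),
    })
    icc = pingouin.intraclass_corr(df, "subject", "rater", "value").set_index("Type")
    assert icc_single(M).value == pytest.approx(icc.loc["ICC(A,1)", "ICC"], abs=1e-9)
    assert icc_single(M, model="icc3").value == pytest.approx(icc.loc["ICC(C,1)", "ICC"], abs=1e-9)


# ---------------------------------------------------------------------------
# comparison tables
# ---------------------------------------------------------------------------


def _cohort_frame(rng, n=12):
    rows = []
    for group, shift in (("NPH", 0.4), ("AD", 0.3), ("HC", 0.28)):
        for i in range(n):
            rows.append({
                "subject_id": f"{group}-{i}",
                "group": group,
                "ei": rng.normal(shift, 0.03),
                "bci": rng.normal(shift * 0.7, 0.03),
            })
    return pd.DataFrame(rows)


def test_intergroup_table_shape_and_dispatch():
    df = _cohort_frame(np.random.default_rng(3))
    table = build_comparison_table(df, ["ei", "bci"], "group")
    assert list(table.table.index) == ["ei", "bci"]
    assert sum(c.startswith("p ") for c in table.table.columns) == 3  # pairwise
    assert all(r.method.startswith("mann-whitney") for r in table.tests.values())
    assert table.n_comparisons == 6


def test_paired_table_routes_to_wilcoxon():
    rng = np.random.default_rng(4)
    rows = []
    for i in range(10):
        base = rng.normal(0.45, 0.05)
        rows.append({"subject_id": i, "group": "NPH", "timepoint": "pre", "z_evans": base})
        rows.append({"subject_id": i, "group": "NPH", "timepoint": "post", "z_evans": base - 0.01})
    table = build_comparison_table(pd.DataFrame(rows), ["z_evans"], "group", paired_col="timepoint")
    (res,) = table.tests.values()
    assert res.method.startswith("wilcoxon")
    assert res.pvalue < 0.05


def test_missing_group_measure_is_named():
    df = _cohort_frame(np.random.default_rng(5))
    df.loc[df.group == "AD", "bci"] = np.nan
    with pytest.raises(StatisticsError, match="AD.*bci"):
        build_comparison_table(df, ["ei", "bci"], "group")


def test_contingency_fisher_requires_2x2():
    df = pd.DataFrame({"a": ["x", "x", "y", "y"], "b": ["u", "v", "u", "v"]})
    ct, res = contingency_fisher(df, "a", "b")
    assert ct.shape == (2, 2)
    df3 = pd.DataFrame({"a": ["x", "y", "z"], "b": ["u", "v", "u"]})
    with pytest.raises(StatisticsError):
        contingency_fisher(df3, "a", "b")
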