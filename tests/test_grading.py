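"""Probit distribution, line fit, grading and its statistical validation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import ndtri
from scipy.stats import studentized_range

import rsreval as rv
from rsreval.grading import GradingScheme


def test_rank_probit_hand_example_n4():
    # P = [25, 50, 75, 100->93.75]; probit = ndtri(P/100) + 5
    d = rv.rank_probit([0.1, 0.2, 0.3, 0.4])
    np.testing.assert_allclose(d.p_percent, [25, 50, 75, 93.75], atol=1e-12)
    np.testing.assert_allclose(
        d.probit,
        [ndtri(0.25) + 5, 5.0, ndtri(0.75) + 5, ndtri(0.9375) + 5],
        atol=1e-12)


def test_p50_maps_to_probit_5_and_correction_never_100():
    rng = np.random.default_rng(0)
    for n in (2, 4, 10, 31, 100):
        d = rv.rank_probit(rng.uniform(size=n))
        assert np.all(d.p_percent < 100)
        assert d.p_percent.max() == pytest.approx(100 * (1 - 1 / (4 * n)))
        mid = np.isclose(d.p_percent, 50.0)
        assert np.allclose(d.probit[mid], 5.0)


def test_corrected_maximum_for_n31_prints_as_99_2():
    d = rv.rank_probit(np.linspace(0.1, 0.9, 31))
    assert round(d.p_percent.max(), 1) == 99.2
    assert d.probit.max() == pytest.approx(7.406, abs=5e-4)


def test_ties_get_equal_p_without_tiebreak_and_strict_with():
    v = np.array([0.5, 0.2, 0.5, 0.9])
    d = rv.rank_probit(v)
    assert d.p_percent[0] == d.p_percent[2]
    assert d.avg_rank[0] == 2.5
    d2 = rv.rank_probit(v, tie_break=[2, 0, 1, 3])
    assert sorted(d2.avg_rank) == [1, 2, 3, 4]
    assert d2.avg_rank[0] == 3 and d2.avg_rank[2] == 2


def test_rank_probit_rejects_bad_input():
    with pytest.raises(ValueError):
        rv.rank_probit([0.5])
    with pytest.raises(ValueError):
        rv.rank_probit([0.5, np.nan])


def test_fit_line_perfect_fit():
    probit = np.linspace(3, 7, 9)
    d = rv.ProbitDistribution(units=[str(i) for i in range(9)],
                              rsr=0.1 * probit, avg_rank=np.arange(1, 10),
                              p_percent=np.linspace(10, 90, 9), probit=probit)
    fit = rv.fit_line(d)
    assert fit.b == pytest.approx(0.1, abs=1e-12)
    assert fit.a == pytest.approx(0.0, abs=1e-12)
    assert fit.pearson_r == pytest.approx(1.0)
    assert fit.adj_r2 == pytest.approx(1.0)


@given(st.integers(0, 2**31 - 1))
def test_ols_matches_closed_form(seed):
    """Slope/intercept/r agree with the two-parameter least-squares
    formulas to 1e-12 on random small vectors."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 12))
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    if np.ptp(x) == 0:
        return
    d = rv.ProbitDistribution(units=[str(i) for i in range(n)], rsr=y,
                              avg_rank=np.arange(1, n + 1),
                              p_percent=np.linspace(10, 90, n), probit=x)
    fit = rv.fit_line(d)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    b = sxy / sxx
    a = y.mean() - b * x.mean()
    assert fit.b == pytest.approx(b, abs=1e-12, rel=1e-12)
    assert fit.a == pytest.approx(a, abs=1e-12, rel=1e-12)
    syy = ((y - y.mean()) ** 2).sum()
    if syy > 1e-12:
        r = sxy / np.sqrt(sxx * syy)
        assert fit.pearson_r == pytest.approx(r, abs=1e-12, rel=1e-9)


def test_constant_probit_rejected():
    d = rv.ProbitDistribution(units=["a", "b"], rsr=[0.1, 0.2],
                              avg_rank=[1, 2], p_percent=[40, 60],
                              probit=[5.0, 5.0])
    with pytest.raises(ValueError, match="constant"):
        rv.fit_line(d)


def _graded(probit, rsr=None):
    probit = np.asarray(probit, dtype=float)
    rsr = probit * 0.1 if rsr is None else np.asarray(rsr, dtype=float)
    n = probit.size
    d = rv.ProbitDistribution(units=[str(i) for i in range(n)], rsr=rsr,
                              avg_rank=np.arange(1, n + 1),
                              p_percent=np.linspace(5, 95, n), probit=probit)
    return rv.grade(d, rv.fit_line(d))


def test_grade_boundaries_and_critical_values():
    s = _graded([3.0, 4.0, 5.0, 6.0, 7.0])
    assert s.grade == ["Low", "Low", "Medium", "High", "High"]
    # critical values are exactly a + b*cut
    assert s.critical_rsr[0] == pytest.approx(s.a + s.b * 4, abs=1e-15)
    assert s.critical_rsr[1] == pytest.approx(s.a + s.b * 6, abs=1e-15)


def test_grade_unordered_cuts_rejected():
    s = _graded([3.0, 5.0, 7.0])
    d = rv.rank_probit([0.1, 0.5, 0.9])
    fit = rv.fit_line(d)
    with pytest.raises(ValueError, match="increasing"):
        rv.grade(d, fit, cuts=(6.0, 4.0))
    assert s.grade[1] == "Medium"  # interior point


def test_grade_monotone_in_rsr():
    rng = np.random.default_rng(7)
    d = rv.rank_probit(rng.uniform(size=31))
    s = rv.grade(d, rv.fit_line(d))
    order = np.argsort(d.rsr)
    seq = [s.grade[i] for i in order]
    level = {"Low": 0, "Medium": 1, "High": 2}
    assert all(level[a] <= level[b] for a, b in zip(seq, seq[1:]))


def test_snk_oracle_three_separated_groups():
    """Groups {1,2}, {10,11}, {20,21}: explicit studentized-range oracle.

    MSw = 0.5 (df 3), SE = 0.5, so q = 18, 20, 38 for the three pairs --
    all beyond the 5% critical values, hence all significant.
    """
    fitted = np.array([1.0, 2.0, 10.0, 11.0, 20.0, 21.0])
    grades = ["Low", "Low", "Medium", "Medium", "High", "High"]
    scheme = GradingScheme(
        units=[str(i) for i in range(6)], a=0, b=1, pearson_r=1, adj_r2=1,
        probit_cuts=(4, 6), critical_rsr=(4, 6), probit=fitted,
        fitted_rsr=fitted, grade=grades, rsr=fitted)
    v = rv.validate_grades(scheme)
    # independent oracle
    ms_within = (2 * (0.5**2 + 0.5**2) * 3 / 2) / 3  # = 0.5
    se = np.sqrt(ms_within / 2 * (1 / 2 + 1 / 2))
    expected = {
        ("Low", "High"): (19.0 / se, studentized_range.ppf(0.95, 3, 3)),
        ("Low", "Medium"): (9.0 / se, studentized_range.ppf(0.95, 2, 3)),
        ("Medium", "High"): (10.0 / se, studentized_range.ppf(0.95, 2, 3)),
    }
    assert set(v.snk_pairs) == set(expected)
    for pair, (q, q_crit) in expected.items():
        got = v.snk_pairs[pair]
        assert got["q"] == pytest.approx(q, rel=1e-12)
        assert got["q_crit"] == pytest.approx(q_crit, rel=1e-9)
        assert got["significant"]
    assert v.all_pairs_significant()
    assert v.group_sizes == {"Low": 2, "Medium": 2, "High": 2}


def test_snk_blocks_subranges_of_nonsignificant_span():
    # three barely-different groups: overall span not significant, so both
    # sub-pairs must be declared non-significant without testing
    fitted = np.array([1.0, 2.0, 1.2, 2.2, 1.4, 2.4])
    grades = ["Low", "Low", "Medium", "Medium", "High", "High"]
    scheme = GradingScheme(
        units=[str(i) for i in range(6)], a=0, b=1, pearson_r=1, adj_r2=1,
        probit_cuts=(4, 6), critical_rsr=(4, 6), probit=fitted,
        fitted_rsr=fitted, grade=grades, rsr=fitted)
    v = rv.validate_grades(scheme)
    assert not any(r["significant"] for r in v.snk_pairs.values())


def test_anova_zero_when_all_fitted_equal():
    fitted = np.full(6, 0.3)
    scheme = GradingScheme(
        units=[str(i) for i in range(6)], a=0, b=1, pearson_r=1, adj_r2=1,
        probit_cuts=(4, 6), critical_rsr=(4, 6), probit=fitted,
        fitted_rsr=fitted, grade=["Low", "Low", "Medium", "Medium", "High", "High"],
        rsr=fitted)
    v = rv.validate_grades(scheme)
    assert v.anova_F == 0.0 and v.anova_p == 1.0


def test_anova_affine_invariance(result_2009):
    """F computed on fitted values equals F computed on probits, since the
    fitted values are an affine transform of the probits."""
    from scipy.stats import f_oneway
    s = result_2009.schemes["needs"]
    grades = np.asarray(s.grade)
    by_fitted = f_oneway(*(s.fitted_rsr[grades == g] for g in rv.GRADE_LABELS))
    by_probit = f_oneway(*(s.probit[grades == g] for g in rv.GRADE_LABELS))
    assert by_fitted.statistic == pytest.approx(by_probit.statistic, rel=1e-9)


def test_singleton_group_warns_and_restricts_snk():
    fitted = np.array([1.0, 10.0, 11.0, 20.0, 21.0])
    grades = ["Low", "Medium", "Medium", "High", "High"]
    scheme = GradingScheme(
        units=[str(i) for i in range(5)], a=0, b=1, pearson_r=1, adj_r2=1,
        probit_cuts=(4, 6), critical_rsr=(4, 6), probit=fitted,
        fitted_rsr=fitted, grade=grades, rsr=fitted)
    with pytest.warns(UserWarning, match="excluded from SNK"):
        v = rv.validate_grades(scheme)
    assert v.group_sizes == {"Low": 1, "Medium": 2, "High": 2}
    assert set(v.snk_pairs) == {("Medium", "High")}
    assert np.isfinite(v.anova_F)
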