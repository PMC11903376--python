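import numpy as np
import pytest
from hypothesis import given, strategies as st

from egflow.stats import (linreg, load_registry_tables, registry_report,
                          t_test_from_summary, two_prop_z)


# printed registry p-values, verified against the published tables
PROPORTION_CASES = [
    ((2, 9, 13, 16), 0.002),    # prior ablation, PAF vs PeAF
    ((2, 9, 12, 16), 0.005),    # cardioversion history
    ((7, 9, 5, 16), 0.013),     # treated per protocol
    ((11, 13, 2, 8), 0.003),    # FFAF de novo vs redo
    ((9, 10, 5, 11), 0.015),    # FFAF high vs low flow consistency
    ((3, 9, 1, 16), 0.038),     # Type I enrichment in paroxysmal AF
]


@pytest.mark.parametrize("args,expected", PROPORTION_CASES)
def test_proportion_tests_reproduce_published_values(args, expected):
    res = two_prop_z(*args)
    assert round(res.p_one_tailed, 3) == expected


def test_equal_proportions_give_half():
    res = two_prop_z(5, 10, 5, 10)
    assert res.statistic == 0.0
    assert res.p_one_tailed == pytest.approx(0.5)


@given(st.integers(0, 12), st.integers(0, 12))
def test_two_prop_z_antisymmetric_under_group_swap(k1, k2):
    a = two_prop_z(k1, 12, k2, 12)
    b = two_prop_z(k2, 12, k1, 12)
    assert a.statistic == pytest.approx(-b.statistic)
    assert a.p_one_tailed == pytest.approx(b.p_one_tailed)


def test_summary_t_test_reproduces_published_value():
    res = t_test_from_summary(0.9, 1.2, 9, 2.2, 1.3, 16)
    assert round(res.p_one_tailed, 3) == 0.011
    assert res.df == 23


def test_equal_means_give_half():
    res = t_test_from_summary(1.0, 0.5, 5, 1.0, 0.7, 8)
    assert res.p_one_tailed == pytest.approx(0.5)


def test_degenerate_variance_cases():
    eq = t_test_from_summary(1.0, 0.0, 5, 1.0, 0.0, 5)
    assert eq.p_one_tailed == 0.5 and eq.flags
    ne = t_test_from_summary(2.0, 0.0, 5, 1.0, 0.0, 5)
    assert ne.p_one_tailed == 0.0 and ne.flags


def test_t_test_matches_resampling_oracle():
    """One-tailed p agrees with a Monte-Carlo estimate from normal draws at
    the stated moments."""
    m1, sd1, n1, m2, sd2, n2 = 0.9, 1.2, 9, 2.2, 1.3, 16
    res = t_test_from_summary(m1, sd1, n1, m2, sd2, n2)
    rng = np.random.default_rng(0)
    reps = 40_000
    # simulate the null: both groups from the pooled distribution
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    a = rng.normal(0, sp, (reps, n1))
    b = rng.normal(0, sp, (reps, n2))
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    spp = np.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2))
    tnull = (a.mean(axis=1) - b.mean(axis=1)) / (spp * np.sqrt(1 / n1 + 1 / n2))
    p_mc = np.mean(tnull <= res.statistic)
    mc_se = np.sqrt(p_mc * (1 - p_mc) / reps)
    assert abs(p_mc - res.p_one_tailed) < 3 * mc_se + 1e-4


def test_welch_option_differs_from_pooled():
    pooled = t_test_from_summary(1.0, 0.2, 5, 2.0, 2.0, 20)
    welch = t_test_from_summary(1.0, 0.2, 5, 2.0, 2.0, 20, welch=True)
    assert pooled.df != welch.df


def test_exact_line_regression():
    x = np.arange(10.0)
    res = linreg(x, 2 * x + 1)
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == pytest.approx(1.0)
    assert res.r == pytest.approx(1.0)
    assert res.F_p < 1e-10


def test_null_regression_is_insignificant():
    rng = np.random.default_rng(1)
    x = rng.normal(size=100)
    y = rng.normal(size=100)
    res = linreg(x, y)
    assert abs(res.r) < 0.25
    assert res.F_p > 0.05


def test_regression_matches_normal_equations_oracle():
    rng = np.random.default_rng(2)
    x = rng.normal(size=30)
    y = 1.5 * x + rng.normal(size=30)
    res = linreg(x, y)
    A = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.lstsq(A, y, rcond=None)[0]
    assert res.slope == pytest.approx(slope)
    assert res.intercept == pytest.approx(intercept)
    assert res.r_squared == pytest.approx(res.r**2)


def test_constant_x_rejected():
    with pytest.raises(ValueError):
        linreg(np.ones(5), np.arange(5.0))


def test_registry_report_covers_all_fixture_comparisons():
    tables = load_registry_tables()
    df = registry_report()
    assert len(df) == len(tables["proportions"]) + len(tables["means"])
    # every recomputable printed value is reproduced at 3 decimals
    target = {"prior_ablation_paf_vs_peaf": 0.002,
              "cardioversion_paf_vs_peaf": 0.005,
              "per_protocol_paf_vs_peaf": 0.013,
              "ffaf_denovo_vs_redo": 0.003,
              "ffaf_high_vs_low_egfc": 0.015,
              "type_i_paf_vs_peaf": 0.038,
              "sources_per_patient_paf_vs_peaf": 0.011}
    got = dict(zip(df["name"], df["p"]))
    for name, expected in target.items():
        assert round(got[name], 3) == expected
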