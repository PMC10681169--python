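"""Index of dispersion, coefficient of variation, pattern labels, and
group comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lungquad import (DispersionSummary, NoAnalyzableTissueError, classify_pattern,
                      compare_groups, summarize)


def naive_two_pass(values, ddof):
    """Independent oracle: textbook two-pass mean/variance."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - ddof)
    return mean, var


def test_constant_signals_give_zero_dispersion():
    s = summarize([2, 2, 2, 2])
    assert (s.mean, s.variance) == (2.0, 0.0)
    assert s.index_of_dispersion == 0.0
    assert s.coefficient_of_variation == 0.0
    assert s.defined


def test_hand_arithmetic_example():
    s = summarize([0, 0, 0, 8], variance_convention="sample")
    assert s.mean == 2.0
    assert s.variance == 16.0
    assert s.index_of_dispersion == 8.0
    assert s.coefficient_of_variation == 2.0


def test_population_convention():
    s = summarize([0, 0, 0, 8], variance_convention="population")
    assert s.variance == 12.0
    assert s.index_of_dispersion == 6.0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=200),
       st.sampled_from(["sample", "population"]))
def test_matches_naive_two_pass_oracle(values, convention):
    s = summarize(values, variance_convention=convention)
    mean, var = naive_two_pass(values, 1 if convention == "sample" else 0)
    assert s.mean == pytest.approx(mean, rel=1e-12, abs=1e-300)
    assert s.variance == pytest.approx(var, rel=1e-12, abs=1e-9)


def test_poisson_counts_recover_unit_dispersion(rng):
    """Counts simulated from the CSR null (Poisson) give D near 1."""
    for lam in (2.0, 3.0, 5.0):
        d = summarize(rng.poisson(lam, size=1000)).index_of_dispersion
        assert 0.9 <= d <= 1.1


def test_poisson_calibration_mean_and_coverage(rng):
    """Over 200 simulations at lambda = 3 the D estimator is centred on 1
    and the [0.9, 1.1] band covers more than 90% of replicates."""
    ds = np.array([summarize(rng.poisson(3.0, size=1000)).index_of_dispersion
                   for _ in range(200)])
    assert 0.97 <= ds.mean() <= 1.03
    assert np.mean((ds >= 0.9) & (ds <= 1.1)) > 0.9


def test_dispersion_scales_with_signal_but_cv_does_not(rng):
    values = rng.poisson(4.0, size=300).astype(float)
    base = summarize(values)
    for k in (2.0, 7.5):
        scaled = summarize(values * k)
        assert scaled.index_of_dispersion == pytest.approx(k * base.index_of_dispersion, rel=1e-9)
        assert scaled.coefficient_of_variation == pytest.approx(base.coefficient_of_variation, rel=1e-9)


def test_zero_mean_flags_undefined_not_zero():
    s = summarize([0.0, 0.0, 0.0])
    assert not s.defined
    assert math.isnan(s.index_of_dispersion)
    assert math.isnan(s.coefficient_of_variation)
    assert classify_pattern(s) == "unclassifiable"


def test_guards():
    with pytest.raises(NoAnalyzableTissueError):
        summarize([])
    with pytest.raises(ValueError):
        summarize([1.0], variance_convention="sample")


@pytest.mark.parametrize("d,label", [
    (41.90, "clustered"),       # intranasal microsphere regime
    (0.627, "underdispersed"),  # aerosol-chamber regime
    (1.0, "poisson_like"),
    (1.19, "poisson_like"),
    (1.21, "clustered"),
])
def test_pattern_labels(d, label):
    s = DispersionSummary(n_cells=10, mean=1.0, variance=d,
                          index_of_dispersion=d, coefficient_of_variation=1.0,
                          variance_convention="sample")
    assert classify_pattern(s, delta=0.2) == label


def welch_t_oracle(a, b):
    """Closed-form Welch statistic and Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


def test_identical_groups_are_not_distinguished():
    cmp = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert cmp.p_value == pytest.approx(1.0)
    perm = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], test="permutation",
                          rng_seed=7)
    assert perm.p_value > 0.99


def test_separated_groups_reject_null():
    from scipy import stats
    a, b = [1.0, 1.0, 1.0], [100.0, 101.0, 102.0]
    cmp = compare_groups(a, b)
    t, df = welch_t_oracle(a, b)
    assert cmp.statistic == pytest.approx(t, rel=1e-9)
    assert cmp.p_value == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-6)
    assert cmp.p_value < 0.01


def test_swapping_groups_preserves_p_and_negates_t():
    a, b = [0.2, 0.5, 0.9, 0.4], [1.4, 2.0, 1.1]
    ab = compare_groups(a, b)
    ba = compare_groups(b, a)
    assert ab.p_value == pytest.approx(ba.p_value, rel=1e-12)
    assert ab.statistic == pytest.approx(-ba.statistic, rel=1e-12)


def test_permutation_p_granularity_for_three_vs_three():
    """With 3 vs 3 distinct values the exact two-sided permutation p-value
    is a multiple of 1/C(6,3) = 1/20."""
    cmp = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 7.0], test="permutation",
                         rng_seed=0)
    assert (cmp.p_value * 20) == pytest.approx(round(cmp.p_value * 20), abs=1e-9)
    assert 0.0 < cmp.p_value <= 1.0


def test_insufficient_group_size_rejected():
    with pytest.raises(ValueError):
        compare_groups([1.0], [2.0, 3.0])
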