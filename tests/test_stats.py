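"""Test battery: Pitman-Morgan, Friedman gating, post-hocs, routing."""

import math

import numpy as np
import pytest
import scipy.stats as sps

from resuslearn import stats
from resuslearn.types import ValidationError


# ---------------------------------------------------------------------------
# Pitman-Morgan

def test_pitman_morgan_identical_margins():
    x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
    res = stats.pitman_morgan(x, x.copy() + 0.5)  # same variance, shifted
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert res.extra["df"] == 3


def test_pitman_morgan_perfect_correlation_rejected():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(ValidationError, match="perfectly correlated"):
        stats.pitman_morgan(x, 2 * x)


def test_pitman_morgan_zero_variance_rejected():
    with pytest.raises(ValidationError, match="zero variance"):
        stats.pitman_morgan([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_pitman_morgan_too_few_pairs():
    with pytest.raises(ValidationError):
        stats.pitman_morgan([1.0, 2.0], [2.0, 1.0])


def test_pitman_morgan_equals_sum_difference_correlation():
    """Identity: the test equals testing corr(x+y, x-y) = 0 on n-2 df,
    because cov(x+y, x-y) = var(x) - var(y)."""
    rng = np.random.default_rng(31)
    for _ in range(20):
        x = rng.normal(0, 1.3, 15)
        y = 0.4 * x + rng.normal(0, 0.8, 15)
        ours = stats.pitman_morgan(x, y)
        r, p = sps.pearsonr(x + y, x - y)
        assert ours.p_value == pytest.approx(p, rel=1e-9)


def test_pitman_morgan_one_sided_direction():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 3.0, 30)           # larger variance
    y = 0.3 * x + rng.normal(0, 0.5, 30)
    greater = stats.pitman_morgan(x, y, alternative="greater")
    less = stats.pitman_morgan(x, y, alternative="less")
    assert greater.p_value < 0.01
    assert greater.p_value + less.p_value == pytest.approx(1.0)


def test_pitman_morgan_type_one_error_calibrated():
    """Nominal 5% rejection rate on equal-variance correlated normal pairs."""
    rng = np.random.default_rng(77)
    n, sims = 20, 2_000
    rejections = 0
    for _ in range(sims):
        z = rng.normal(size=(n, 2))
        x = z[:, 0]
        y = 0.5 * z[:, 0] + math.sqrt(1 - 0.25) * z[:, 1]  # same variance, r=0.5
        if stats.pitman_morgan(x, y).p_value < 0.05:
            rejections += 1
    rate = rejections / sims
    assert 0.03 < rate < 0.07  # +-4 binomial SE at 2000 sims


# ---------------------------------------------------------------------------
# Friedman gate

def test_friedman_identical_columns_closes_gate():
    m = np.tile(np.arange(10.0)[:, None], (1, 3))
    res = stats.friedman_gate(m)
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    assert res.extra["gate_open"] is False


def test_friedman_matches_scipy_on_three_columns():
    rng = np.random.default_rng(8)
    m = rng.normal(size=(18, 3))
    m[:, 1] += 0.4
    ours = stats.friedman_gate(m)
    stat, p = sps.friedmanchisquare(m[:, 0], m[:, 1], m[:, 2])
    assert ours.statistic == pytest.approx(stat)
    assert ours.p_value == pytest.approx(p)


def test_friedman_strictly_increasing_scores_opens_gate():
    rng = np.random.default_rng(1)
    base = rng.normal(size=20)
    m = np.column_stack([base, base + 1.0, base + 2.0])
    res = stats.friedman_gate(m)
    assert res.p_value < 1e-3
    assert res.extra["gate_open"] is True


def test_friedman_two_learners_flagged_low_power():
    res = stats.friedman_gate(np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 3.0]]))
    assert res.extra["low_power"] is True


def test_friedman_two_timepoints_supported():
    rng = np.random.default_rng(3)
    base = rng.normal(size=30)
    res = stats.friedman_gate(np.column_stack([base, base + 1.0]))
    assert res.p_value < 1e-3


# ---------------------------------------------------------------------------
# post-hocs and Bonferroni

@pytest.fixture
def learning_matrix():
    rng = np.random.default_rng(21)
    base = rng.normal(0.4, 0.1, 24)
    return np.column_stack([base, base + 0.3 + rng.normal(0, 0.05, 24),
                            base + 0.28 + rng.normal(0, 0.05, 24)])


def test_posthoc_refuses_when_gate_closed():
    m = np.tile(np.arange(8.0)[:, None], (1, 3))
    gate = stats.friedman_gate(m)
    with pytest.raises(stats.GateClosedError):
        stats.posthoc_pairwise(m, gate)
    forced = stats.posthoc_pairwise(m, gate, force=True)
    assert len(forced) == 2


@pytest.mark.parametrize("m,corrected", [(2, 0.025), (5, 0.01), (1, 0.05)])
def test_bonferroni_corrected_threshold(learning_matrix, m, corrected):
    gate = stats.friedman_gate(learning_matrix)
    results = stats.posthoc_pairwise(learning_matrix, gate, m=m)
    for res in results:
        assert res.corrected_alpha == pytest.approx(corrected)


def test_bonferroni_rejections_subset_of_uncorrected(learning_matrix):
    gate = stats.friedman_gate(learning_matrix)
    plain = stats.posthoc_pairwise(learning_matrix, gate, m=1)
    strict = stats.posthoc_pairwise(learning_matrix, gate, m=4)
    for a, b in zip(plain, strict):
        assert a.p_value == pytest.approx(b.p_value)  # same test, new threshold
        if b.significant:
            assert a.significant


def test_posthoc_one_sided_detects_improvement(learning_matrix):
    gate = stats.friedman_gate(learning_matrix)
    res = stats.posthoc_pairwise(learning_matrix, gate, pairs=((0, 1),),
                                 alternatives={(0, 1): "less"}, m=2)[0]
    assert res.p_value < 1e-4
    assert res.test_name == "wilcoxon_signed_rank"


# ---------------------------------------------------------------------------
# group comparison

def test_group_compare_identical_multisets_p_one():
    res = stats.group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.test_name == "mann_whitney_u"
    assert res.p_value == pytest.approx(1.0)


def test_group_compare_shifted_one_sided():
    rng = np.random.default_rng(4)
    a = rng.normal(10, 1, 30) + 10
    b = rng.normal(10, 1, 30)
    res = stats.group_compare(a, b, alternative="greater")
    assert res.p_value < 1e-3


def test_group_compare_single_observation_rejected():
    with pytest.raises(ValidationError):
        stats.group_compare([1.0], [2.0])


def test_one_sided_p_not_above_two_sided_in_effect_direction():
    rng = np.random.default_rng(15)
    a = rng.normal(1.0, 1, 25)
    b = rng.normal(0.0, 1, 25)
    one = stats.group_compare(a, b, alternative="greater")
    two = stats.group_compare(a, b, alternative="two_sided")
    assert one.p_value <= two.p_value + 1e-12


# ---------------------------------------------------------------------------
# routing

def test_routing_normal_homogeneous_selects_t_tests():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 60)
    b = rng.normal(0.2, 1, 60)
    plan = stats.build_plan(a, b, paired=False)
    assert plan.chosen_test == "t_independent"
    plan_paired = stats.build_plan(a, b, paired=True)
    assert plan_paired.chosen_test == "t_paired"


def test_routing_nonnormal_selects_nonparametric():
    rng = np.random.default_rng(2)
    a = rng.exponential(1.0, 60)
    b = rng.exponential(1.0, 60)
    plan = stats.build_plan(a, b, paired=False)
    assert plan.chosen_test == "mann_whitney_u"
    assert stats.build_plan(a, b, paired=True).chosen_test == "wilcoxon_signed_rank"


def test_normality_check_extreme_mass_fails():
    x = np.array([0.0] * 19 + [1.0])
    ok, res = stats.normality_check(x)
    assert not ok
    assert res.p_value < 0.05


def test_variance_check_f_test_detects_inflation():
    rng = np.random.default_rng(10)
    a = rng.normal(0, 3, 40)
    b = rng.normal(0, 1, 40)
    ok, res = stats.variance_check(a, b, paired=False, alternative="greater")
    assert not ok
    assert res.test_name == "f_test"
    assert res.statistic > 1


# ---------------------------------------------------------------------------
# Pearson correlation

def test_pearson_r_exact_lines():
    x = np.array([1.0, 2.0, 3.0, 5.0])
    assert stats.pearson_r(x, x).statistic == pytest.approx(1.0)
    assert stats.pearson_r(x, -x).statistic == pytest.approx(-1.0)


def test_pearson_r_constant_rejected():
    with pytest.raises(ValidationError):
        stats.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_pearson_r_independent_small():
    rng = np.random.default_rng(6)
    hits = sum(abs(stats.pearson_r(rng.normal(size=100),
                                   rng.normal(size=100)).statistic) < 0.3
               for _ in range(50))
    assert hits >= 49


# ---------------------------------------------------------------------------
# result container

def test_result_p_value_range_enforced():
    with pytest.raises(ValidationError):
        stats.TestResult(test_name="x", statistic=0.0, p_value=1.5)


def test_result_serializes_with_metadata():
    res = stats.TestResult(test_name="x", statistic=1.0, p_value=0.01,
                           alternative="less", n=(10, 12), alpha_used=0.05,
                           bonferroni_m=2)
    d = res.to_dict()
    assert d["corrected_alpha"] == pytest.approx(0.025)
    assert d["significant"] is True
    assert d["n"] == [10, 12]
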