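"""The study's statistical test battery with explicit routing and correction.

Routing follows the classical scheme: Shapiro-Wilk for normality and a
variance-homogeneity check decide between parametric tests (paired /
independent t) and their conservative nonparametric counterparts
(Wilcoxon signed-rank / Mann-Whitney U).  Repeated measures over the
three test administrations are gated by a Friedman test before any
pairwise post-hoc comparison, and post-hocs carry a Bonferroni-corrected
threshold alpha/m.

The Pitman-Morgan test for equality of variances of two *correlated*
(paired) samples is implemented from its closed form: with variance
ratio F = s_x^2 / s_y^2 and Pearson correlation r of the pairs,

    t = (F - 1) * sqrt(n - 2) / (2 * sqrt(F * (1 - r^2)))

follows a t distribution on n - 2 degrees of freedom under the null.
Equivalently, it is the test for zero correlation between the pairwise
sums x + y and differences x - y, since cov(x+y, x-y) = var(x) - var(y);
that identity serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps

from .types import ValidationError

__all__ = [
    "TestResult",
    "ComparisonPlan",
    "GateClosedError",
    "pitman_morgan",
    "friedman_gate",
    "posthoc_pairwise",
    "group_compare",
    "paired_compare",
    "normality_check",
    "variance_check",
    "pearson_r",
    "build_plan",
    "bonferroni_alpha",
]

ALTERNATIVES = ("two_sided", "less", "greater")
_SCIPY_ALT = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


class GateClosedError(RuntimeError):
    """Post-hoc comparisons refused because the preliminary gate did not open."""


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise corrected threshold alpha/m (m = number of post-hocs)."""
    if m < 1:
        raise ValidationError("m", "Bonferroni factor must be >= 1")
    return alpha / m


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    alternative: str = "two_sided"
    n: int | tuple[int, int] = 0
    alpha_used: float = 0.05
    bonferroni_m: int = 1
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValidationError("p_value", f"p-value {self.p_value} outside [0, 1]")
        if self.alternative not in ALTERNATIVES:
            raise ValidationError("alternative", f"unknown alternative {self.alternative!r}")

    @property
    def corrected_alpha(self) -> float:
        return bonferroni_alpha(self.alpha_used, self.bonferroni_m)

    @property
    def significant(self) -> bool:
        return self.p_value < self.corrected_alpha

    def to_dict(self) -> dict:
        d = asdict(self)
        d["corrected_alpha"] = self.corrected_alpha
        d["significant"] = self.significant
        if isinstance(d["n"], tuple):
            d["n"] = list(d["n"])
        return d


@dataclass(frozen=True)
class ComparisonPlan:
    """Test routing decision for one comparison."""

    paired: bool
    normality_ok: bool
    variance_homogeneity_ok: bool = True

    @property
    def chosen_test(self) -> str:
        if self.paired:
            return "t_paired" if self.normality_ok else "wilcoxon_signed_rank"
        if self.normality_ok and self.variance_homogeneity_ok:
            return "t_independent"
        return "mann_whitney_u"


def _clean_pair(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x", "paired samples must have equal length")
    if x.size < min_n:
        raise ValidationError("x", f"need at least {min_n} pairs, got {x.size}")
    return x, y


# ---------------------------------------------------------------------------
# Pitman-Morgan paired-variance test

def pitman_morgan(x, y, alternative: str = "two_sided",
                  alpha: float = 0.05) -> TestResult:
    """Test equality of variances of two paired samples.

    ``alternative='greater'`` tests var(x) > var(y) (the statistic is
    built from F = s_x^2 / s_y^2).  Degenerate inputs — fewer than three
    pairs, a zero-variance margin, or perfectly correlated pairs
    (|r| = 1, which makes the statistic undefined) — raise a validation
    error rather than returning a number.
    """
    if alternative not in ALTERNATIVES:
        raise ValidationError("alternative", f"unknown alternative {alternative!r}")
    x, y = _clean_pair(x, y, min_n=3)
    n = x.size
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    if vx == 0.0 or vy == 0.0:
        raise ValidationError("x", "zero variance in a margin; variance ratio undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    one_minus_r2 = 1.0 - r * r
    F = vx / vy
    if one_minus_r2 <= 1e-12:
        if abs(F - 1.0) <= 1e-12:
            # y is x up to a shift: variances identical, no evidence either way
            t = 0.0
        else:
            raise ValidationError("x", "pairs are perfectly correlated with unequal "
                                       "variances; statistic undefined")
    else:
        t = (F - 1.0) * math.sqrt(n - 2) / (2.0 * math.sqrt(F * one_minus_r2))
    df = n - 2
    if alternative == "two_sided":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif alternative == "greater":
        p = sps.t.sf(t, df)
    else:
        p = sps.t.cdf(t, df)
    return TestResult(
        test_name="pitman_morgan", statistic=float(t), p_value=float(min(p, 1.0)),
        alternative=alternative, n=n, alpha_used=alpha,
        extra={"variance_ratio": F, "pearson_r": r, "df": df},
    )


# ---------------------------------------------------------------------------
# repeated-measures gate and post-hocs

def _friedman_statistic(m: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square on a (blocks x treatments) matrix.

    Implemented directly (rank within each block, tie correction over
    per-block tied groups) so two-treatment designs are supported, where
    the statistic reduces to a sign test; for k >= 3 it matches
    scipy.stats.friedmanchisquare.
    """
    n, k = m.shape
    ranks = sps.rankdata(m, axis=1)
    ssbn = float((ranks.sum(axis=0) ** 2).sum())
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts ** 3 - counts).sum())
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c <= 0.0:
        # every block fully tied: no rank information, chi-square 0 by convention
        return 0.0, 1.0
    chi2 = (12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)) / c
    return float(chi2), float(sps.chi2.sf(chi2, k - 1))


def friedman_gate(scores_by_timepoint, alpha: float = 0.05) -> TestResult:
    """Friedman rank test across timepoints; the gate for post-hoc pairwise tests.

    ``scores_by_timepoint`` is (learners x timepoints), complete cases
    only.  Fully tied data (every learner identical across timepoints)
    yields statistic 0 and the gate stays closed.  Fewer than five
    learners is allowed but flagged ``low_power`` in the metadata.
    """
    m = np.asarray(scores_by_timepoint, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 2:
        raise ValidationError("scores_by_timepoint",
                              "need at least 2 learners and 2 timepoints")
    if np.isnan(m).any():
        raise ValidationError("scores_by_timepoint", "complete cases only; drop NaN rows first")
    stat, p = _friedman_statistic(m)
    res = TestResult(
        test_name="friedman", statistic=float(stat), p_value=float(p),
        alternative="two_sided", n=int(m.shape[0]), alpha_used=alpha,
        extra={"k_timepoints": int(m.shape[1]), "gate_open": bool(p < alpha),
               "low_power": bool(m.shape[0] < 5)},
    )
    return res


def _wilcoxon(x, y, alternative: str) -> tuple[float, float, dict]:
    """Wilcoxon signed-rank: zero differences dropped; exact null for
    n <= 25 without ties, normal approximation with continuity above."""
    d = np.asarray(x, float) - np.asarray(y, float)
    nz = d[d != 0]
    meta = {"n_zero_dropped": int(d.size - nz.size)}
    if nz.size == 0:
        return 0.0, 1.0, meta | {"method": "degenerate_all_zero"}
    has_ties = np.unique(np.abs(nz)).size < nz.size
    if nz.size <= 25 and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(np.asarray(x, float), np.asarray(y, float),
                       zero_method="wilcox", correction=(method == "approx"),
                       alternative=_SCIPY_ALT[alternative], method=method)
    return float(res.statistic), float(res.pvalue), meta | {"method": method}


def paired_compare(x, y, plan: ComparisonPlan | None = None,
                   alternative: str = "two_sided", alpha: float = 0.05,
                   bonferroni_m: int = 1) -> TestResult:
    """Compare paired samples: Wilcoxon signed-rank, or paired t when the plan allows."""
    if alternative not in ALTERNATIVES:
        raise ValidationError("alternative", f"unknown alternative {alternative!r}")
    x, y = _clean_pair(x, y, min_n=2)
    use_t = plan is not None and plan.paired and plan.normality_ok
    if use_t:
        res = sps.ttest_rel(x, y, alternative=_SCIPY_ALT[alternative])
        stat, p, extra = float(res.statistic), float(res.pvalue), {}
        name = "t_paired"
    else:
        stat, p, extra = _wilcoxon(x, y, alternative)
        name = "wilcoxon_signed_rank"
    return TestResult(test_name=name, statistic=stat, p_value=p,
                      alternative=alternative, n=int(x.size), alpha_used=alpha,
                      bonferroni_m=bonferroni_m, extra=extra)


def posthoc_pairwise(scores_by_timepoint, gate: TestResult,
                     pairs: tuple[tuple[int, int], ...] = ((0, 1), (1, 2)),
                     m: int | None = None,
                     alternatives: dict[tuple[int, int], str] | str = "two_sided",
                     plan: ComparisonPlan | None = None, alpha: float = 0.05,
                     force: bool = False) -> list[TestResult]:
    """Pairwise paired post-hoc tests after an open Friedman gate.

    Each result carries the Bonferroni factor ``m`` (default: the number
    of pairs) and hence the corrected threshold alpha/m.  With the gate
    closed the call refuses (``GateClosedError``) unless ``force=True``,
    which exists to reproduce exploratory tables.
    """
    if not gate.extra.get("gate_open", False) and not force:
        raise GateClosedError(
            f"Friedman gate closed (p = {gate.p_value:.3g} >= alpha = {gate.alpha_used});"
            " post-hoc comparisons refused (pass force=True to override)"
        )
    mat = np.asarray(scores_by_timepoint, dtype=float)
    m_eff = len(pairs) if m is None else m
    results = []
    for (i, j) in pairs:
        alt = alternatives if isinstance(alternatives, str) else alternatives.get((i, j), "two_sided")
        res = paired_compare(mat[:, i], mat[:, j], plan=plan, alternative=alt,
                             alpha=alpha, bonferroni_m=m_eff)
        res.extra["pair"] = (i, j)
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# independent-group comparisons

def group_compare(a, b, plan: ComparisonPlan | None = None,
                  alternative: str = "two_sided", alpha: float = 0.05,
                  bonferroni_m: int = 1) -> TestResult:
    """Compare independent groups: Mann-Whitney U, or independent t when the plan allows.

    The Mann-Whitney p is exact for small samples without ties and uses
    the tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    if alternative not in ALTERNATIVES:
        raise ValidationError("alternative", f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("a", "need at least 2 observations per group")
    use_t = plan is not None and not plan.paired and plan.normality_ok \
        and plan.variance_homogeneity_ok
    if use_t:
        res = sps.ttest_ind(a, b, alternative=_SCIPY_ALT[alternative])
        name, extra = "t_independent", {}
    else:
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        small = max(a.size, b.size) <= 25
        method = "exact" if small else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative=_SCIPY_ALT[alternative],
                               method=method, use_continuity=True)
        name, extra = "mann_whitney_u", {"method": method, "ties": bool(has_ties)}
    return TestResult(test_name=name, statistic=float(res.statistic),
                      p_value=float(res.pvalue), alternative=alternative,
                      n=(int(a.size), int(b.size)), alpha_used=alpha,
                      bonferroni_m=bonferroni_m, extra=extra)


# ---------------------------------------------------------------------------
# routing checks

def normality_check(x, alpha: float = 0.05) -> tuple[bool, TestResult]:
    """Shapiro-Wilk normality; returns (normality_ok, result)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValidationError("x", "Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0.0:
        # constant sample: W undefined; treat as non-normal (no spread to judge)
        res = TestResult(test_name="shapiro_wilk", statistic=math.nan, p_value=0.0,
                         n=int(x.size), alpha_used=alpha, extra={"constant": True})
        return False, res
    stat, p = sps.shapiro(x)
    res = TestResult(test_name="shapiro_wilk", statistic=float(stat), p_value=float(p),
                     n=int(x.size), alpha_used=alpha)
    return bool(p >= alpha), res


def variance_check(a, b, paired: bool = False, alpha: float = 0.05,
                   alternative: str = "two_sided") -> tuple[bool, TestResult]:
    """Variance homogeneity: F-test for independent groups, Pitman-Morgan for paired."""
    if paired:
        res = pitman_morgan(a, b, alternative=alternative, alpha=alpha)
        return bool(res.p_value >= alpha), res
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("a", "F-test needs n >= 3 per group")
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    if va == 0.0 or vb == 0.0:
        raise ValidationError("a", "zero variance in a group; F undefined")
    F = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    if alternative == "two_sided":
        p = 2.0 * min(sps.f.sf(F, dfa, dfb), sps.f.cdf(F, dfa, dfb))
    elif alternative == "greater":
        p = sps.f.sf(F, dfa, dfb)
    else:
        p = sps.f.cdf(F, dfa, dfb)
    res = TestResult(test_name="f_test", statistic=float(F), p_value=float(min(p, 1.0)),
                     alternative=alternative, n=(int(a.size), int(b.size)),
                     alpha_used=alpha, extra={"df": (dfa, dfb)})
    return bool(res.p_value >= alpha), res


def pearson_r(x, y, alpha: float = 0.05) -> TestResult:
    """Pearson linear correlation with its two-sided test."""
    x, y = _clean_pair(x, y, min_n=3)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValidationError("x", "constant input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult(test_name="pearson_r", statistic=float(r), p_value=float(p),
                      n=int(x.size), alpha_used=alpha)


def build_plan(a, b, paired: bool, alpha: float = 0.05) -> ComparisonPlan:
    """Decide the routing for one comparison from normality and variance checks."""
    ok_a, _ = normality_check(a, alpha)
    ok_b, _ = normality_check(b, alpha)
    normal = ok_a and ok_b
    if paired:
        return ComparisonPlan(paired=True, normality_ok=normal)
    if normal:
        try:
            var_ok, _ = variance_check(a, b, paired=False, alpha=alpha)
        except ValidationError:
            var_ok = False
        return ComparisonPlan(paired=False, normality_ok=True,
                              variance_homogeneity_ok=var_ok)
    return ComparisonPlan(paired=False, normality_ok=False,
                          variance_homogeneity_ok=True)
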