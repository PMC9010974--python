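"""Competence stratification, stratified randomization and its validity check.

Learners are stratified by a competence level 0-3: the count of prior
experiences among simulator practice, theoretical training and clinical
practice.  Group allocation is a stratified random split: within each
stratum the two groups receive shares proportional to the global target
sizes (within one learner), so the strata marginals of the two groups
match as closely as the targets allow.

The design's balance is then validated on the pre-training test scores:
the two-sample Kolmogorov-Smirnov distance D of the realized split is
compared, by Monte Carlo, against the D of a large number of completely
random splits of the same roster into the same group sizes.  The check
reports the fraction of random splits that would have done strictly
better (smaller D) than the design — a small fraction certifies that the
stratified design is at least as balanced as almost any random one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import LearnerProfile, ValidationError

__all__ = [
    "Allocation",
    "DesignCheck",
    "competence_level",
    "stratified_assign",
    "ks_distance",
    "monte_carlo_design_check",
]


def competence_level(profile: LearnerProfile) -> int:
    """Competence stratum: number of prior experiences (0 = none, up to 3)."""
    return int(profile.has_simulation) + int(profile.has_theory) + int(profile.has_clinical)


@dataclass(frozen=True)
class Allocation:
    stratum: dict[str, int]   # learner id -> competence level
    group: dict[str, str]     # learner id -> "dgbl" | "classic"
    seed: int

    def group_sizes(self) -> tuple[int, int]:
        g = list(self.group.values())
        return g.count("dgbl"), g.count("classic")


def stratified_assign(profiles: list[LearnerProfile], target_sizes: tuple[int, int],
                      seed: int) -> Allocation:
    """Randomly split learners into (dgbl, classic) groups, stratified by competence.

    Each stratum of size s contributes either floor(s*n1/n) or
    floor(s*n1/n)+1 learners to the first group, so every stratum's split
    mirrors the global n1:n2 ratio within one learner.  The +1 remainders
    go to the strata with the largest fractional quota (ties broken by
    stratum level), which keeps the first group's total exactly n1.
    Reproducible: the same profiles, targets and seed give the same
    allocation.
    """
    n1, n2 = target_sizes
    n = len(profiles)
    if n1 < 0 or n2 < 0 or n1 + n2 != n:
        raise ValidationError("target_sizes", f"sizes {target_sizes} infeasible for {n} learners")
    rng = np.random.default_rng(seed)

    strata: dict[int, list[str]] = {}
    stratum_of: dict[str, int] = {}
    for p in profiles:
        lev = competence_level(p)
        stratum_of[p.learner_id] = lev
        strata.setdefault(lev, []).append(p.learner_id)

    # largest-remainder apportionment of the first group's quota over strata
    levels = sorted(strata)
    quotas = {lev: len(strata[lev]) * n1 / n for lev in levels}
    base = {lev: math.floor(quotas[lev]) for lev in levels}
    deficit = n1 - sum(base.values())
    by_remainder = sorted(levels, key=lambda lev: (-(quotas[lev] - base[lev]), lev))
    take = dict(base)
    for lev in by_remainder[:deficit]:
        take[lev] += 1

    group: dict[str, str] = {}
    for lev in levels:
        members = list(strata[lev])
        rng.shuffle(members)
        for i, lid in enumerate(members):
            group[lid] = "dgbl" if i < take[lev] else "classic"
    return Allocation(stratum=stratum_of, group=group, seed=seed)


def ks_distance(a, b) -> float:
    """Two-sample Kolmogorov-Smirnov distance sup_x |F_a(x) - F_b(x)|.

    Evaluated at the pooled sorted unique values (the ECDF jump points),
    which handles ties exactly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("samples", "both samples must be non-empty")
    a_sorted = np.sort(a)
    b_sorted = np.sort(b)
    grid = np.union1d(a_sorted, b_sorted)
    cdf_a = np.searchsorted(a_sorted, grid, side="right") / a.size
    cdf_b = np.searchsorted(b_sorted, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


@dataclass(frozen=True)
class DesignCheck:
    observed_D: float
    reps: int
    n_better: int          # random splits with D strictly below observed_D
    prop_better: float
    seed: int
    sizes: tuple[int, int] = field(default=(0, 0))


def monte_carlo_design_check(scores, sizes: tuple[int, int], observed_D: float,
                             reps: int = 100_000, seed: int = 0,
                             batch: int = 20_000) -> DesignCheck:
    """Estimate how often a fully random split beats the realized design.

    ``reps`` times, the pooled pre-training scores are randomly divided
    into two groups of the stated sizes (simple random partition, not
    stratified — the null of a completely random design); each split's KS
    distance D is computed and ``prop_better`` is the fraction with
    D strictly below ``observed_D``.

    Vectorized over ties: with the scores sorted once, a random split is
    a random permutation of group labels over sorted positions; D is the
    maximum of |cumulative ECDF difference| read at the last index of
    each tied run.
    """
    scores = np.asarray(scores, dtype=float)
    n1, n2 = sizes
    if n1 < 1 or n2 < 1 or n1 + n2 != scores.size:
        raise ValidationError("sizes", f"sizes {sizes} infeasible for {scores.size} scores")
    if reps < 1:
        raise ValidationError("reps", "need reps >= 1")
    rng = np.random.default_rng(seed)

    order = np.argsort(scores, kind="stable")
    s = scores[order]
    run_end = np.r_[s[1:] != s[:-1], True]  # last index of each tied run
    weights = np.r_[np.full(n1, 1.0 / n1), np.full(n2, -1.0 / n2)]

    n_better = 0
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        perm = np.argsort(rng.random((b, scores.size)), axis=1)
        cum = np.cumsum(weights[perm], axis=1)
        D = np.abs(cum[:, run_end]).max(axis=1)
        n_better += int((D < observed_D).sum())
        done += b
    return DesignCheck(
        observed_D=float(observed_D), reps=reps, n_better=n_better,
        prop_better=n_better / reps, seed=seed, sizes=(n1, n2),
    )
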