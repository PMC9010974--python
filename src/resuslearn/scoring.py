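"""Score functions for the written test, equipment check and timed games.

Knowledge test
    Negative marking: +1 per correct answer, 0 per unanswered question,
    -0.2 per incorrect answer, normalized by the number of questions.
    With six options per question the expected score under uniform random
    answering is exactly zero: (1/6)(+1) + (5/6)(-0.2) = 0 per question.

Equipment check
    Selections are counted per category (totally correct / partially
    correct / incorrect) and reported as the fraction of that category's
    items selected; categories are never netted against each other.

Act-timing regularity
    For a series of acts at times t_1 < ... < t_n, the inter-act
    intervals Delta_i = t_i - t_{i-1} (in hundredths of a second) are
    compared against the allowed interval [min_timing, max_timing] =
    [1/max_freq, 1/min_freq].  The per-act deviation is

        d_i = 0                                          if Delta_i in [min, max]
        d_i = max(|Delta_i - min|, |Delta_i - max|)      otherwise

    i.e. the distance to the FAR endpoint of the allowed band.  A
    ``nearest_endpoint`` mode (distance to the violated bound) is
    available but not the default; the two coincide on which acts score
    zero and disagree only in the magnitude of violations.  The series is
    summarized by the mean of the d_i (0 iff the rhythm never left the
    band) and their standard deviation (irregularity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import (
    ActSeries,
    CATEGORIES,
    ItemBank,
    QUESTION_CATEGORIES,
    RateSpec,
    ResponseSheet,
    SessionLog,
    TimingInterval,
    ValidationError,
)

__all__ = [
    "KnowledgeScore",
    "EquipmentScore",
    "TimingScore",
    "GameSessionScore",
    "INCORRECT_PENALTY",
    "percent_floor",
    "percent_round",
    "score_knowledge",
    "expected_random_score",
    "monte_carlo_random_score",
    "score_equipment",
    "rate_to_interval",
    "act_deviations",
    "score_game_session",
]

#: Marking penalty for an incorrect answer on the written test.
INCORRECT_PENALTY = -0.2

#: Hundredths of a second per minute; 6000 / (acts per minute) is the
#: allowed inter-act interval in hundredths.
_HUNDREDTHS_PER_MINUTE = 6000


def percent_floor(fraction: float, decimals: int = 1) -> float:
    """Fraction -> percentage truncated (floored) to ``decimals`` places.

    Knowledge-test percentages are printed with this truncating
    convention (9/21 -> 42.8, not 42.9).  A tiny epsilon absorbs binary
    float noise just below integer tenths.
    """
    scale = 10 ** decimals
    return math.floor(fraction * 100 * scale + 1e-9) / scale


def percent_round(fraction: float, decimals: int = 1) -> float:
    """Fraction -> percentage rounded half-up to ``decimals`` places.

    Equipment-category percentages use ordinary rounding
    (19/21 -> 90.5, 2/13 -> 15.4).
    """
    scale = 10 ** decimals
    return math.floor(fraction * 100 * scale + 0.5 + 1e-9) / scale


# ---------------------------------------------------------------------------
# written knowledge test

@dataclass(frozen=True)
class KnowledgeScore:
    n_correct: int
    n_incorrect: int
    n_null: int
    raw_points: float
    normalized: float  # raw / n_questions, in [-0.2, 1]

    @property
    def n_questions(self) -> int:
        return self.n_correct + self.n_incorrect + self.n_null

    @property
    def percent(self) -> float:
        """Normalized score as a percentage, truncated to one decimal."""
        return percent_floor(self.normalized)


def score_knowledge(sheet: ResponseSheet, bank: ItemBank,
                    penalty: float = INCORRECT_PENALTY) -> KnowledgeScore:
    """Score one written test sheet against the bank with negative marking."""
    sheet.check_against(bank)
    n_correct = sum(1 for s in sheet.answers.values() if s == "correct")
    n_incorrect = sum(1 for s in sheet.answers.values() if s == "incorrect")
    n_null = bank.n_questions - n_correct - n_incorrect
    raw = n_correct * 1.0 + n_incorrect * penalty
    return KnowledgeScore(
        n_correct=n_correct, n_incorrect=n_incorrect, n_null=n_null,
        raw_points=raw, normalized=raw / bank.n_questions,
    )


def expected_random_score(bank: ItemBank, penalty: float = INCORRECT_PENALTY) -> float:
    """Exact expected normalized score under uniform random answering.

    For a question with k options and one keyed answer the per-question
    expectation is (1/k) + ((k-1)/k) * penalty; the default six-option,
    -0.2 marking scheme makes this exactly zero by construction.
    """
    total = 0.0
    for q in bank.questions:
        k = len(q.options)
        total += 1.0 / k + (k - 1) / k * penalty
    return total / bank.n_questions


def monte_carlo_random_score(bank: ItemBank, reps: int = 100_000, seed: int = 0,
                             penalty: float = INCORRECT_PENALTY) -> dict:
    """Simulate ``reps`` uniformly-random sheets; report mean and its SE.

    A consistency check on :func:`expected_random_score`: the simulated
    mean should fall within a few standard errors of the analytic value.
    """
    if reps < 1:
        raise ValidationError("reps", "need reps >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([1.0 / len(q.options) for q in bank.questions])
    correct = rng.random((reps, bank.n_questions)) < p  # random answer hits key
    n_correct = correct.sum(axis=1)
    raw = n_correct + (bank.n_questions - n_correct) * penalty
    normalized = raw / bank.n_questions
    mean = float(normalized.mean())
    se = float(normalized.std(ddof=1) / math.sqrt(reps))
    return {"mean": mean, "se": se, "reps": reps, "seed": seed,
            "analytic": expected_random_score(bank, penalty)}


# ---------------------------------------------------------------------------
# equipment check

@dataclass(frozen=True)
class EquipmentScore:
    n_totally: int
    n_partial: int
    n_incorrect: int
    frac_totally: float
    frac_partial: float
    frac_incorrect: float

    def fraction(self, category: str) -> float:
        return {
            "totally_correct": self.frac_totally,
            "partially_correct": self.frac_partial,
            "incorrect": self.frac_incorrect,
        }[category]

    def percent(self, category: str) -> float:
        """Category fraction as a percentage, rounded to one decimal."""
        return percent_round(self.fraction(category))


def score_equipment(selected: frozenset[str] | set[str], bank: ItemBank) -> EquipmentScore:
    """Count selected items per category and normalize by category size."""
    unknown = set(selected) - bank.equipment_ids
    if unknown:
        raise ValidationError("selected", f"unknown equipment ids {sorted(unknown)}")
    sizes = bank.category_sizes()
    counts = {c: 0 for c in CATEGORIES}
    by_id = {e.id: e.category for e in bank.equipment_items}
    for item in selected:
        counts[by_id[item]] += 1
    return EquipmentScore(
        n_totally=counts["totally_correct"],
        n_partial=counts["partially_correct"],
        n_incorrect=counts["incorrect"],
        frac_totally=counts["totally_correct"] / sizes["totally_correct"],
        frac_partial=counts["partially_correct"] / sizes["partially_correct"],
        frac_incorrect=counts["incorrect"] / sizes["incorrect"],
    )


# ---------------------------------------------------------------------------
# act-timing regularity

def rate_to_interval(spec: RateSpec) -> TimingInterval:
    """Convert an acts/min band to the allowed inter-act interval.

    The effective frequency adds the virtual assistant's interleaved acts
    (``assistant_offset_per_min``; 30 for chest compressions).  Bounds are
    expressed in hundredths of a second and truncated (floored) to
    integers: a 80-100/min compression band with the +30 assistant share
    gives 6000/130 = 46.15 -> 46 and 6000/110 = 54.54 -> 54.
    """
    lo_freq = spec.min_freq + spec.assistant_offset_per_min
    hi_freq = spec.max_freq + spec.assistant_offset_per_min
    if lo_freq <= 0 or hi_freq <= 0:
        raise ValidationError("min_freq", "effective frequencies must be positive")
    raw_lo = _HUNDREDTHS_PER_MINUTE / hi_freq
    raw_hi = _HUNDREDTHS_PER_MINUTE / lo_freq
    if raw_hi - raw_lo < 1.0:
        raise ValidationError(
            "max_freq",
            f"band [{spec.min_freq}, {spec.max_freq}] acts/min is narrower than one "
            "hundredth of a second; degenerate timing interval",
        )
    min_timing = math.floor(raw_lo)
    max_timing = math.floor(raw_hi)
    if min_timing >= max_timing:
        raise ValidationError(
            "max_freq",
            f"degenerate interval [{min_timing}, {max_timing}] from band "
            f"[{spec.min_freq}, {spec.max_freq}] (+{spec.assistant_offset_per_min})",
        )
    return TimingInterval(min_timing=min_timing, max_timing=max_timing)


@dataclass(frozen=True)
class TimingScore:
    """Per-act deviations (hundredths of a second) and their summaries.

    ``score_mean`` is 0 iff every interval stayed inside the allowed
    band; for series with fewer than two acts both summaries are NaN
    (undefined-as-missing, never reported as a perfect 0).
    """

    deviations: tuple[float, ...]
    score_mean: float
    score_std: float

    @property
    def n_intervals(self) -> int:
        return len(self.deviations)


def act_deviations(series: ActSeries, interval: TimingInterval,
                   mode: str = "far_endpoint", ddof: int = 0) -> TimingScore:
    """Deviation statistic of an act series against the allowed interval.

    Timestamps (seconds) are converted to inter-act intervals in
    hundredths of a second.  ``mode`` selects the deviation magnitude for
    out-of-band intervals: ``far_endpoint`` (default, the printed
    definition: max of the distances to the two bounds) or
    ``nearest_endpoint`` (distance to the violated bound).  ``ddof``
    selects the standard-deviation divisor (0 = population, default).
    """
    if mode not in ("far_endpoint", "nearest_endpoint"):
        raise ValidationError("mode", f"unknown deviation mode {mode!r}")
    ts = np.asarray(series.timestamps, dtype=float)
    if ts.size < 2:
        return TimingScore(deviations=(), score_mean=math.nan, score_std=math.nan)
    deltas = np.diff(ts) * 100.0  # seconds -> hundredths
    lo, hi = float(interval.min_timing), float(interval.max_timing)
    inside = (deltas >= lo) & (deltas <= hi)
    d_lo = np.abs(deltas - lo)
    d_hi = np.abs(deltas - hi)
    if mode == "far_endpoint":
        dev = np.maximum(d_lo, d_hi)
    else:
        dev = np.minimum(d_lo, d_hi)
    dev = np.where(inside, 0.0, dev)
    return TimingScore(
        deviations=tuple(float(x) for x in dev),
        score_mean=float(dev.mean()),
        score_std=float(dev.std(ddof=ddof)),
    )


# ---------------------------------------------------------------------------
# in-game session scores

@dataclass(frozen=True)
class GameSessionScore:
    """Per-category knowledge fraction, response-time medians, equipment check.

    The knowledge fraction is (number correct) / (questions asked); a
    "get help" choice is neutral — it stays in the denominator and
    contributes nothing to the numerator, so the fraction lives in [0, 1].
    ``points`` applies the in-game marking (+1 correct, configurable
    penalty for incorrect, 0 for help), normalized the same way.
    """

    fraction_correct: dict[str, float]        # per category present in session
    points: dict[str, float]
    median_response_time: dict[str, float]    # seconds, per category
    overall_median_response_time: float
    equipment: EquipmentScore


def score_game_session(log: SessionLog, bank: ItemBank,
                       penalty: float = INCORRECT_PENALTY) -> GameSessionScore:
    """Score one game session's question events and 1-minute equipment check."""
    from .types import SESSION_CATEGORIES  # local to avoid cycle at import time

    fractions: dict[str, float] = {}
    points: dict[str, float] = {}
    medians: dict[str, float] = {}
    for cat in QUESTION_CATEGORIES:
        if cat not in SESSION_CATEGORIES[log.session_number]:
            continue
        events = log.events_in_category(cat)
        if not events:
            raise ValidationError(
                "question_events",
                f"session {log.session_number} expects category {cat!r} but has no events",
            )
        n = len(events)
        n_correct = sum(1 for ev in events if ev.outcome == "correct")
        n_incorrect = sum(1 for ev in events if ev.outcome == "incorrect")
        fractions[cat] = n_correct / n
        points[cat] = (n_correct + n_incorrect * penalty) / n
        medians[cat] = float(np.median([ev.response_time for ev in events]))
    overall = float(np.median([ev.response_time for ev in log.question_events]))
    return GameSessionScore(
        fraction_correct=fractions,
        points=points,
        median_response_time=medians,
        overall_median_response_time=overall,
        equipment=score_equipment(log.equipment_selected, bank),
    )
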