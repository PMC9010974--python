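"""Scoring module: negative marking, equipment categories, timing statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resuslearn import scoring
from resuslearn.types import ActSeries, RateSpec, TimingInterval, ValidationError


# ---------------------------------------------------------------------------
# knowledge test

@pytest.mark.parametrize(
    "n_correct,n_incorrect,n_null,raw,percent",
    [
        (21, 0, 0, 21.0, 100.0),          # perfect sheet
        (0, 21, 0, -4.2, -20.0),          # all wrong: -0.2 per question
        (15, 0, 6, 15.0, 71.4),
        (18, 2, 1, 17.6, 83.8),
        (9, 0, 12, 9.0, 42.8),            # truncating percent convention
        (0, 0, 21, 0.0, 0.0),
    ],
)
def test_knowledge_marking(make_sheet, bank, n_correct, n_incorrect, n_null, raw, percent):
    ks = scoring.score_knowledge(make_sheet(n_correct, n_incorrect, n_null), bank)
    assert ks.raw_points == pytest.approx(raw)
    assert ks.normalized == pytest.approx(raw / 21)
    assert ks.percent == percent
    assert ks.n_questions == bank.n_questions


def test_knowledge_requires_full_coverage(bank, make_sheet):
    sheet = make_sheet(21, 0, 0)
    partial = sheet.answers.copy()
    partial.pop(bank.question_ids[0])
    bad = type(sheet)(learner_id="L001", timepoint="test0", answers=partial)
    with pytest.raises(ValidationError, match="misses"):
        scoring.score_knowledge(bad, bank)


@given(data=st.data())
@settings(max_examples=50, deadline=None)
def test_knowledge_monotone_in_single_answer(data):
    """Upgrading one answer incorrect -> null -> correct never lowers the score."""
    from resuslearn.io import default_item_bank
    from resuslearn.types import ResponseSheet

    bank = default_item_bank()
    states = data.draw(st.lists(st.sampled_from(["correct", "incorrect", "null"]),
                                min_size=21, max_size=21))
    q = data.draw(st.integers(min_value=0, max_value=20))
    order = ["incorrect", "null", "correct"]

    def score_with(state_q):
        s = list(states)
        s[q] = state_q
        sheet = ResponseSheet("L", "test0", dict(zip(bank.question_ids, s)))
        return scoring.score_knowledge(sheet, bank).normalized

    values = [score_with(s) for s in order]
    assert values == sorted(values)


def test_expected_random_score_is_zero_for_default_marking(bank):
    assert scoring.expected_random_score(bank) == pytest.approx(0.0, abs=1e-12)


def test_expected_random_score_general_form(bank):
    # 1-of-2 options with the same -0.2 penalty: (1/2)(1) + (1/2)(-0.2) = 0.4
    from resuslearn.types import ItemBank, QuestionSpec

    q = QuestionSpec(id="q1", options=("a", "b"), correct="a")
    two = ItemBank(questions=(q,), equipment_items=bank.equipment_items)
    assert scoring.expected_random_score(two) == pytest.approx(0.4)


def test_monte_carlo_agrees_with_analytic(bank):
    mc = scoring.monte_carlo_random_score(bank, reps=20_000, seed=7)
    assert abs(mc["mean"] - mc["analytic"]) < 3 * mc["se"]


# ---------------------------------------------------------------------------
# equipment check

def test_equipment_fractions_and_percent(select_items, bank):
    es = scoring.score_equipment(
        select_items(totally_correct=19, partially_correct=2, incorrect=2), bank)
    assert (es.n_totally, es.n_partial, es.n_incorrect) == (19, 2, 2)
    assert es.percent("totally_correct") == 90.5
    assert es.percent("partially_correct") == 33.3
    assert es.percent("incorrect") == 15.4


def test_equipment_empty_selection(bank):
    es = scoring.score_equipment(frozenset(), bank)
    assert es.frac_totally == es.frac_partial == es.frac_incorrect == 0.0


def test_equipment_unknown_item_rejected(bank):
    with pytest.raises(ValidationError, match="unknown equipment"):
        scoring.score_equipment({"nonsense"}, bank)


@given(st.data())
@settings(max_examples=30, deadline=None)
def test_equipment_count_conservation(data):
    """Selected + unselected fractions sum to 1 within each category."""
    from resuslearn.io import default_item_bank

    bank = default_item_bank()
    ids = sorted(bank.equipment_ids)
    picked = data.draw(st.sets(st.sampled_from(ids)))
    es = scoring.score_equipment(frozenset(picked), bank)
    complement = scoring.score_equipment(frozenset(ids) - frozenset(picked), bank)
    for cat in ("totally_correct", "partially_correct", "incorrect"):
        assert es.fraction(cat) + complement.fraction(cat) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# rate -> interval

@pytest.mark.parametrize(
    "spec,expected",
    [
        (RateSpec(40, 60, 0), (100, 150)),     # ventilation band
        (RateSpec(80, 100, 30), (46, 54)),     # compressions + assistant breaths
    ],
)
def test_rate_to_interval_printed_bounds(spec, expected):
    iv = scoring.rate_to_interval(spec)
    assert (iv.min_timing, iv.max_timing) == expected


def test_rate_to_interval_truncates_not_rounds():
    # 6000/110 = 54.54..., 6000/130 = 46.15...: floored, never rounded up
    iv = scoring.rate_to_interval(RateSpec(80, 100, 30))
    assert iv.max_timing == 54 and iv.min_timing == 46


def test_rate_to_interval_degenerate_band_rejected():
    with pytest.raises(ValidationError):
        scoring.rate_to_interval(RateSpec(60, 60.0001, 0))


# ---------------------------------------------------------------------------
# act-timing deviations

VENT = TimingInterval(100, 150)


def series_from_deltas(deltas_hundredths):
    """Act series starting at t=0 whose inter-act intervals are the deltas."""
    ts = np.concatenate([[0.0], np.cumsum(np.asarray(deltas_hundredths, float))]) / 100.0
    return ActSeries("ventilation", tuple(float(t) for t in ts))


def oracle_deviations(deltas, lo, hi, mode="far_endpoint"):
    """Literal per-element evaluation of the deviation definition."""
    out = []
    for d in deltas:
        if lo <= d <= hi:
            out.append(0.0)
        elif mode == "far_endpoint":
            out.append(max(abs(d - lo), abs(d - hi)))
        else:
            out.append(min(abs(d - lo), abs(d - hi)))
    return out


def test_perfect_rhythm_scores_zero():
    ts = scoring.act_deviations(series_from_deltas([120] * 24), VENT)
    assert ts.score_mean == 0.0 and ts.score_std == 0.0


@pytest.mark.parametrize(
    "delta,expected",
    [
        (200, 100.0),   # above band: far endpoint is the lower bound
        (80, 70.0),     # below band: far endpoint is the upper bound
        (100, 0.0),     # endpoints are inside (closed interval)
        (150, 0.0),
    ],
)
def test_single_interval_far_endpoint(delta, expected):
    ts = scoring.act_deviations(series_from_deltas([delta]), VENT)
    assert ts.deviations[0] == pytest.approx(expected)


def test_nearest_endpoint_mode():
    ts = scoring.act_deviations(series_from_deltas([200]), VENT, mode="nearest_endpoint")
    assert ts.deviations[0] == pytest.approx(50.0)


def test_short_series_is_missing_not_zero():
    ts = scoring.act_deviations(ActSeries("ventilation", (1.0,)), VENT)
    assert math.isnan(ts.score_mean) and math.isnan(ts.score_std)
    assert ts.n_intervals == 0


@given(st.data())
@settings(max_examples=200, deadline=None)
def test_deviations_match_bruteforce_oracle(data):
    deltas = data.draw(st.lists(st.floats(min_value=1.0, max_value=400.0),
                                min_size=1, max_size=30))
    mode = data.draw(st.sampled_from(["far_endpoint", "nearest_endpoint"]))
    series = series_from_deltas(deltas)
    ts = scoring.act_deviations(series, VENT, mode=mode)
    # oracle over the intervals as the implementation sees them, so exact
    # boundary cases are judged identically on both routes
    recovered = (np.diff(series.timestamps) * 100.0).tolist()
    expected = oracle_deviations(recovered, 100, 150, mode)
    assert np.allclose(ts.deviations, expected, atol=1e-9)
    assert ts.score_mean == pytest.approx(np.mean(expected))
    assert ts.score_std == pytest.approx(np.std(expected))


@given(st.data())
@settings(max_examples=60, deadline=None)
def test_widening_interval_never_increases_deviations(data):
    deltas = data.draw(st.lists(st.integers(min_value=5, max_value=400),
                                min_size=2, max_size=20))
    lo = data.draw(st.integers(min_value=50, max_value=120))
    hi = data.draw(st.integers(min_value=lo + 10, max_value=300))
    widen = data.draw(st.integers(min_value=1, max_value=40))
    s = series_from_deltas(deltas)
    narrow = scoring.act_deviations(s, TimingInterval(lo, hi), mode="nearest_endpoint")
    wide = scoring.act_deviations(
        s, TimingInterval(max(1, lo - widen), hi + widen), mode="nearest_endpoint")
    assert all(w <= n + 1e-9 for n, w in zip(narrow.deviations, wide.deviations))


def test_score_mean_translation_and_scale_invariance():
    deltas = [90, 130, 170, 200]
    s = series_from_deltas(deltas)
    shifted = ActSeries("ventilation", tuple(t + 7.5 for t in s.timestamps))
    base = scoring.act_deviations(s, VENT)
    assert scoring.act_deviations(shifted, VENT).score_mean == pytest.approx(base.score_mean)
    doubled = series_from_deltas([2 * d for d in deltas])
    scaled = scoring.act_deviations(doubled, TimingInterval(200, 300))
    assert scaled.score_mean == pytest.approx(2 * base.score_mean)


def test_std_divisor_switchable():
    s = series_from_deltas([200, 200, 80])
    pop = scoring.act_deviations(s, VENT, ddof=0)
    samp = scoring.act_deviations(s, VENT, ddof=1)
    assert samp.score_std > pop.score_std


# ---------------------------------------------------------------------------
# game-session scores

def test_session_fraction_counts_get_help_in_denominator(bank):
    from resuslearn.types import QuestionEvent, SessionLog

    events = [
        QuestionEvent("c1", "care_ppv", "correct", 10.0),
        QuestionEvent("c2", "care_ppv", "correct", 12.0),
        QuestionEvent("c3", "care_ppv", "get_help", 14.0),
        QuestionEvent("c4", "care_ppv", "incorrect", 16.0),
    ]
    log = SessionLog("L001", 2, tuple(events))
    gs = scoring.score_game_session(log, bank)
    assert gs.fraction_correct["care_ppv"] == pytest.approx(0.5)  # 2 of 4
    assert gs.points["care_ppv"] == pytest.approx((2 - 0.2) / 4)
    assert gs.median_response_time["care_ppv"] == pytest.approx(13.0)


def test_session_all_correct_and_median_time(bank):
    from resuslearn.types import QuestionEvent, SessionLog

    events = [QuestionEvent(f"q{i}", "care_ppv", "correct", t)
              for i, t in enumerate([10.0, 12.0, 14.0])]
    gs = scoring.score_game_session(SessionLog("L001", 2, tuple(events)), bank)
    assert gs.fraction_correct["care_ppv"] == 1.0
    assert gs.overall_median_response_time == 12.0


def test_session_missing_expected_category_rejected(bank):
    from resuslearn.types import QuestionEvent, SessionLog

    # session 1 must cover all three categories
    events = (QuestionEvent("q1", "care_ppv", "correct", 5.0),)
    with pytest.raises(ValidationError, match="no events"):
        scoring.score_game_session(SessionLog("L001", 1, events), bank)
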