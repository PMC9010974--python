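"""Synthetic study generator: cohorts, written tests, game sessions, act series.

No per-learner data from real training studies of this kind is publicly
deposited, so every downstream stage of the pipeline is exercised on
synthetic cohorts from this module.  The generative model is deliberately
simple and structural:

* each learner carries a latent probability of answering a question
  correctly (*ability*), drawn around a per-stratum baseline — not a
  psychometric item-response model;
* training adds a per-group gain to ability for the post-test, and the
  follow-up subtracts a retention loss; game-session ability follows a
  learning curve with per-session increments that plateau at the last
  session;
* question outcomes are independent Bernoulli draws given ability;
  wrong answers split between "incorrect" and "null"/"get help";
* response times are lognormal around a median that decays
  multiplicatively session over session;
* act series accumulate Gaussian inter-act intervals around a target
  plus a systematic offset (too fast / too slow), with non-positive
  intervals resampled so timestamps stay strictly increasing.

Defaults emulate the qualitative pattern of a resident cohort: pre-test
scores around 43%, post-test around 70-84% with the game group ahead,
stable follow-up, session scores rising from ~65% toward ~95% with a
plateau between the last two sessions, response times decaying ~12 s to
~8 s, ventilation rhythm improving with practice while chest-compression
rhythm stays too fast and irregular.  These are structural fixtures, not
empirical claims.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design, scoring
from .types import (
    ActSeries,
    CATEGORIES,
    ItemBank,
    LearnerProfile,
    QuestionEvent,
    ResponseSheet,
    SESSION_CATEGORIES,
    COMPRESSION_SESSIONS,
    SessionLog,
    StudyFrame,
    TIMEPOINTS,
    RateSpec,
    ValidationError,
)
from .io import default_item_bank

__all__ = [
    "CohortConfig",
    "TimingModel",
    "LearningModel",
    "SimulatedStudy",
    "simulate_cohort",
    "simulate_act_series",
    "parameter_recovery_suite",
    "VENTILATION_RATE",
    "COMPRESSION_RATE",
]

#: Clinical target bands: 40-60 ventilations/min; 80-100 compressions/min
#: with the assistant's 30 interleaved breaths.
VENTILATION_RATE = RateSpec(min_freq=40, max_freq=60, assistant_offset_per_min=0)
COMPRESSION_RATE = RateSpec(min_freq=80, max_freq=100, assistant_offset_per_min=30)

#: Questions per in-game category (invented session content sizes).
SESSION_QUESTION_COUNTS = {"care_ppv": 8, "intubation_compression": 6, "drugs": 4}

_GAME_DURATION_S = 30.0  # each timed rhythm game lasts 30 s


@dataclass(frozen=True)
class CohortConfig:
    """Cohort structure: size, competence mix, group split.

    Defaults mirror a 48-learner resident cohort split 27 (classic
    teaching) / 21 (game group), with mostly junior, low-experience
    members: ~46% with no prior experience and ~10% with all three.
    """

    n_learners: int = 48
    group_sizes: tuple[int, int] = (21, 27)  # (dgbl, classic)
    strata_proportions: tuple[float, float, float, float] = (0.46, 0.27, 0.17, 0.10)
    year_proportions: tuple[float, ...] = (0.28, 0.28, 0.20, 0.14, 0.10)
    dropout_rate: float = 0.0  # probability a learner misses the follow-up test
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.strata_proportions) - 1.0) > 1e-9:
            raise ValidationError("strata_proportions", "must sum to 1")
        if sum(self.group_sizes) != self.n_learners:
            raise ValidationError("group_sizes",
                                  f"{self.group_sizes} do not sum to {self.n_learners}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate", "must be in [0, 1)")


@dataclass(frozen=True)
class TimingModel:
    """Inter-act interval model for one rhythm game.

    ``offset`` (hundredths of a second) is a systematic bias added to the
    target interval — negative means acts come too fast; ``jitter_sd``
    is the Gaussian spread; ``improvement`` multiplies both once per
    session (1.0 = no learning, as observed for chest compressions).
    """

    jitter_sd: float
    offset: float
    improvement: float = 1.0

    def at_session(self, session: int) -> tuple[float, float]:
        f = self.improvement ** (session - 1)
        return self.jitter_sd * f, self.offset * f


def _per_group(value) -> dict[str, float]:
    if isinstance(value, dict):
        return {"dgbl": float(value["dgbl"]), "classic": float(value["classic"])}
    return {"dgbl": float(value), "classic": float(value)}


def _default_equipment_probs() -> dict:
    """P(select item) per category/timepoint/group on the written test."""
    return {
        "totally_correct": {"test0": _per_group(0.57),
                            "test1": {"dgbl": 0.90, "classic": 0.71},
                            "test2": {"dgbl": 0.90, "classic": 0.71}},
        "partially_correct": {"test0": _per_group(0.33),
                              "test1": {"dgbl": 0.33, "classic": 0.50},
                              "test2": {"dgbl": 0.33, "classic": 0.50}},
        "incorrect": {"test0": _per_group(0.23),
                      "test1": {"dgbl": 0.15, "classic": 0.23},
                      "test2": {"dgbl": 0.15, "classic": 0.23}},
    }


@dataclass(frozen=True)
class LearningModel:
    """Learning dynamics for written tests and game sessions."""

    # written test: latent P(correct) baseline per competence stratum
    baseline_ability: tuple[float, float, float, float] = (0.42, 0.50, 0.58, 0.66)
    ability_sd: float = 0.08
    test_gain: dict | float = field(default_factory=lambda: {"dgbl": 0.40, "classic": 0.28})
    test_gain_sd: float = 0.05
    retention_loss: dict | float = field(default_factory=lambda: {"dgbl": 0.01, "classic": 0.05})
    retention_sd: dict | float = field(default_factory=lambda: {"dgbl": 0.03, "classic": 0.07})
    guess_rate: float = 0.8        # P(answer rather than leave null | not known)
    # game sessions
    session_bonus: float = 0.20    # session-1 ability above test-0 ability
    gain_per_session: tuple[float, float, float] = (0.15, 0.10, 0.02)  # plateau at the end
    get_help_rate: float = 0.08    # P(ask the assistant | not known), in-game only
    response_time_start: float = 11.9       # median seconds, session 1
    response_time_decay: float = 0.865      # multiplicative per session
    response_time_cv: float = 0.25          # lognormal sigma
    # session equipment check
    session_equip_start: float = 0.24
    session_equip_gain: float = 0.107       # per session, totally-correct selection prob
    session_equip_wrong: float = 0.05       # partial/incorrect selection prob, flat
    # rhythm games
    ventilation_timing: TimingModel = TimingModel(jitter_sd=30.0, offset=35.0, improvement=0.55)
    compression_timing: TimingModel = TimingModel(jitter_sd=15.0, offset=-12.0, improvement=1.0)
    deterministic: bool = False    # expected-value outcomes, no sampling noise

    def session_ability(self, baseline: float, session: int) -> float:
        a = baseline + self.session_bonus + sum(self.gain_per_session[: session - 1])
        return float(np.clip(a, 0.0, 1.0))


@dataclass
class SimulatedStudy:
    """A complete synthetic study plus the latent truth that generated it."""

    frame: StudyFrame
    sheets: list[ResponseSheet]
    logs: list[SessionLog]
    bank: ItemBank
    truth: dict
    seed: int


def simulate_act_series(target_interval: float, duration: float = _GAME_DURATION_S,
                        jitter_sd: float = 0.0, offset: float = 0.0,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None,
                        kind: str = "ventilation",
                        assistant_offset_per_min: int = 0) -> ActSeries:
    """Generate one act series: intervals ~ target + offset + noise.

    ``target_interval`` and ``offset`` are in hundredths of a second;
    ``duration`` in seconds.  Non-positive intervals are resampled so the
    series is strictly increasing; acts accumulate until the duration is
    exceeded (an act landing exactly on the final whistle counts).
    """
    if target_interval <= 0 or duration <= 0:
        raise ValidationError("target_interval", "target interval and duration must be > 0")
    mean = target_interval + offset
    if mean <= 0:
        raise ValidationError("offset", f"mean interval {mean} is not positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    max_acts = int(duration * 100 / mean * 4) + 64  # generous cap
    if jitter_sd == 0.0:
        deltas = np.full(max_acts, mean)
    else:
        deltas = rng.normal(mean, jitter_sd, size=max_acts)
        for _ in range(64):
            bad = deltas <= 0
            if not bad.any():
                break
            deltas[bad] = rng.normal(mean, jitter_sd, size=int(bad.sum()))
        else:  # pragma: no cover - pathological parameters
            raise ValidationError("jitter_sd", "could not sample positive intervals")
    times = np.cumsum(deltas) / 100.0  # hundredths -> seconds
    times = times[times <= duration + 1e-9]
    return ActSeries(kind=kind, timestamps=tuple(float(t) for t in times),
                     assistant_offset_per_min=assistant_offset_per_min)


# ---------------------------------------------------------------------------
# cohort generation

_COMBOS = {k: list(itertools.combinations(("has_simulation", "has_theory", "has_clinical"), k))
           for k in range(4)}


def _draw_profiles(config: CohortConfig, rng: np.random.Generator) -> list[LearnerProfile]:
    strata = rng.choice(4, size=config.n_learners, p=np.asarray(config.strata_proportions))
    years = rng.choice(np.arange(1, len(config.year_proportions) + 1),
                       size=config.n_learners, p=np.asarray(config.year_proportions))
    profiles = []
    for i in range(config.n_learners):
        k = int(strata[i])
        combo = _COMBOS[k][int(rng.integers(len(_COMBOS[k])))] if k else ()
        flags = {f: (f in combo) for f in ("has_simulation", "has_theory", "has_clinical")}
        profiles.append(LearnerProfile(learner_id=f"L{i + 1:03d}",
                                       specialty_year=int(years[i]), **flags))
    return profiles


def _draw_answers(bank: ItemBank, ability: float, guess_rate: float,
                  rng: np.random.Generator, deterministic: bool) -> dict[str, str]:
    qids = bank.question_ids
    n = len(qids)
    if deterministic:
        n_correct = int(round(ability * n))
        states = ["correct"] * n_correct + ["null"] * (n - n_correct)
    else:
        u = rng.random(n)
        states = np.where(u < ability, "correct",
                          np.where(rng.random(n) < guess_rate, "incorrect", "null"))
    return dict(zip(qids, (str(s) for s in states)))


def _draw_equipment(bank: ItemBank, probs: dict[str, float],
                    rng: np.random.Generator, deterministic: bool) -> frozenset[str]:
    picked: set[str] = set()
    for cat in CATEGORIES:
        items = bank.items_in_category(cat)
        p = probs[cat]
        if deterministic:
            picked.update(e.id for e in items[: int(round(p * len(items)))])
        else:
            mask = rng.random(len(items)) < p
            picked.update(e.id for e, m in zip(items, mask) if m)
    return frozenset(picked)


def _draw_times(median: float, cv: float, size: int, rng: np.random.Generator,
                deterministic: bool) -> np.ndarray:
    if deterministic or cv == 0.0:
        return np.full(size, median)
    return median * np.exp(rng.normal(0.0, cv, size=size))


def simulate_cohort(config: CohortConfig | None = None,
                    model: LearningModel | None = None,
                    bank: ItemBank | None = None) -> SimulatedStudy:
    """Generate a complete synthetic study, reproducible under the config seed.

    Produces the learner roster with stratified group allocation, three
    written-test response sheets per learner (minus simulated dropouts at
    follow-up), and four game-session logs per game-group learner with
    learning dynamics on scores, response times, equipment picks and
    ventilation/compression rhythm.  Study-frame scores are computed from
    the generated sheets with the package's own scoring functions.
    """
    config = config or CohortConfig()
    model = model or LearningModel()
    bank = bank or default_item_bank()
    rng = np.random.default_rng(config.seed)

    profiles = _draw_profiles(config, rng)
    alloc = design.stratified_assign(profiles, config.group_sizes,
                                     seed=int(rng.integers(2 ** 31)))
    # stratified_assign labels its first target group "dgbl"
    gain = _per_group(model.test_gain)
    loss = _per_group(model.retention_loss)
    loss_sd = _per_group(model.retention_sd)
    equip_probs = _default_equipment_probs()

    vent_interval = scoring.rate_to_interval(VENTILATION_RATE)
    comp_interval = scoring.rate_to_interval(COMPRESSION_RATE)
    vent_target = (vent_interval.min_timing + vent_interval.max_timing) / 2.0
    comp_target = (comp_interval.min_timing + comp_interval.max_timing) / 2.0

    sheets: list[ResponseSheet] = []
    logs: list[SessionLog] = []
    score_rows: dict[str, dict[str, float]] = {}
    truth_ability: dict[str, dict[str, float]] = {}

    for p in profiles:
        lid = p.learner_id
        grp = alloc.group[lid]
        stratum = alloc.stratum[lid]
        base = model.baseline_ability[stratum]
        if not model.deterministic:
            base = float(np.clip(rng.normal(base, model.ability_sd), 0.02, 0.95))
        a1 = base + gain[grp]
        a2 = a1 - loss[grp]
        if not model.deterministic:
            a1 += rng.normal(0.0, model.test_gain_sd)
            a2 = a1 - max(0.0, rng.normal(loss[grp], loss_sd[grp]))
        a1 = float(np.clip(a1, 0.02, 0.98))
        a2 = float(np.clip(a2, 0.02, 0.98))
        abilities = {"test0": base, "test1": a1, "test2": a2}
        truth_ability[lid] = abilities

        dropped = (not model.deterministic) and rng.random() < config.dropout_rate
        row: dict[str, float] = {}
        for tp in TIMEPOINTS:
            if tp == "test2" and dropped:
                continue
            answers = _draw_answers(bank, abilities[tp], model.guess_rate, rng,
                                    model.deterministic)
            eq_probs_tp = {cat: equip_probs[cat][tp][grp] for cat in CATEGORIES}
            picks = _draw_equipment(bank, eq_probs_tp, rng, model.deterministic)
            sheet = ResponseSheet(learner_id=lid, timepoint=tp,
                                  answers=answers, equipment_selected=picks)
            sheets.append(sheet)
            ks = scoring.score_knowledge(sheet, bank)
            es = scoring.score_equipment(picks, bank)
            row[f"knowledge_{tp}"] = ks.normalized
            row[f"equip_totally_correct_{tp}"] = es.frac_totally
            row[f"equip_partially_correct_{tp}"] = es.frac_partial
            row[f"equip_incorrect_{tp}"] = es.frac_incorrect
        score_rows[lid] = row

        if grp != "dgbl":
            continue
        # four game sessions with a learning curve
        for session in (1, 2, 3, 4):
            a_sess = model.session_ability(base, session)
            median_t = model.response_time_start * model.response_time_decay ** (session - 1)
            events = []
            for cat in sorted(SESSION_CATEGORIES[session]):
                nq = SESSION_QUESTION_COUNTS[cat]
                times = _draw_times(median_t, model.response_time_cv, nq, rng,
                                    model.deterministic)
                if model.deterministic:
                    n_correct = int(round(a_sess * nq))
                    outcomes = ["correct"] * n_correct + ["incorrect"] * (nq - n_correct)
                else:
                    u = rng.random(nq)
                    outcomes = np.where(
                        u < a_sess, "correct",
                        np.where(rng.random(nq) < model.get_help_rate,
                                 "get_help", "incorrect"))
                events.extend(
                    QuestionEvent(question_id=f"{cat[:4]}_{i + 1:02d}", category=cat,
                                  outcome=str(o), response_time=float(t))
                    for i, (o, t) in enumerate(zip(outcomes, times))
                )
            p_tot = min(1.0, model.session_equip_start
                        + model.session_equip_gain * (session - 1))
            picks = _draw_equipment(
                bank,
                {"totally_correct": p_tot,
                 "partially_correct": model.session_equip_wrong,
                 "incorrect": model.session_equip_wrong},
                rng, model.deterministic)
            vj, vo = model.ventilation_timing.at_session(session)
            if model.deterministic:
                vj = 0.0
            vent = simulate_act_series(vent_target, _GAME_DURATION_S, vj, vo, rng=rng,
                                       kind="ventilation", assistant_offset_per_min=0)
            comp = None
            if session in COMPRESSION_SESSIONS:
                cj, co = model.compression_timing.at_session(session)
                if model.deterministic:
                    cj = 0.0
                comp = simulate_act_series(comp_target, _GAME_DURATION_S, cj, co, rng=rng,
                                           kind="compression", assistant_offset_per_min=30)
            logs.append(SessionLog(
                learner_id=lid, session_number=session, question_events=tuple(events),
                equipment_selected=picks, ventilation_series=vent,
                compression_series=comp))

    scores = pd.DataFrame.from_dict(score_rows, orient="index").sort_index()
    frame = StudyFrame(profiles=profiles, stratum=alloc.stratum,
                       group=alloc.group, scores=scores)
    truth = {
        "ability": truth_ability,
        "gain_per_session": list(model.gain_per_session),
        "response_time_decay": model.response_time_decay,
        "ventilation_timing": {"jitter_sd": model.ventilation_timing.jitter_sd,
                               "offset": model.ventilation_timing.offset,
                               "target": vent_target},
        "compression_timing": {"jitter_sd": model.compression_timing.jitter_sd,
                               "offset": model.compression_timing.offset,
                               "target": comp_target},
    }
    return SimulatedStudy(frame=frame, sheets=sheets, logs=logs, bank=bank,
                          truth=truth, seed=config.seed)


# ---------------------------------------------------------------------------
# parameter recovery

def parameter_recovery_suite(model: LearningModel | None = None,
                             config: CohortConfig | None = None,
                             reps: int = 50, seed: int = 0) -> dict:
    """Estimate generator parameters back from simulated data.

    Per replicate the suite simulates a cohort and estimates, from the
    game-group session logs alone:

    * the per-session ability gains, as differences of the mean
      care/ventilation fraction-correct between consecutive sessions
      (unbiased: the expected fraction correct equals the latent ability);
    * the response-time decay, as the geometric mean of successive
      ratios of pooled median response times;
    * the session-1 ventilation timing offset, as the mean inter-act
      interval minus the target interval.

    Returns per-quantity true value, mean estimate, bias and RMSE.
    """
    if reps < 1:
        raise ValidationError("reps", "need reps >= 1")
    model = model or LearningModel()
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)

    names = [f"gain_session_{k}_{k + 1}" for k in (1, 2, 3)] + ["response_time_decay",
                                                                "ventilation_offset"]
    truths = list(model.gain_per_session) + [model.response_time_decay,
                                             model.ventilation_timing.offset]
    estimates = {name: [] for name in names}

    for _ in range(reps):
        cfg = CohortConfig(**{**config.__dict__, "seed": int(rng.integers(2 ** 31))})
        study = simulate_cohort(cfg, model)
        by_session: dict[int, list[float]] = {s: [] for s in (1, 2, 3, 4)}
        times: dict[int, list[float]] = {s: [] for s in (1, 2, 3, 4)}
        vent_offsets = []
        for log in study.logs:
            gs = scoring.score_game_session(log, study.bank)
            by_session[log.session_number].append(gs.fraction_correct["care_ppv"])
            times[log.session_number].extend(
                ev.response_time for ev in log.question_events)
            if log.session_number == 1 and log.ventilation_series.n >= 2:
                deltas = np.diff(log.ventilation_series.timestamps) * 100.0
                vent_offsets.append(
                    float(deltas.mean()) - study.truth["ventilation_timing"]["target"])
        means = {s: float(np.mean(v)) for s, v in by_session.items()}
        for k in (1, 2, 3):
            estimates[f"gain_session_{k}_{k + 1}"].append(means[k + 1] - means[k])
        med = {s: float(np.median(v)) for s, v in times.items()}
        estimates["response_time_decay"].append((med[4] / med[1]) ** (1.0 / 3.0))
        estimates["ventilation_offset"].append(float(np.mean(vent_offsets)))

    report = {}
    for name, true in zip(names, truths):
        est = np.asarray(estimates[name])
        report[name] = {
            "true": float(true),
            "mean_estimate": float(est.mean()),
            "bias": float(est.mean() - true),
            "rmse": float(np.sqrt(np.mean((est - true) ** 2))),
            "reps": reps,
        }
    return report
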