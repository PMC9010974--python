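"""Core domain types for serious-game resuscitation-training studies.

The study instruments are:

* a written knowledge test — a fixed bank of multiple-choice questions
  (one keyed answer each) administered before training (``test0``), one
  day after (``test1``) and at the 28-day follow-up (``test2``), with
  negative marking;
* an equipment checklist — a fixed list of resuscitation tools, each
  labelled *totally correct*, *partially correct* or *incorrect*, from
  which the learner selects within a time limit;
* in-game session logs — per-question outcomes and response times,
  equipment picks, and timestamped series of ventilation or chest
  compression acts.

All types validate their invariants on construction and raise
:class:`ValidationError` on violation; nothing is silently repaired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ValidationError",
    "CATEGORIES",
    "TIMEPOINTS",
    "QUESTION_CATEGORIES",
    "SESSION_CATEGORIES",
    "QuestionSpec",
    "EquipmentItem",
    "ItemBank",
    "ResponseSheet",
    "ActSeries",
    "RateSpec",
    "TimingInterval",
    "QuestionEvent",
    "SessionLog",
    "LearnerProfile",
    "StudyFrame",
]


class ValidationError(ValueError):
    """A domain invariant was violated; carries the offending field name."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


#: Equipment checklist categories.
CATEGORIES = ("totally_correct", "partially_correct", "incorrect")

#: Written-test administrations: pre-training, 1 day post, 28-day follow-up.
TIMEPOINTS = ("test0", "test1", "test2")

#: In-game question topic groups.
QUESTION_CATEGORIES = ("care_ppv", "intubation_compression", "drugs")

#: Which question categories each game session covers.  Care and assisted
#: ventilation run in every session; intubation/chest-compression content
#: only in sessions 1, 3 and 4; drug administration only in 1 and 4.
SESSION_CATEGORIES = {
    1: frozenset(QUESTION_CATEGORIES),
    2: frozenset({"care_ppv"}),
    3: frozenset({"care_ppv", "intubation_compression"}),
    4: frozenset(QUESTION_CATEGORIES),
}

#: Sessions whose interactive part reaches chest compressions.
COMPRESSION_SESSIONS = frozenset({1, 3, 4})


@dataclass(frozen=True)
class QuestionSpec:
    """One multiple-choice question: six options, exactly one keyed correct."""

    id: str
    options: tuple[str, ...]
    correct: str

    def __post_init__(self):
        if len(self.options) != len(set(self.options)):
            raise ValidationError("options", f"duplicate option ids in question {self.id!r}")
        if self.correct not in self.options:
            raise ValidationError(
                "correct", f"keyed answer {self.correct!r} not among options of {self.id!r}"
            )


@dataclass(frozen=True)
class EquipmentItem:
    id: str
    label: str
    category: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(
                "category", f"item {self.id!r} has unknown category {self.category!r}"
            )


@dataclass(frozen=True)
class ItemBank:
    """The fixed test structure: question bank plus equipment checklist.

    The default shipped bank has 21 questions (one keyed answer and five
    distractors each) and 40 equipment items split 21 totally correct /
    6 partially correct / 13 incorrect.
    """

    questions: tuple[QuestionSpec, ...]
    equipment_items: tuple[EquipmentItem, ...]

    def __post_init__(self):
        qids = [q.id for q in self.questions]
        if len(qids) != len(set(qids)):
            raise ValidationError("questions", "duplicate question ids")
        eids = [e.id for e in self.equipment_items]
        if len(eids) != len(set(eids)):
            raise ValidationError("equipment_items", "duplicate equipment item ids")

    @property
    def n_questions(self) -> int:
        return len(self.questions)

    @property
    def question_ids(self) -> tuple[str, ...]:
        return tuple(q.id for q in self.questions)

    @property
    def equipment_ids(self) -> frozenset[str]:
        return frozenset(e.id for e in self.equipment_items)

    def category_sizes(self) -> dict[str, int]:
        sizes = {c: 0 for c in CATEGORIES}
        for e in self.equipment_items:
            sizes[e.category] += 1
        return sizes

    def items_in_category(self, category: str) -> tuple[EquipmentItem, ...]:
        if category not in CATEGORIES:
            raise ValidationError("category", f"unknown category {category!r}")
        return tuple(e for e in self.equipment_items if e.category == category)


ANSWER_STATES = ("correct", "incorrect", "null")


@dataclass(frozen=True)
class ResponseSheet:
    """One learner's written test: per-question answer state + equipment picks."""

    learner_id: str
    timepoint: str
    answers: dict[str, str]  # question id -> correct | incorrect | null
    equipment_selected: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError("timepoint", f"unknown timepoint {self.timepoint!r}")
        for qid, state in self.answers.items():
            if state not in ANSWER_STATES:
                raise ValidationError("answers", f"{qid!r}: unknown answer state {state!r}")

    def check_against(self, bank: ItemBank) -> None:
        """Raise unless the sheet covers every bank question and selects only known items."""
        missing = set(bank.question_ids) - set(self.answers)
        if missing:
            raise ValidationError("answers", f"sheet misses questions {sorted(missing)}")
        extra = set(self.answers) - set(bank.question_ids)
        if extra:
            raise ValidationError("answers", f"sheet has unknown questions {sorted(extra)}")
        unknown = set(self.equipment_selected) - bank.equipment_ids
        if unknown:
            raise ValidationError(
                "equipment_selected", f"unknown equipment ids {sorted(unknown)}"
            )


@dataclass(frozen=True)
class ActSeries:
    """Ordered act timestamps (seconds from game start) for one game.

    ``assistant_offset_per_min`` is the act rate contributed by the virtual
    assistant interleaved with the learner's acts: 0 for the ventilation
    game, 30 for chest compressions (one assisted breath per three learner
    compressions).  The assistant's own acts are not in ``timestamps``;
    they only shift the effective target frequency.
    """

    kind: str  # "ventilation" | "compression"
    timestamps: tuple[float, ...]
    assistant_offset_per_min: int = 0

    def __post_init__(self):
        if self.kind not in ("ventilation", "compression"):
            raise ValidationError("kind", f"unknown act kind {self.kind!r}")
        ts = self.timestamps
        if any(t < 0 or not math.isfinite(t) for t in ts):
            raise ValidationError("timestamps", "timestamps must be finite and >= 0")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError("timestamps", "timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class RateSpec:
    """Allowed act-frequency band in acts/min, plus the assistant's share."""

    min_freq: float
    max_freq: float
    assistant_offset_per_min: int = 0

    def __post_init__(self):
        if not (0 < self.min_freq < self.max_freq):
            raise ValidationError("min_freq", "need 0 < min_freq < max_freq")


@dataclass(frozen=True)
class TimingInterval:
    """Allowed inter-act interval, in integer hundredths of a second."""

    min_timing: int
    max_timing: int

    def __post_init__(self):
        if not (0 < self.min_timing < self.max_timing):
            raise ValidationError("min_timing", "need 0 < min_timing < max_timing")

    def contains(self, delta: float) -> bool:
        # closed interval: acts exactly on an endpoint are in range
        return self.min_timing <= delta <= self.max_timing


@dataclass(frozen=True)
class QuestionEvent:
    question_id: str
    category: str
    outcome: str  # correct | incorrect | get_help
    response_time: float  # seconds

    def __post_init__(self):
        if self.category not in QUESTION_CATEGORIES:
            raise ValidationError("category", f"unknown question category {self.category!r}")
        if self.outcome not in ("correct", "incorrect", "get_help"):
            raise ValidationError("outcome", f"unknown outcome {self.outcome!r}")
        if not self.response_time > 0:
            raise ValidationError("response_time", "response time must be > 0")


@dataclass(frozen=True)
class SessionLog:
    """One learner x one game session.

    Category coverage must respect the session structure (see
    :data:`SESSION_CATEGORIES`) and the compression game only exists in
    sessions whose interactive part reaches chest compressions.
    """

    learner_id: str
    session_number: int
    question_events: tuple[QuestionEvent, ...]
    equipment_selected: frozenset[str] = frozenset()
    ventilation_series: ActSeries | None = None
    compression_series: ActSeries | None = None

    def __post_init__(self):
        if self.session_number not in SESSION_CATEGORIES:
            raise ValidationError("session_number", f"invalid session {self.session_number!r}")
        allowed = SESSION_CATEGORIES[self.session_number]
        bad = {ev.category for ev in self.question_events} - allowed
        if bad:
            raise ValidationError(
                "question_events",
                f"categories {sorted(bad)} not part of session {self.session_number}",
            )
        if self.compression_series is not None and self.session_number not in COMPRESSION_SESSIONS:
            raise ValidationError(
                "compression_series",
                f"session {self.session_number} has no chest-compression game",
            )

    def events_in_category(self, category: str) -> tuple[QuestionEvent, ...]:
        return tuple(ev for ev in self.question_events if ev.category == category)


@dataclass(frozen=True)
class LearnerProfile:
    """Prior-experience record used for competence stratification."""

    learner_id: str
    specialty_year: int
    has_simulation: bool
    has_theory: bool
    has_clinical: bool

    def __post_init__(self):
        if self.specialty_year not in range(1, 6):
            raise ValidationError("specialty_year", "specialty year must be in 1..5")


GROUPS = ("dgbl", "classic")

KNOWLEDGE_COLUMNS = tuple(f"knowledge_{tp}" for tp in TIMEPOINTS)
EQUIPMENT_COLUMNS = tuple(
    f"equip_{cat}_{tp}" for cat in CATEGORIES for tp in TIMEPOINTS
)
SCORE_COLUMNS = KNOWLEDGE_COLUMNS + EQUIPMENT_COLUMNS


@dataclass
class StudyFrame:
    """Roster of learners with strata, group allocation and test scores.

    ``scores`` is indexed by learner id with one column per measure and
    timepoint (``knowledge_test0`` ... ``equip_incorrect_test2``).
    Knowledge scores are normalized fractions in [-0.2, 1]; equipment
    scores are per-category selected fractions in [0, 1].  ``NaN`` marks
    a missing timepoint (dropout); missingness is represented, never
    imputed, and learners with a missing timepoint are excluded from
    paired analyses downstream.
    """

    profiles: list[LearnerProfile]
    stratum: dict[str, int]
    group: dict[str, str]
    scores: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        ids = [p.learner_id for p in self.profiles]
        if len(ids) != len(set(ids)):
            raise ValidationError("profiles", "duplicate learner ids")
        for lid in ids:
            if lid not in self.stratum:
                raise ValidationError("stratum", f"learner {lid!r} has no stratum")
            if self.stratum[lid] not in (0, 1, 2, 3):
                raise ValidationError("stratum", f"learner {lid!r}: stratum outside 0..3")
            if lid not in self.group:
                raise ValidationError("group", f"learner {lid!r} has no group")
            if self.group[lid] not in GROUPS:
                raise ValidationError("group", f"learner {lid!r}: unknown group")
        if len(self.scores):
            for col in self.scores.columns:
                if col not in SCORE_COLUMNS:
                    raise ValidationError("scores", f"unknown score column {col!r}")
                vals = self.scores[col].dropna()
                lo = -0.2 if col.startswith("knowledge") else 0.0
                if ((vals < lo - 1e-12) | (vals > 1 + 1e-12)).any():
                    raise ValidationError("scores", f"column {col!r} outside [{lo}, 1]")

    @property
    def learner_ids(self) -> list[str]:
        return [p.learner_id for p in self.profiles]

    def ids_in_group(self, group: str) -> list[str]:
        return [lid for lid in self.learner_ids if self.group[lid] == group]

    def complete_cases(self, columns: list[str]) -> pd.DataFrame:
        """Scores restricted to learners with no missing value in ``columns``."""
        sub = self.scores[list(columns)]
        return sub.dropna()
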