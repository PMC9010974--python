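"""Readers and writers for item banks, event logs, rosters and report bundles.

No raw-log format is standardized for this kind of study, so the CSV
contracts here are this package's own.  All files are plain text:

* item bank — YAML (or JSON, a YAML subset) mirroring :class:`ItemBank`,
  with a ``declared`` section of expected counts that is verified at read
  time;
* session event log — one row per atomic event with a ``kind``
  discriminator column (``question`` / ``equipment`` / ``act``);
* response sheets — one row per answer or equipment pick, with a ``kind``
  discriminator (``answer`` / ``equipment``);
* roster — one row per learner (profile, stratum, group), scores in a
  separate wide CSV indexed by learner id;
* report bundle — a directory of CSV tables plus one JSON manifest.

Readers enforce every domain invariant and reject malformed input with a
:class:`~resuslearn.types.ValidationError` naming the offending field and,
for tabular input, the offending row numbers.  Nothing is repaired.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .types import (
    ActSeries,
    EquipmentItem,
    ItemBank,
    LearnerProfile,
    QuestionEvent,
    QuestionSpec,
    ResponseSheet,
    SessionLog,
    StudyFrame,
    SCORE_COLUMNS,
    ValidationError,
)

__all__ = [
    "read_item_bank",
    "default_item_bank",
    "read_session_logs",
    "write_session_logs",
    "read_response_sheets",
    "write_response_sheets",
    "read_study_frame",
    "write_study_frame",
    "write_report",
    "read_report_manifest",
]

# deterministic float formatting for byte-identical reruns
_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# item bank

def read_item_bank(path: str | Path) -> ItemBank:
    """Load and validate an item bank from YAML/JSON.

    The file's ``declared`` totals (question count, per-category equipment
    counts) are cross-checked against the actual lists; a mismatch is a
    validation error, never silently accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValidationError("bank", f"{path}: not a mapping (empty or malformed file)")
    return _bank_from_dict(raw)


def _bank_from_dict(raw: dict) -> ItemBank:
    questions = []
    for q in raw.get("questions", []):
        opts = q.get("options", [])
        keyed = [o["id"] for o in opts if o.get("correct")]
        if len(keyed) != 1:
            raise ValidationError(
                "questions", f"question {q.get('id')!r} has {len(keyed)} keyed answers, expected 1"
            )
        if len(opts) != 6:
            raise ValidationError(
                "questions", f"question {q.get('id')!r} has {len(opts)} options, expected 6"
            )
        questions.append(
            QuestionSpec(id=q["id"], options=tuple(o["id"] for o in opts), correct=keyed[0])
        )
    equipment = [
        EquipmentItem(id=e["id"], label=e.get("label", e["id"]), category=e["category"])
        for e in raw.get("equipment", [])
    ]
    bank = ItemBank(questions=tuple(questions), equipment_items=tuple(equipment))

    declared = raw.get("declared", {})
    if "n_questions" in declared and declared["n_questions"] != bank.n_questions:
        raise ValidationError(
            "declared.n_questions",
            f"declared {declared['n_questions']} questions, found {bank.n_questions}",
        )
    if "equipment_totals" in declared:
        sizes = bank.category_sizes()
        for cat, n in declared["equipment_totals"].items():
            if sizes.get(cat) != n:
                raise ValidationError(
                    "declared.equipment_totals",
                    f"category {cat!r}: declared {n}, found {sizes.get(cat)}",
                )
    return bank


def default_item_bank() -> ItemBank:
    """The shipped default bank: 21 questions; 40 items (21/6/13 by category)."""
    ref = resources.files("resuslearn").joinpath("data/default_bank.yaml")
    raw = yaml.safe_load(ref.read_text())
    return _bank_from_dict(raw)


# ---------------------------------------------------------------------------
# session event logs

_SESSION_COLUMNS = [
    "learner_id", "session_number", "kind", "question_id", "category",
    "outcome", "response_time", "item_id", "act_kind", "timestamp",
    "assistant_offset_per_min",
]


def write_session_logs(logs: list[SessionLog], path: str | Path) -> None:
    rows = []
    for log in logs:
        base = {"learner_id": log.learner_id, "session_number": log.session_number}
        for ev in log.question_events:
            rows.append(base | {
                "kind": "question", "question_id": ev.question_id,
                "category": ev.category, "outcome": ev.outcome,
                "response_time": ev.response_time,
            })
        for item in sorted(log.equipment_selected):
            rows.append(base | {"kind": "equipment", "item_id": item})
        for series in (log.ventilation_series, log.compression_series):
            if series is None:
                continue
            for t in series.timestamps:
                rows.append(base | {
                    "kind": "act", "act_kind": series.kind, "timestamp": t,
                    "assistant_offset_per_min": series.assistant_offset_per_min,
                })
    # full float precision so write -> read is the identity
    pd.DataFrame(rows, columns=_SESSION_COLUMNS).to_csv(path, index=False)


def read_session_logs(path: str | Path) -> list[SessionLog]:
    """Parse an event-log CSV into per-(learner, session) logs.

    Raises a validation error listing the offending rows for out-of-order
    act timestamps or question categories not part of a session.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # keep_default_na=False: literal strings like "null" are data, not NaN
    df = pd.read_csv(path, keep_default_na=False)
    if df.empty:
        return []
    missing = set(_SESSION_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValidationError("columns", f"event log misses columns {sorted(missing)}")
    for col in _SESSION_COLUMNS:
        if col not in df.columns:
            df[col] = ""

    logs: list[SessionLog] = []
    # row numbers are 1-based data rows (header = row 0), for error messages
    df = df.reset_index(names="_row")
    df["_row"] += 1
    for (lid, sess), grp in df.groupby(["learner_id", "session_number"], sort=True):
        events = []
        for _, r in grp[grp["kind"] == "question"].iterrows():
            try:
                events.append(QuestionEvent(
                    question_id=str(r["question_id"]), category=str(r["category"]),
                    outcome=str(r["outcome"]), response_time=float(r["response_time"]),
                ))
            except ValidationError as err:
                raise ValidationError(err.field_name, f"row {r['_row']}: {err}") from err
        items = frozenset(str(i) for i in grp.loc[grp["kind"] == "equipment", "item_id"])
        series: dict[str, ActSeries] = {}
        acts = grp[grp["kind"] == "act"]
        for act_kind, agrp in acts.groupby("act_kind"):
            # astype(float) round-trips shortest-repr floats exactly
            ts = agrp["timestamp"].astype(float).to_numpy()
            if (ts[1:] <= ts[:-1]).any():
                bad = agrp["_row"].to_numpy()[1:][ts[1:] <= ts[:-1]]
                raise ValidationError(
                    "timestamp",
                    f"out-of-order act timestamps for learner {lid!r} session {sess}"
                    f" at rows {bad.tolist()}",
                )
            off_raw = agrp["assistant_offset_per_min"].iloc[0]
            off = int(float(off_raw)) if str(off_raw) != "" else 0
            series[str(act_kind)] = ActSeries(
                kind=str(act_kind), timestamps=tuple(ts), assistant_offset_per_min=off
            )
        try:
            logs.append(SessionLog(
                learner_id=str(lid), session_number=int(sess),
                question_events=tuple(events), equipment_selected=items,
                ventilation_series=series.get("ventilation"),
                compression_series=series.get("compression"),
            ))
        except ValidationError as err:
            rows = grp["_row"].tolist()
            raise ValidationError(
                err.field_name, f"rows {rows[0]}..{rows[-1]}: {err}"
            ) from err
    return logs


# ---------------------------------------------------------------------------
# response sheets

_SHEET_COLUMNS = ["learner_id", "timepoint", "kind", "question_id", "answer", "item_id"]


def write_response_sheets(sheets: list[ResponseSheet], path: str | Path) -> None:
    rows = []
    for sh in sheets:
        base = {"learner_id": sh.learner_id, "timepoint": sh.timepoint}
        for qid in sorted(sh.answers):
            rows.append(base | {"kind": "answer", "question_id": qid, "answer": sh.answers[qid]})
        for item in sorted(sh.equipment_selected):
            rows.append(base | {"kind": "equipment", "item_id": item})
    pd.DataFrame(rows, columns=_SHEET_COLUMNS).to_csv(path, index=False)


def read_response_sheets(path: str | Path) -> list[ResponseSheet]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, keep_default_na=False)
    if df.empty:
        return []
    for col in _SHEET_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    sheets = []
    for (lid, tp), grp in df.groupby(["learner_id", "timepoint"], sort=True):
        answers = {
            str(r["question_id"]): str(r["answer"])
            for _, r in grp[grp["kind"] == "answer"].iterrows()
        }
        items = frozenset(str(i) for i in grp.loc[grp["kind"] == "equipment", "item_id"])
        sheets.append(ResponseSheet(
            learner_id=str(lid), timepoint=str(tp), answers=answers, equipment_selected=items
        ))
    return sheets


# ---------------------------------------------------------------------------
# study frame (roster + scores)

_ROSTER_COLUMNS = [
    "learner_id", "specialty_year", "has_simulation", "has_theory",
    "has_clinical", "stratum", "group",
]


def write_study_frame(frame: StudyFrame, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "learner_id": p.learner_id, "specialty_year": p.specialty_year,
            "has_simulation": p.has_simulation, "has_theory": p.has_theory,
            "has_clinical": p.has_clinical, "stratum": frame.stratum[p.learner_id],
            "group": frame.group[p.learner_id],
        }
        for p in frame.profiles
    ]
    pd.DataFrame(rows, columns=_ROSTER_COLUMNS).to_csv(directory / "roster.csv", index=False)
    scores = frame.scores.copy()
    scores.index.name = "learner_id"
    # full precision: reading the dataset back must reproduce the analysis exactly
    scores.to_csv(directory / "scores.csv")


def read_study_frame(directory: str | Path) -> StudyFrame:
    directory = Path(directory)
    roster = pd.read_csv(directory / "roster.csv")
    profiles, stratum, group = [], {}, {}
    for _, r in roster.iterrows():
        p = LearnerProfile(
            learner_id=str(r["learner_id"]), specialty_year=int(r["specialty_year"]),
            has_simulation=bool(r["has_simulation"]), has_theory=bool(r["has_theory"]),
            has_clinical=bool(r["has_clinical"]),
        )
        profiles.append(p)
        stratum[p.learner_id] = int(r["stratum"])
        group[p.learner_id] = str(r["group"])
    scores_path = directory / "scores.csv"
    if scores_path.exists():
        scores = pd.read_csv(scores_path, index_col="learner_id",
                             float_precision="round_trip")
        scores.index = scores.index.astype(str)
        scores = scores[[c for c in SCORE_COLUMNS if c in scores.columns]]
    else:
        scores = pd.DataFrame(index=[p.learner_id for p in profiles])
    return StudyFrame(profiles=profiles, stratum=stratum, group=group, scores=scores)


# ---------------------------------------------------------------------------
# report bundle

def write_report(tables: dict[str, pd.DataFrame], summary: dict, directory: str | Path) -> None:
    """Write a report bundle: one CSV per table plus ``manifest.json``.

    Output is deterministic: fixed column order as provided, stable float
    formatting, sorted JSON keys.  Rerunning on identical inputs produces
    byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tables": {}, "summary": summary}
    for name in sorted(tables):
        df = tables[name]
        fname = f"{name}.csv"
        df.to_csv(directory / fname, index=False, float_format=_FLOAT_FMT)
        manifest["tables"][name] = {"file": fname, "n_rows": int(len(df))}
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def _json_default(obj):
    try:
        import numpy as np
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_report_manifest(directory: str | Path) -> dict:
    return json.loads((Path(directory) / "manifest.json").read_text())
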