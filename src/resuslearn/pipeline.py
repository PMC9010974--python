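"""End-to-end study analysis: from a validated dataset to a report bundle.

The pipeline runs, in order:

1. baseline equality of the two groups on the pre-training test
   (two-sided unpaired comparison plus a two-sample KS distance);
2. the Monte-Carlo design check of the stratified allocation;
3. per-group knowledge retention: Friedman gate over the three test
   administrations, then Bonferroni-corrected paired post-hocs
   (improvement pre -> post, decay post -> follow-up) and paired
   variance analyses (Pitman-Morgan), plus an F-test comparing the two
   groups' variances at follow-up;
4. the between-group difference of post-minus-pre score deltas
   (one-sided unpaired, the non-inferiority-style comparison);
5. the same retention battery per equipment category;
6. game-session learning curves (per question category: score fraction
   and median response time, with one-sided monotonicity post-hocs);
7. rhythm-game timing summaries (deviation mean/std per session for
   ventilation and compression, with monotonicity post-hocs);
8. pooled per-item selection counts across the three written tests.

Learners missing any timepoint of a paired analysis are excluded from
that analysis (complete cases) and logged; baseline checks use all
available learners.  Every statistical entry in the bundle records the
test name, sidedness, sample size, alpha and Bonferroni factor.  A
closed Friedman gate suppresses the corresponding post-hocs and is
reported as a status, never as a p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import design, scoring, stats
from .io import (
    default_item_bank,
    read_response_sheets,
    read_session_logs,
    read_study_frame,
    write_report,
)
from .types import (
    CATEGORIES,
    ItemBank,
    QUESTION_CATEGORIES,
    ResponseSheet,
    SESSION_CATEGORIES,
    SessionLog,
    StudyFrame,
    TIMEPOINTS,
    ValidationError,
)

__all__ = ["PipelineConfig", "ReportBundle", "run_study", "item_choice_counts",
           "load_dataset", "StudyData"]

GROUP_LABELS = ("dgbl", "classic")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis configuration: sidedness and Bonferroni factors per family.

    Defaults are the study-faithful settings: one-sided improvement
    post-hocs with m = 2 for the written-test retention families, m = 5
    for the care/ventilation session curves and the session equipment
    scores, m = 3 for the intubation/compression curves.
    """

    alpha: float = 0.05
    bonferroni: dict = field(default_factory=lambda: {
        "retention": 2, "equipment": 2,
        "care_ppv": 5, "intubation_compression": 3, "drugs": 1,
        "session_equipment": 5,
    })
    posthoc_pairs: tuple[tuple[int, int], ...] = ((0, 1), (1, 2))
    design_reps: int = 100_000
    design_seed: int = 0
    force_posthoc: bool = False

    def m_for(self, family: str) -> int:
        return int(self.bonferroni.get(family, 1))


@dataclass
class StudyData:
    """An in-memory dataset: roster+scores, written sheets, session logs."""

    frame: StudyFrame
    sheets: list[ResponseSheet]
    logs: list[SessionLog]
    bank: ItemBank


def load_dataset(directory: str | Path, bank: ItemBank | None = None) -> StudyData:
    """Load and validate a dataset directory written by the simulator/CLI."""
    directory = Path(directory)
    bank = bank or default_item_bank()
    frame = read_study_frame(directory)
    sheets = read_response_sheets(directory / "sheets.csv") \
        if (directory / "sheets.csv").exists() else []
    logs = read_session_logs(directory / "sessions.csv") \
        if (directory / "sessions.csv").exists() else []
    for sh in sheets:
        sh.check_against(bank)
    return StudyData(frame=frame, sheets=sheets, logs=logs, bank=bank)


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    summary: dict

    def write(self, directory: str | Path) -> None:
        write_report(self.tables, self.summary, directory)


def _result_row(res: stats.TestResult, **labels) -> dict:
    d = res.to_dict()
    extra = d.pop("extra", {})
    d["n"] = str(d["n"])
    row = labels | d
    row["status"] = "ok"
    if "method" in extra:
        row["method"] = extra["method"]
    return row


def _closed_row(family: str, gate: stats.TestResult, **labels) -> dict:
    return labels | {"status": "gate_closed",
                     "test_name": "", "p_value": np.nan,
                     "gate_p": gate.p_value}


# ---------------------------------------------------------------------------
# component analyses

def item_choice_counts(sheets: list[ResponseSheet], bank: ItemBank) -> pd.DataFrame:
    """Pooled selection counts per equipment item and timepoint.

    Counts are pooled over both groups, labeled by category; an all-zero
    row flags a poor distractor that learners never selected.
    """
    counts = {e.id: {tp: 0 for tp in TIMEPOINTS} for e in bank.equipment_items}
    for sh in sheets:
        for item in sh.equipment_selected:
            counts[item][sh.timepoint] += 1
    rows = [
        {"item_id": e.id, "label": e.label, "category": e.category}
        | {tp: counts[e.id][tp] for tp in TIMEPOINTS}
        for e in bank.equipment_items
    ]
    return pd.DataFrame(rows)


def _retention_battery(scores: pd.DataFrame, columns: list[str], family: str,
                       config: PipelineConfig, group: str,
                       measure: str) -> tuple[list[dict], dict]:
    """Friedman gate + paired post-hocs + paired variance tests for one measure."""
    rows: list[dict] = []
    complete = scores[columns].dropna()
    excluded = sorted(set(scores.index) - set(complete.index))
    labels = {"group": group, "measure": measure}
    if len(complete) < 3:
        rows.append(labels | {"status": "insufficient_n", "test_name": "",
                              "p_value": np.nan})
        return rows, {"excluded": excluded, "gate_open": False}
    mat = complete.to_numpy()
    gate = stats.friedman_gate(mat, alpha=config.alpha)
    rows.append(_result_row(gate, **labels, comparison="friedman_gate"))
    m = config.m_for(family)
    gate_open = gate.extra["gate_open"]
    if gate_open or config.force_posthoc:
        # improvement pre->post tested one-sided (post greater), decay
        # post->follow-up two-sided
        alts = {(0, 1): "less", (1, 2): "two_sided"}
        posthocs = stats.posthoc_pairwise(
            mat, gate, pairs=config.posthoc_pairs, m=m,
            alternatives={p: alts.get(p, "two_sided") for p in config.posthoc_pairs},
            alpha=config.alpha, force=config.force_posthoc)
        for res in posthocs:
            i, j = res.extra["pair"]
            rows.append(_result_row(
                res, **labels, comparison=f"{columns[i]}_vs_{columns[j]}"))
    else:
        for (i, j) in config.posthoc_pairs:
            rows.append(_closed_row(family, gate, **labels,
                                    comparison=f"{columns[i]}_vs_{columns[j]}"))
    # paired variance analyses run regardless of the rank gate: variance
    # homogenization is a separate question from location shifts
    for (i, j), alt in (((0, 1), "greater"), ((1, 2), "less")):
        try:
            res = stats.pitman_morgan(mat[:, i], mat[:, j], alternative=alt,
                                      alpha=config.alpha)
            rows.append(_result_row(
                res, **labels, comparison=f"variance_{columns[i]}_vs_{columns[j]}"))
        except ValidationError as err:
            rows.append(labels | {"status": f"undefined ({err})", "test_name":
                                  "pitman_morgan", "p_value": np.nan,
                                  "comparison": f"variance_{columns[i]}_vs_{columns[j]}"})
    return rows, {"excluded": excluded, "gate_open": bool(gate_open)}


def _baseline_comparison(frame: StudyFrame, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    a = frame.scores.loc[frame.scores.index.isin(frame.ids_in_group("dgbl"))]
    b = frame.scores.loc[frame.scores.index.isin(frame.ids_in_group("classic"))]
    for measure, col in [("knowledge", "knowledge_test0"),
                         ("equip_totally_correct", "equip_totally_correct_test0")]:
        if col not in frame.scores.columns:
            continue
        x = a[col].dropna().to_numpy()
        y = b[col].dropna().to_numpy()
        plan = stats.build_plan(x, y, paired=False, alpha=config.alpha)
        res = stats.group_compare(x, y, plan=plan, alternative="two_sided",
                                  alpha=config.alpha)
        rows.append(_result_row(res, measure=measure, comparison="test0_location",
                                chosen=plan.chosen_test))
        rows.append({"measure": measure, "comparison": "test0_ks_distance",
                     "test_name": "ks_distance",
                     "statistic": design.ks_distance(x, y),
                     "p_value": np.nan, "status": "ok"})
    return pd.DataFrame(rows)


def _group_difference(frame: StudyFrame, config: PipelineConfig,
                      col_pre: str, col_post: str, measure: str) -> dict:
    """One-sided unpaired comparison of post-minus-pre deltas (dgbl vs classic)."""
    deltas = {}
    for g in GROUP_LABELS:
        sub = frame.scores.loc[frame.scores.index.isin(frame.ids_in_group(g)),
                               [col_pre, col_post]].dropna()
        deltas[g] = (sub[col_post] - sub[col_pre]).to_numpy()
    res = stats.group_compare(deltas["dgbl"], deltas["classic"],
                              alternative="greater", alpha=config.alpha)
    return _result_row(res, measure=measure,
                       comparison="delta_post_pre_dgbl_vs_classic")


def _session_learning(logs: list[SessionLog], bank: ItemBank,
                      config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-session score/time medians and monotonicity post-hocs per category."""
    per_learner: dict[str, dict[int, scoring.GameSessionScore]] = {}
    for log in logs:
        per_learner.setdefault(log.learner_id, {})[log.session_number] = \
            scoring.score_game_session(log, bank)

    curve_rows = []
    test_rows = []
    for cat in QUESTION_CATEGORIES:
        sessions = sorted(s for s, cats in SESSION_CATEGORIES.items() if cat in cats)
        ids = [lid for lid, by_s in per_learner.items()
               if all(s in by_s for s in sessions)]
        if not ids:
            continue
        frac = np.array([[per_learner[lid][s].fraction_correct[cat] for s in sessions]
                         for lid in ids])
        rt = np.array([[per_learner[lid][s].median_response_time[cat] for s in sessions]
                       for lid in ids])
        for k, s in enumerate(sessions):
            curve_rows.append({
                "category": cat, "session": s, "n": len(ids),
                "median_fraction_correct": float(np.median(frac[:, k])),
                "median_response_time_s": float(np.median(rt[:, k])),
            })
        pairs = tuple((k, k + 1) for k in range(len(sessions) - 1))
        m = config.m_for(cat)
        for name, mat, alt in (("score", frac, "less"), ("response_time", rt, "greater")):
            gate = stats.friedman_gate(mat, alpha=config.alpha)
            test_rows.append(_result_row(gate, category=cat, measure=name,
                                         comparison="friedman_gate"))
            if gate.extra["gate_open"] or config.force_posthoc:
                for res in stats.posthoc_pairwise(mat, gate, pairs=pairs, m=m,
                                                  alternatives=alt, alpha=config.alpha,
                                                  force=config.force_posthoc):
                    i, j = res.extra["pair"]
                    test_rows.append(_result_row(
                        res, category=cat, measure=name,
                        comparison=f"session_{sessions[i]}_vs_{sessions[j]}"))
            else:
                for (i, j) in pairs:
                    test_rows.append(_closed_row(
                        cat, gate, category=cat, measure=name,
                        comparison=f"session_{sessions[i]}_vs_{sessions[j]}"))
    return pd.DataFrame(curve_rows), pd.DataFrame(test_rows)


def _timing_table(logs: list[SessionLog], config: PipelineConfig) -> tuple[pd.DataFrame,
                                                                           pd.DataFrame]:
    from .simulate import VENTILATION_RATE, COMPRESSION_RATE  # rate constants

    intervals = {"ventilation": scoring.rate_to_interval(VENTILATION_RATE),
                 "compression": scoring.rate_to_interval(COMPRESSION_RATE)}
    per: dict[str, dict[str, dict[int, scoring.TimingScore]]] = {
        "ventilation": {}, "compression": {}}
    for log in logs:
        for kind in ("ventilation", "compression"):
            series = getattr(log, f"{kind}_series")
            if series is None or series.n < 2:
                continue
            ts = scoring.act_deviations(series, intervals[kind])
            per[kind].setdefault(log.learner_id, {})[log.session_number] = ts

    summary_rows = []
    test_rows = []
    for kind, by_learner in per.items():
        sessions = sorted({s for d in by_learner.values() for s in d})
        if not sessions:
            continue
        ids = [lid for lid, d in by_learner.items() if all(s in d for s in sessions)]
        means = np.array([[by_learner[lid][s].score_mean for s in sessions]
                          for lid in ids])
        stds = np.array([[by_learner[lid][s].score_std for s in sessions]
                         for lid in ids])
        for k, s in enumerate(sessions):
            summary_rows.append({
                "kind": kind, "session": s, "n": len(ids),
                "median_score_mean": float(np.median(means[:, k])),
                "median_score_std": float(np.median(stds[:, k])),
            })
        pairs = tuple((k, k + 1) for k in range(len(sessions) - 1))
        for name, mat in (("score_mean", means), ("score_std", stds)):
            gate = stats.friedman_gate(mat, alpha=config.alpha)
            test_rows.append(_result_row(gate, kind=kind, measure=name,
                                         comparison="friedman_gate"))
            if gate.extra["gate_open"] or config.force_posthoc:
                for res in stats.posthoc_pairwise(
                        mat, gate, pairs=pairs, m=len(pairs),
                        alternatives="greater", alpha=config.alpha,
                        force=config.force_posthoc):
                    i, j = res.extra["pair"]
                    test_rows.append(_result_row(
                        res, kind=kind, measure=name,
                        comparison=f"session_{sessions[i]}_vs_{sessions[j]}"))
            else:
                for (i, j) in pairs:
                    test_rows.append(_closed_row(
                        kind, gate, kind=kind, measure=name,
                        comparison=f"session_{sessions[i]}_vs_{sessions[j]}"))
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)


# ---------------------------------------------------------------------------
# orchestration

def run_study(data: StudyData, config: PipelineConfig | None = None) -> ReportBundle:
    """Execute the full analysis and assemble the report bundle.

    Deterministic: identical data and config produce an identical bundle
    (the Monte-Carlo design check uses ``config.design_seed``).
    """
    config = config or PipelineConfig()
    frame = data.frame
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"n_learners": len(frame.profiles),
                     "group_sizes": {g: len(frame.ids_in_group(g)) for g in GROUP_LABELS},
                     "alpha": config.alpha,
                     "bonferroni": dict(config.bonferroni),
                     "design_seed": config.design_seed,
                     "exclusions": {}}

    tables["baseline_comparison"] = _baseline_comparison(frame, config)

    # Monte-Carlo design check on pre-training knowledge scores
    if "knowledge_test0" in frame.scores.columns:
        t0 = frame.scores["knowledge_test0"].dropna()
        a = t0[t0.index.isin(frame.ids_in_group("dgbl"))].to_numpy()
        b = t0[t0.index.isin(frame.ids_in_group("classic"))].to_numpy()
        observed = design.ks_distance(a, b)
        check = design.monte_carlo_design_check(
            t0.to_numpy(), (a.size, b.size), observed,
            reps=config.design_reps, seed=config.design_seed)
        tables["design_check"] = pd.DataFrame([{
            "observed_D": check.observed_D, "reps": check.reps,
            "n_better": check.n_better, "prop_better": check.prop_better,
            "seed": check.seed, "n_dgbl": a.size, "n_classic": b.size,
        }])
        summary["design_check"] = {"observed_D": check.observed_D,
                                   "prop_better": check.prop_better}

    # knowledge + equipment retention batteries, per group
    retention_rows: list[dict] = []
    gates: dict[str, bool] = {}
    measures = [("knowledge", "retention")] + [
        (f"equip_{cat}", "equipment") for cat in CATEGORIES]
    for group in GROUP_LABELS:
        ids = frame.ids_in_group(group)
        sub = frame.scores.loc[frame.scores.index.isin(ids)]
        for measure, family in measures:
            cols = [f"{measure}_{tp}" for tp in TIMEPOINTS]
            if not all(c in sub.columns for c in cols):
                continue
            rows, meta = _retention_battery(sub, cols, family, config, group, measure)
            retention_rows.extend(rows)
            gates[f"{group}:{measure}"] = meta["gate_open"]
            if meta["excluded"]:
                summary["exclusions"][f"{group}:{measure}"] = meta["excluded"]
    tables["knowledge_retention"] = pd.DataFrame(
        [r for r in retention_rows if r["measure"] == "knowledge"])
    tables["equipment_category"] = pd.DataFrame(
        [r for r in retention_rows if r["measure"] != "knowledge"])
    summary["gates_open"] = gates

    # between-group F-test of follow-up variances and delta comparison
    extra_rows = []
    if "knowledge_test2" in frame.scores.columns:
        x = frame.scores.loc[frame.scores.index.isin(frame.ids_in_group("classic")),
                             "knowledge_test2"].dropna().to_numpy()
        y = frame.scores.loc[frame.scores.index.isin(frame.ids_in_group("dgbl")),
                             "knowledge_test2"].dropna().to_numpy()
        try:
            _, res = stats.variance_check(x, y, paired=False, alpha=config.alpha,
                                          alternative="greater")
            extra_rows.append(_result_row(
                res, measure="knowledge",
                comparison="variance_test2_classic_vs_dgbl"))
        except ValidationError as err:
            extra_rows.append({"measure": "knowledge", "test_name": "f_test",
                               "comparison": "variance_test2_classic_vs_dgbl",
                               "p_value": np.nan, "status": f"undefined ({err})"})
        extra_rows.append(_group_difference(frame, config, "knowledge_test0",
                                            "knowledge_test1", "knowledge"))
    if "equip_totally_correct_test1" in frame.scores.columns:
        extra_rows.append(_group_difference(
            frame, config, "equip_totally_correct_test0",
            "equip_totally_correct_test1", "equip_totally_correct"))
    tables["group_difference"] = pd.DataFrame(extra_rows)

    # game-session analyses (game-group logs)
    if data.logs:
        curves, session_tests = _session_learning(data.logs, data.bank, config)
        tables["session_learning"] = curves
        tables["session_learning_tests"] = session_tests
        timing, timing_tests = _timing_table(data.logs, config)
        tables["timing"] = timing
        tables["timing_tests"] = timing_tests

    if data.sheets:
        tables["item_choice_counts"] = item_choice_counts(data.sheets, data.bank)

    return ReportBundle(tables=tables, summary=summary)
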