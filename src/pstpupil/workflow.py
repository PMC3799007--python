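"""End-to-end orchestration: generate -> train -> measure -> normalize -> test.

``run_study`` simulates the whole study from a single master seed and
produces the study-shaped outputs: a per-subject condition summary
(pupil percent change from Task 2, percent correct, mean RT, per
group x time x task), group-level summary tables, the mixed
repeated-measures ANOVA battery, post-hoc tests, and the per-training-day
Task 4 - Task 2 pupil trend from the first block of each day.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .pipeline import AnalysisConfig, analyze_session
from .stats import (cousineau_morey, difference_score, mixed_rm_anova,
                    paired_t, two_sample_t)
from .study import (SessionData, StudyConfig, SubjectContext, assign_subjects,
                    simulate_test_session, simulate_training_block)

PHASE_TO_TIME = {"baseline": "pre", "posttest": "post"}


@dataclass
class StudyReport:
    """All numeric outputs of one simulated study."""

    subject_summary: pd.DataFrame   # subject, group, time, task, pupil/acc/rt
    group_table: pd.DataFrame       # group x time x task means, study precision
    anovas: dict[str, pd.DataFrame]
    posthoc: pd.DataFrame
    followup: pd.DataFrame          # two-sample t on (post - pre) T4-T2
    baseline_error_bars: pd.DataFrame
    training_trend: Optional[pd.DataFrame]
    training_trend_subjects: Optional[pd.DataFrame]
    qc: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subject_summary.to_csv(out / "subject_summary.tsv", sep="\t", index=False)
        self.group_table.to_csv(out / "group_table.tsv", sep="\t", index=False)
        for name, table in self.anovas.items():
            table.to_csv(out / f"anova_{name}.tsv", sep="\t", index=False)
        self.posthoc.to_csv(out / "posthoc_tests.tsv", sep="\t", index=False)
        self.followup.to_csv(out / "followup_test.tsv", sep="\t", index=False)
        self.baseline_error_bars.to_csv(out / "baseline_error_bars.tsv",
                                        sep="\t", index=False)
        if self.training_trend is not None:
            self.training_trend.to_csv(out / "training_trend.tsv", sep="\t", index=False)
        if self.training_trend_subjects is not None:
            self.training_trend_subjects.to_csv(out / "training_trend_subjects.tsv",
                                                sep="\t", index=False)
        self.qc.to_csv(out / "qc_trials.tsv", sep="\t", index=False)


def summarize_session(sess: SessionData, analysis: AnalysisConfig
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-task measures for one session: pupil percent change (fixation-
    and window-restricted), percent correct over the individually counted
    central/peripheral responses, and mean RT.

    Returns (per-task summary rows, per-trial QC table).
    """
    qc, _, pct = analyze_session(sess.eye, sess.events, analysis)
    resp = sess.responses.copy()
    resp["n_correct"] = resp["central_correct"] + pd.to_numeric(
        resp["peripheral_correct"], errors="coerce").fillna(0)
    resp["n_responses"] = 1 + (resp["task_level"] >= 2).astype(int)
    rows = []
    for level in analysis.levels:
        sub = resp[resp["task_level"] == level]
        rows.append({
            "subject": sess.subject_id, "group": sess.group,
            "time": PHASE_TO_TIME.get(sess.phase, sess.phase), "task": level,
            "pupil_pct_change": pct.get(level, np.nan),
            "accuracy_pct": 100.0 * sub["n_correct"].sum() / sub["n_responses"].sum(),
            "rt_mean_s": sub["rt_s"].mean(),
        })
    qc.insert(0, "subject", sess.subject_id)
    qc.insert(1, "phase", sess.phase)
    return pd.DataFrame(rows), qc


def _anova_battery(summary: pd.DataFrame) -> tuple[dict[str, pd.DataFrame],
                                                   pd.DataFrame, pd.DataFrame]:
    """The study's statistical surface on the subject-level summary."""
    anovas: dict[str, pd.DataFrame] = {}
    for measure, name in (("pupil_pct_change", "pupil_3way"),
                          ("accuracy_pct", "accuracy_3way"),
                          ("rt_mean_s", "rt_3way")):
        long = summary.rename(columns={measure: "value"})
        anovas[name] = mixed_rm_anova(long, dv="value", subject="subject",
                                      between="group", within=["time", "task"])
    baseline = summary[summary["time"] == "pre"].rename(
        columns={"pupil_pct_change": "value"})
    anovas["pupil_baseline_2way"] = mixed_rm_anova(
        baseline, dv="value", subject="subject", between="group", within=["task"])

    diff = difference_score(summary, value="pupil_pct_change", task="task",
                            keys=["subject", "group", "time"])
    diff_long = diff.rename(columns={"difference": "value"})
    anovas["pupil_t4_minus_t2_2way"] = mixed_rm_anova(
        diff_long, dv="value", subject="subject", between="group", within=["time"])

    # post-hoc paired t tests (uncorrected, n = all subjects)
    posthoc_rows = []
    pre = baseline.pivot(index="subject", columns="task", values="value")
    acc = (summary.groupby(["subject", "task"])["accuracy_pct"].mean()
           .unstack("task"))
    for label, frame in (("pupil_pre", pre), ("accuracy", acc)):
        for a, b in ((2, 4), (3, 4), (2, 3)):
            res = paired_t(frame[a].to_numpy(), frame[b].to_numpy())
            posthoc_rows.append({"measure": label, "contrast": f"task{a}-task{b}",
                                 "t": res.t, "df": res.df, "p": res.p})
    posthoc = pd.DataFrame(posthoc_rows)

    # follow-up to the Group x Time interaction: two-sample t on each
    # subject's (post - pre) change of the Task 4 - Task 2 contrast
    change = diff.pivot_table(index=["subject", "group"], columns="time",
                              values="difference")
    change = (change["post"] - change["pre"]).rename("delta").reset_index()
    trained = change.loc[change["group"] == "trained", "delta"].to_numpy()
    control = change.loc[change["group"] == "control", "delta"].to_numpy()
    res = two_sample_t(trained, control)
    followup = pd.DataFrame([{
        "contrast": "(post-pre) Task4-Task2, trained vs control",
        "mean_trained": trained.mean(), "mean_control": control.mean(),
        "t": res.t, "df": res.df, "p": res.p,
    }])
    return anovas, posthoc, followup


def _group_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Group x time x task means at the study's reporting precision
    (pupil percent change to 2 decimals, accuracy to whole percent,
    RT to 2 decimals)."""
    g = (summary.groupby(["time", "group", "task"])
         .agg(pupil_pct_change=("pupil_pct_change", "mean"),
              accuracy_pct=("accuracy_pct", "mean"),
              rt_mean_s=("rt_mean_s", "mean"))
         .reset_index())
    g["pupil_pct_change"] = g["pupil_pct_change"].round(2)
    g["accuracy_pct"] = g["accuracy_pct"].round(0)
    g["rt_mean_s"] = g["rt_mean_s"].round(2)
    order = pd.CategoricalDtype(["pre", "post"], ordered=True)
    return g.astype({"time": order}).sort_values(["time", "group", "task"],
                                                 ignore_index=True)


def training_trend(cfg: StudyConfig, subjects: list[SubjectContext] | None = None,
                   analysis: AnalysisConfig = AnalysisConfig(),
                   low_n_trials: int = 4) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-training-day Task 4 - Task 2 pupil difference, trained group.

    Uses only the first block of each day.  Training is adaptive, so
    trial counts per task are unequal; days where a subject spent fewer
    than ``low_n_trials`` usable trials in either task are flagged (and
    days with no Task-2 trials are missing).  Returns the per-day group
    aggregate and the per-subject table behind it.
    """
    if subjects is None:
        subjects = assign_subjects(cfg)
    rows = []
    for subject in subjects:
        if subject.group != "trained":
            continue
        for day in range(1, cfg.n_training_days + 1):
            sess, _ = simulate_training_block(subject, day, 1, cfg, with_eye=True)
            n2 = int((sess.events["task_level"] == 2).sum())
            n4 = int((sess.events["task_level"] == 4).sum())
            try:
                _, _, pct = analyze_session(sess.eye, sess.events, analysis)
                value = pct.get(4, np.nan)
            except Exception:
                value = np.nan
            rows.append({"subject": subject.subject_id, "day": day,
                         "t4_minus_t2_pct": value,
                         "n_task2_trials": n2, "n_task4_trials": n4,
                         "low_n": int(n2 < low_n_trials or n4 < low_n_trials
                                      or not np.isfinite(value))})
    per_subject = pd.DataFrame(rows)
    daily = (per_subject.groupby("day")
             .agg(mean_t4_minus_t2_pct=("t4_minus_t2_pct", "mean"),
                  n_subjects=("t4_minus_t2_pct", lambda s: int(s.notna().sum())),
                  n_low_n=("low_n", "sum"),
                  mean_n_task2_trials=("n_task2_trials", "mean"),
                  mean_n_task4_trials=("n_task4_trials", "mean"))
             .reset_index())
    return daily, per_subject


def run_study(cfg: StudyConfig, out_dir=None, *, seed: int | None = None,
              analysis: AnalysisConfig = AnalysisConfig(),
              with_training: bool = True) -> StudyReport:
    """Simulate and analyze one full study.

    Deterministic in ``cfg.master_seed`` (overridable via ``seed``) and
    invariant to subject processing order.  When ``out_dir`` is given the
    report tables are written there as TSV.
    """
    if seed is not None:
        cfg = dataclasses.replace(cfg, master_seed=int(seed))
    subjects = assign_subjects(cfg)
    summaries, qcs = [], []
    for subject in subjects:
        for phase in ("baseline", "posttest"):
            try:
                sess = simulate_test_session(subject, phase, cfg, with_eye=True)
                rows, qc = summarize_session(sess, analysis)
            except Exception as exc:
                raise RuntimeError(
                    f"stage {phase!r} failed for {subject.subject_id}") from exc
            summaries.append(rows)
            qcs.append(qc)
    summary = pd.concat(summaries, ignore_index=True)
    qc = pd.concat(qcs, ignore_index=True)

    anovas, posthoc, followup = _anova_battery(summary)
    baseline_wide = (summary[summary["time"] == "pre"]
                     .pivot(index="subject", columns="task",
                            values="pupil_pct_change"))
    error_bars = cousineau_morey(baseline_wide)

    trend = trend_subjects = None
    if with_training:
        trend, trend_subjects = training_trend(cfg, subjects, analysis)
    report = StudyReport(subject_summary=summary,
                         group_table=_group_table(summary),
                         anovas=anovas, posthoc=posthoc, followup=followup,
                         baseline_error_bars=error_bars,
                         training_trend=trend,
                         training_trend_subjects=trend_subjects, qc=qc)
    if out_dir is not None:
        report.write(out_dir)
    return report
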