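"""Pupil measurement pipeline.

The analysis restricts pupil samples to fixations (eye movements bias the
measured diameter) inside a 500-ms window of interest ending at probe
onset — the final 500 ms of the white-noise mask, where luminance is
identical across conditions.  Because the tracker's arbitrary units drift
between sessions, all inference is on within-session percent change of
the per-task mean pupil diameter relative to Task 2, whose mean is
defined to be zero.

Fixations are re-derived from the raw samples with a dispersion-threshold
(I-DT) detector: maximal runs of valid, temporally contiguous samples
whose dispersion (x-range + y-range) stays below a threshold for at least
a minimum duration.  Blink (invalid) samples always split runs and never
enter any mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .paradigm import TrialTimeline

EYE_COLUMNS = ["t_ms", "x", "y", "pupil_au", "valid"]

WINDOW_MS = 500
DISPERSION_THRESHOLD_DEG = 1.0
MIN_FIXATION_MS = 100

ANALYSIS_LEVELS = (2, 3, 4)  # Task 1 engages focused attention; excluded


class EyeFormatError(ValueError):
    """Raised for malformed or non-monotone eye-sample files."""


@dataclass(frozen=True)
class FixationEvent:
    """Half-open interval [start_ms, end_ms) of stable, valid gaze."""

    start_ms: int
    end_ms: int
    mean_x: float
    mean_y: float
    n_samples: int

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class PupilTrialMeasure:
    trial_index: int
    task_level: int
    window: tuple[float, float]
    mean_pupil_au: Optional[float]  # None when no fixated sample in window
    n_window_samples: int


@dataclass(frozen=True)
class AnalysisConfig:
    dispersion_threshold: float = DISPERSION_THRESHOLD_DEG
    min_fixation_ms: int = MIN_FIXATION_MS
    window_ms: int = WINDOW_MS
    per_fixation_means: bool = False  # mean of per-fixation means instead of sample-weighted
    include_task1: bool = False

    @property
    def levels(self) -> tuple[int, ...]:
        return (1, 2, 3, 4) if self.include_task1 else ANALYSIS_LEVELS


def read_eye_samples(path) -> tuple[pd.DataFrame, dict]:
    """Read an eye-sample TSV (columns ``t_ms  x  y  pupil_au  valid``).

    Lines starting with ``#`` are ``key=value`` metadata.  Returns the
    samples (invalid rows retained, flagged) and the metadata dict.
    Raises :class:`EyeFormatError` with a line number on malformed rows
    and on non-increasing timestamps.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (pd.errors.ParserError, ValueError) as exc:
        raise EyeFormatError(f"{path}: cannot parse eye-sample TSV: {exc}") from exc
    missing = [c for c in EYE_COLUMNS if c not in df.columns]
    if missing:
        raise EyeFormatError(f"{path}: missing columns {missing}")
    df = df[EYE_COLUMNS]
    for col in EYE_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(coerced.isna().to_numpy())[0]
        if bad.size:
            # +2: 1-based and the column-header line (metadata lines precede it)
            lineno = int(bad[0]) + header_lines + 2
            raise EyeFormatError(f"{path}:{lineno}: non-numeric value in column {col!r}")
        df[col] = coerced
    if not set(np.unique(df["valid"])) <= {0, 1}:
        raise EyeFormatError(f"{path}: valid flag must be 0 or 1")
    t = df["t_ms"].to_numpy()
    nonmono = np.nonzero(np.diff(t) <= 0)[0]
    if nonmono.size:
        lineno = int(nonmono[0]) + header_lines + 3
        raise EyeFormatError(
            f"{path}:{lineno}: timestamps must be strictly increasing "
            f"(t={t[nonmono[0] + 1]} follows t={t[nonmono[0]]})")
    df["t_ms"] = df["t_ms"].astype(np.int64)
    df["valid"] = df["valid"].astype(np.int8)
    return df.reset_index(drop=True), meta


def write_eye_samples(df: pd.DataFrame, path, meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def _idt_runs(t: np.ndarray, x: np.ndarray, y: np.ndarray,
              threshold: float, min_len: int) -> list[tuple[int, int]]:
    """I-DT on one contiguous valid run; returns index intervals [i, j)."""
    n = len(t)
    out = []
    i = 0
    while i + min_len <= n:
        xs, ys = x[i:], y[i:]
        # running dispersion of the window anchored at i
        disp = (np.maximum.accumulate(xs) - np.minimum.accumulate(xs)
                + np.maximum.accumulate(ys) - np.minimum.accumulate(ys))
        over = np.nonzero(disp > threshold)[0]
        j = i + (int(over[0]) if over.size else len(xs))
        if j - i >= min_len:
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_fixations(samples: pd.DataFrame,
                     dispersion_threshold: float = DISPERSION_THRESHOLD_DEG,
                     min_duration_ms: int = MIN_FIXATION_MS) -> list[FixationEvent]:
    """Dispersion-threshold fixation detection on 1-ms samples.

    Runs are split at invalid samples and at any gap in the 1-ms sample
    clock, so no fixation ever contains a blink or spans a recording gap.
    """
    if len(samples) == 0:
        return []
    t = samples["t_ms"].to_numpy()
    x = samples["x"].to_numpy(float)
    y = samples["y"].to_numpy(float)
    valid = samples["valid"].to_numpy() == 1
    # boundaries: invalid samples and clock gaps
    breaks = np.nonzero(np.diff(t) != 1)[0] + 1
    run_edges = np.concatenate(([0], breaks, [len(t)]))
    events: list[FixationEvent] = []
    for a, b in zip(run_edges[:-1], run_edges[1:]):
        v = valid[a:b]
        # split further at invalid samples
        idx = np.nonzero(v)[0]
        if idx.size == 0:
            continue
        sub_breaks = np.nonzero(np.diff(idx) != 1)[0] + 1
        for seg in np.split(idx, sub_breaks):
            s0, s1 = a + seg[0], a + seg[-1] + 1
            for i, j in _idt_runs(t[s0:s1], x[s0:s1], y[s0:s1],
                                  dispersion_threshold, int(min_duration_ms)):
                lo, hi = s0 + i, s0 + j
                events.append(FixationEvent(
                    start_ms=int(t[lo]), end_ms=int(t[hi - 1]) + 1,
                    mean_x=float(x[lo:hi].mean()), mean_y=float(y[lo:hi].mean()),
                    n_samples=hi - lo))
    return events


def window_of_interest(timeline: TrialTimeline, window_ms: int = WINDOW_MS,
                       t0_ms: float = 0.0) -> tuple[float, float]:
    """The ``window_ms`` (default 500) before probe onset, half-open.

    Coincides with the final 500 ms of the mask, where luminance is
    identical across conditions.  ``t0_ms`` shifts to the session clock.
    """
    probe = timeline.probe_on_ms + t0_ms
    return (probe - window_ms, probe)


def trial_pupil(samples: pd.DataFrame, fixations: Sequence[FixationEvent],
                window: tuple[float, float], *, trial_index: int = 0,
                task_level: int = 0,
                per_fixation_means: bool = False) -> PupilTrialMeasure:
    """Mean pupil over samples inside both the window and a fixation.

    Default weighting is per sample; ``per_fixation_means`` instead
    averages each fixation's in-window mean (unweighted across
    fixations).  Missing when no fixated sample falls in the window.
    """
    t = samples["t_ms"].to_numpy()
    pupil = samples["pupil_au"].to_numpy(float)
    lo, hi = window
    in_win = (t >= lo) & (t < hi)
    per_fix_vals = []
    mask = np.zeros(len(t), bool)
    for fx in fixations:
        sel = in_win & (t >= fx.start_ms) & (t < fx.end_ms)
        if sel.any():
            per_fix_vals.append(pupil[sel].mean())
            mask |= sel
    n = int(mask.sum())
    if n == 0:
        mean = None
    elif per_fixation_means:
        mean = float(np.mean(per_fix_vals))
    else:
        mean = float(pupil[mask].mean())
    return PupilTrialMeasure(trial_index=trial_index, task_level=task_level,
                             window=(float(lo), float(hi)), mean_pupil_au=mean,
                             n_window_samples=n)


class NormalizationError(ValueError):
    """Raised when the Task-2 reference mean is absent or non-positive."""


def session_condition_means(measures: Iterable[PupilTrialMeasure],
                            levels: Sequence[int] = (1, 2, 3, 4)) -> dict[int, float]:
    """Unweighted mean over non-missing trial measures, per task level.

    Levels with zero usable trials are omitted from the result (the
    caller decides whether that is fatal; normalization refuses without
    Task 2).
    """
    by_level: dict[int, list[float]] = {lv: [] for lv in levels}
    for m in measures:
        if m.task_level in by_level and m.mean_pupil_au is not None:
            by_level[m.task_level].append(m.mean_pupil_au)
    return {lv: float(np.mean(vals)) for lv, vals in by_level.items() if vals}


def pct_change_from_task2(means: Mapping[int, float],
                          levels: Sequence[int] = ANALYSIS_LEVELS) -> dict[int, float]:
    """Percent change of each task's mean pupil from the Task-2 mean.

    Task 2 is exactly 0 by definition.  Scale-invariant: multiplying
    every session sample by a constant leaves the outputs unchanged.
    """
    if 2 not in means:
        raise NormalizationError("no usable Task-2 trials: percent change undefined")
    ref = means[2]
    if not (ref > 0):
        raise NormalizationError(f"Task-2 mean must be positive, got {ref!r}")
    out: dict[int, float] = {}
    for lv in levels:
        if lv == 2:
            out[2] = 0.0
        elif lv in means:
            out[lv] = 100.0 * (means[lv] - ref) / ref
    return out


def analyze_session(eye: pd.DataFrame, events: pd.DataFrame,
                    cfg: AnalysisConfig = AnalysisConfig()
                    ) -> tuple[pd.DataFrame, dict[int, float], dict[int, float]]:
    """Run the full measurement chain on one session.

    ``events`` is the trial-event table with absolute session times
    (``cue_on_ms`` ... ``probe_on_ms``).  Returns (per-trial QC table,
    per-level mean pupil in au, per-level percent change from Task 2).
    """
    t_all = eye["t_ms"].to_numpy()
    measures: list[PupilTrialMeasure] = []
    qc_rows = []
    for row in events.itertuples(index=False):
        lo_idx = np.searchsorted(t_all, row.cue_on_ms, "left")
        hi_idx = np.searchsorted(t_all, row.probe_on_ms, "left")
        trial_samples = eye.iloc[lo_idx:hi_idx]
        fixations = detect_fixations(trial_samples, cfg.dispersion_threshold,
                                     cfg.min_fixation_ms)
        window = (row.probe_on_ms - cfg.window_ms, row.probe_on_ms)
        m = trial_pupil(trial_samples, fixations, window,
                        trial_index=row.trial_index, task_level=row.task_level,
                        per_fixation_means=cfg.per_fixation_means)
        measures.append(m)
        qc_rows.append({
            "trial_index": row.trial_index, "task_level": row.task_level,
            "n_fixations": len(fixations), "n_window_samples": m.n_window_samples,
            "mean_pupil_au": np.nan if m.mean_pupil_au is None else m.mean_pupil_au,
            "missing_reason": "" if m.mean_pupil_au is not None
                              else "no fixated sample in window",
        })
    means = session_condition_means(measures, levels=(1, 2, 3, 4))
    pct = pct_change_from_task2(means, levels=cfg.levels)
    return pd.DataFrame(qc_rows), means, pct
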