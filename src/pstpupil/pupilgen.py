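"""Synthetic 1000-Hz eye-tracker streams with a load-dependent
task-evoked pupillary response.

Pupil diameter is produced in arbitrary units (au), as real video-based
trackers report it: a session-specific gain multiplies everything, so only
within-session contrasts are meaningful.  Per sample at time t (ms from
cue onset):

    pupil(t) = gain * (baseline_au * (1 + A_level/100 * k(t)) + noise)

where A_level is the task-evoked amplitude in percent of baseline and
k(t) is a smoothstep rise starting ``response_latency_ms`` after stimulus
onset and saturating at exactly 1 after ``response_width_ms`` more, i.e.
before and throughout the 500-ms window preceding the probe.  Because the
analysis only reads that plateau, the rise shape is immaterial to the
measured contrasts, and injected amplitude differences are recovered
exactly when noise and blinks are disabled.  Luminance is constant by
construction (the mask is equiluminant across conditions), so there is no
light-reflex term.

Gaze follows a central fixation with Gaussian jitter, interrupted by
Poisson-rate saccades (valid samples, large dispersion) and blinks
(invalid samples, pupil = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .paradigm import TrialSpec, TrialTimeline, trial_timeline

#: default task-evoked amplitudes (% of baseline) before training; the
#: Task-2 amplitude is the reference the percent-change analysis zeroes.
DEFAULT_AMPLITUDES_PCT: Mapping[int, float] = {1: 0.0, 2: 1.0, 3: 1.1, 4: 3.17}

#: trained-group posttest amplitudes: the Task-3/4 load response is
#: flattened toward the Task-2 level, emulating more efficient allocation.
POST_TRAINED_AMPLITUDES_PCT: Mapping[int, float] = {1: 0.0, 2: 1.0, 3: 0.283, 4: 0.939}


@dataclass(frozen=True)
class PupilGenParams:
    """Generator knobs for one subject's eye streams.

    ``baseline_au = 1000`` with ``sample_noise_au = 2`` mirrors the
    relative resolution of a video tracker (0.2% of a mid-size pupil);
    both are order-of-magnitude emulation, not physiology.
    """

    baseline_au: float = 1000.0
    load_amplitude_pct: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES_PCT))
    response_latency_ms: float = 200.0
    response_width_ms: float = 300.0
    sample_noise_au: float = 2.0
    blink_rate_hz: float = 0.1
    blink_duration_ms: float = 150.0
    saccade_rate_hz: float = 1.0
    saccade_duration_ms: float = 30.0
    saccade_spread_deg: float = 0.8
    fixation_jitter_deg: float = 0.05
    gain_jitter_pct: float = 10.0

    def __post_init__(self) -> None:
        if not (self.baseline_au > 0):
            raise ValueError("baseline_au must be positive")
        for lv in (1, 2, 3, 4):
            if lv not in self.load_amplitude_pct or not np.isfinite(self.load_amplitude_pct[lv]):
                raise ValueError("load_amplitude_pct must map levels 1-4 to finite values")
        if self.response_latency_ms < 0 or self.response_width_ms <= 0:
            raise ValueError("evoked-kernel latency/width must be non-negative/positive")
        for name in ("sample_noise_au", "blink_rate_hz", "saccade_rate_hz",
                     "gain_jitter_pct", "fixation_jitter_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def evoked_kernel(t_ms: np.ndarray, stim_on_ms: float,
                  latency_ms: float, width_ms: float) -> np.ndarray:
    """Smoothstep rise from 0 to exactly 1, anchored to stimulus onset.

    Zero until ``stim_on + latency``; exactly 1 from ``stim_on + latency
    + width`` onward (the analysis window reads this plateau).
    """
    return _smoothstep((np.asarray(t_ms, float) - stim_on_ms - latency_ms) / width_ms)


def draw_session_gain(params: PupilGenParams, rng: np.random.Generator) -> float:
    """Session-specific multiplicative gain (camera/geometry drift)."""
    sd = params.gain_jitter_pct / 100.0
    return float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0


def simulate_trial_eye(spec: TrialSpec, params: PupilGenParams,
                       rng: np.random.Generator,
                       *, gain: float = 1.0,
                       timeline: TrialTimeline | None = None,
                       t0_ms: int = 0) -> pd.DataFrame:
    """One trial's eye stream: one sample per ms from cue onset to probe
    onset, columns ``t_ms, x, y, pupil_au, valid``.

    Timestamps start at ``t0_ms`` (the trial's cue onset on the session
    clock).  Blink samples have ``valid = 0`` and ``pupil_au = 0``.
    """
    tl = timeline if timeline is not None else trial_timeline(spec)
    n = int(round(tl.probe_on_ms - tl.cue_on_ms))
    t_rel = np.arange(n, dtype=float)

    amp = params.load_amplitude_pct[spec.task_level]
    k = evoked_kernel(t_rel, tl.stim_on_ms, params.response_latency_ms,
                      params.response_width_ms)
    pupil = params.baseline_au * (1.0 + amp / 100.0 * k)
    if params.sample_noise_au > 0:
        pupil = pupil + rng.normal(0.0, params.sample_noise_au, n)
    pupil = gain * pupil

    # gaze: piecewise-constant fixation centres with short linear saccadic
    # transitions, plus per-sample jitter
    x = np.zeros(n)
    y = np.zeros(n)
    cx, cy = 0.0, 0.0
    n_sacc = rng.poisson(params.saccade_rate_hz * n / 1000.0)
    sacc_onsets = np.sort(rng.integers(0, n, size=n_sacc)) if n_sacc else np.array([], int)
    pos = 0
    for onset in sacc_onsets:
        onset = int(onset)
        if onset < pos:
            continue
        x[pos:onset] = cx
        y[pos:onset] = cy
        nx = float(rng.normal(0.0, params.saccade_spread_deg))
        ny = float(rng.normal(0.0, params.saccade_spread_deg))
        dur = max(1, int(round(params.saccade_duration_ms)))
        end = min(n, onset + dur)
        ramp = np.linspace(0.0, 1.0, end - onset)
        x[onset:end] = cx + (nx - cx) * ramp
        y[onset:end] = cy + (ny - cy) * ramp
        cx, cy = nx, ny
        pos = end
    x[pos:] = cx
    y[pos:] = cy
    if params.fixation_jitter_deg > 0:
        x = x + rng.normal(0.0, params.fixation_jitter_deg, n)
        y = y + rng.normal(0.0, params.fixation_jitter_deg, n)

    valid = np.ones(n, dtype=np.int8)
    n_blinks = rng.poisson(params.blink_rate_hz * n / 1000.0)
    if n_blinks:
        for onset in rng.integers(0, n, size=n_blinks):
            end = min(n, int(onset) + int(round(params.blink_duration_ms)))
            valid[int(onset):end] = 0
    pupil = np.where(valid == 1, pupil, 0.0)

    return pd.DataFrame({
        "t_ms": (t0_ms + np.arange(n)).astype(np.int64),
        "x": x, "y": y, "pupil_au": pupil, "valid": valid,
    })
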