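"""Whole-study synthetic data generation.

Emulates everything the real experiment measured for twenty subjects
randomized 10/10 to processing-speed training or no-contact control:
a 500-trial baseline test, six training days of two 375-trial adaptive
blocks (trained group only), and a 500-trial posttest, each with per-trial
dual responses and a 1000-Hz eye stream.

Subject heterogeneity (psychometric threshold, task-evoked amplitude,
response speed) and session-level variability (tracker gain, amplitude
scatter) are explicit dispersion knobs: the study's published group-level
statistics come from unavailable human data, so these defaults are chosen
to produce realistic effect sizes, not to assert physiology.

All randomness derives from a single master seed through keyed
``SeedSequence`` streams (subject x phase x block x trial), so the full
study regenerates bit-identically and is independent of processing order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import paradigm, staircase
from .observer import ObserverParams, simulate_response
from .paradigm import TrialSpec, trial_timeline
from .pipeline import write_eye_samples
from .pupilgen import (DEFAULT_AMPLITUDES_PCT, POST_TRAINED_AMPLITUDES_PCT,
                       PupilGenParams, draw_session_gain, simulate_trial_eye)

PHASE_CODE = {"baseline": 0, "training": 1, "posttest": 2}

# seed-stream purpose tags (keyed SeedSequence entropy)
_K_SCHED, _K_RESP, _K_EYE, _K_GAIN, _K_GROUP, _K_SUBJ, _K_TRAIN, _K_SESS = range(1, 9)


def keyed_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Deterministic, order-invariant stream for a (purpose, indices) key."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, key)]))


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class ObserverStudyConfig:
    """Population observer model: base psychometric parameters plus
    between-subject dispersion and a posttest practice effect on RT."""

    base: ObserverParams = field(default_factory=ObserverParams)
    subject_threshold_log_sd: float = 0.2
    subject_rt_sd_s: float = 0.1
    rt_practice_factor: float = 0.94  # both groups respond a bit faster at posttest


@dataclass(frozen=True)
class PupilStudyConfig:
    """Population pupil model: stream generator defaults plus the
    amplitude schedule and its subject/session dispersion (% points)."""

    gen: PupilGenParams = field(default_factory=PupilGenParams)
    amplitudes_pre: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES_PCT))
    amplitudes_post_trained: Mapping[int, float] = field(
        default_factory=lambda: dict(POST_TRAINED_AMPLITUDES_PCT))
    subject_amp_sd_pct: float = 1.5
    session_amp_sd_pct: float = 1.0
    #: interpolate trained-group amplitudes from pre toward post across
    #: training days (the within-training trend the study tracked)
    interpolate_training: bool = True


@dataclass(frozen=True)
class StaircaseConfig:
    ladder_ms: tuple[float, ...] = staircase.DEFAULT_LADDER_MS
    check_every: int = staircase.CHECK_EVERY
    up_threshold_pct: float = staircase.UP_THRESHOLD_PCT
    down_threshold_pct: float = staircase.DOWN_THRESHOLD_PCT
    start_level: int = staircase.START_LEVEL
    start_duration_ms: float = staircase.START_DURATION_MS
    reset_each_block: bool = True

    def ladder(self) -> staircase.DurationLadder:
        return staircase.DurationLadder(tuple(self.ladder_ms))


@dataclass(frozen=True)
class StudyConfig:
    n_per_group: int = 10
    n_training_days: int = 6
    blocks_per_day: int = 2
    trials_per_block: int = 375
    n_sets: int = 5
    set_size: int = 25
    cue_ms: float = paradigm.CUE_MS
    mask_ms: float = paradigm.MASK_MS
    n_locations: int = paradigm.N_LOCATIONS
    eccentricity_deg: float = paradigm.ECCENTRICITY_DEG
    iti_ms: int = 500
    master_seed: int = 20131018
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    observer: ObserverStudyConfig = field(default_factory=ObserverStudyConfig)
    pupil: PupilStudyConfig = field(default_factory=PupilStudyConfig)
    training_eye: str = "first_block"  # which training blocks get eye streams

    def __post_init__(self) -> None:
        for name in ("n_per_group", "n_training_days", "blocks_per_day",
                     "trials_per_block", "n_sets", "set_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)!r}")
        if self.training_eye not in ("first_block", "all", "none"):
            raise ValueError("training_eye must be first_block/all/none")

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_per_group


def _amp_map(d: Mapping) -> dict[int, float]:
    return {int(k): float(v) for k, v in d.items()}


def config_from_dict(raw: Mapping) -> StudyConfig:
    """Build a :class:`StudyConfig` from a (JSON-decoded) mapping,
    rejecting unknown keys with an explicit message."""

    def build(cls, section: Mapping, path: str):
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(section) - set(fields)
        if unknown:
            raise ValueError(f"unknown {path} keys: {sorted(unknown)}; "
                             f"allowed: {sorted(fields)}")
        kwargs = {}
        for key, val in section.items():
            if key == "base":
                val = dict(val)
                if "threshold_ms" in val:
                    val["threshold_ms"] = _amp_map(val["threshold_ms"])
                val = ObserverParams(**val)
            elif key == "gen":
                val = dict(val)
                if "load_amplitude_pct" in val:
                    val["load_amplitude_pct"] = _amp_map(val["load_amplitude_pct"])
                val = PupilGenParams(**val)
            elif key in ("amplitudes_pre", "amplitudes_post_trained"):
                val = _amp_map(val)
            elif key == "ladder_ms":
                val = tuple(float(x) for x in val)
            kwargs[key] = val
        return cls(**kwargs)

    raw = dict(raw)
    sub = {"staircase": StaircaseConfig, "observer": ObserverStudyConfig,
           "pupil": PupilStudyConfig}
    kwargs = {}
    for key, val in raw.items():
        if key in sub:
            kwargs[key] = build(sub[key], val, key)
        else:
            kwargs[key] = val
    return build(StudyConfig, kwargs, "top-level")


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        return config_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# per-subject derived parameters

@dataclass(frozen=True)
class SubjectContext:
    index: int
    subject_id: str
    group: str  # trained | control
    threshold_mult: float
    rt_shift_s: float
    amp_offset_pct: Mapping[int, float]


def assign_subjects(cfg: StudyConfig) -> list[SubjectContext]:
    """Randomize subjects to groups and draw per-subject traits."""
    n = cfg.n_subjects
    rng = keyed_rng(cfg.master_seed, _K_GROUP)
    order = rng.permutation(n)
    groups = {int(i): ("trained" if rank < cfg.n_per_group else "control")
              for rank, i in enumerate(order)}
    out = []
    for i in range(n):
        r = keyed_rng(cfg.master_seed, _K_SUBJ, i)
        thr = float(np.exp(r.normal(0.0, cfg.observer.subject_threshold_log_sd)))
        rt = float(r.normal(0.0, cfg.observer.subject_rt_sd_s))
        amps = {lv: float(r.normal(0.0, cfg.pupil.subject_amp_sd_pct))
                for lv in (1, 2, 3, 4)}
        out.append(SubjectContext(index=i, subject_id=f"S{i + 1:02d}",
                                  group=groups[i], threshold_mult=thr,
                                  rt_shift_s=rt, amp_offset_pct=amps))
    return out


def _observer_for(subject: SubjectContext, cfg: StudyConfig, *,
                  threshold_shift: float = 1.0,
                  rt_factor: float = 1.0) -> ObserverParams:
    base = cfg.observer.base
    thr = {lv: v * subject.threshold_mult * threshold_shift
           for lv, v in base.threshold_ms.items()}
    return replace(base, threshold_ms=thr,
                   rt_mean_s=max(base.rt_min_s + 1e-6,
                                 base.rt_mean_s * rt_factor + subject.rt_shift_s))


def _session_amplitudes(subject: SubjectContext, cfg: StudyConfig,
                        base_amps: Mapping[int, float],
                        rng: np.random.Generator) -> dict[int, float]:
    sd = cfg.pupil.session_amp_sd_pct
    return {lv: float(base_amps[lv] + subject.amp_offset_pct[lv]
                      + (rng.normal(0.0, sd) if sd > 0 else 0.0))
            for lv in (1, 2, 3, 4)}


def training_day_amplitudes(cfg: StudyConfig, day: int) -> dict[int, float]:
    """Trained-group amplitude schedule on training day ``day`` (1-based):
    linear interpolation from the pre-training to the post-training map."""
    pre = _amp_map(cfg.pupil.amplitudes_pre)
    post = _amp_map(cfg.pupil.amplitudes_post_trained)
    if not cfg.pupil.interpolate_training:
        return pre
    frac = day / cfg.n_training_days
    return {lv: pre[lv] + (post[lv] - pre[lv]) * frac for lv in (1, 2, 3, 4)}


def training_threshold_shift(cfg: StudyConfig, day: int, block: int) -> float:
    """Practice effect during training: thresholds slide from 1 toward
    ``training_shift`` as blocks are completed."""
    total = cfg.n_training_days * cfg.blocks_per_day
    done = (day - 1) * cfg.blocks_per_day + (block - 1)
    shift = cfg.observer.base.training_shift
    return 1.0 + (shift - 1.0) * (done / total)


# ---------------------------------------------------------------------------
# session simulation

@dataclass
class SessionData:
    subject_id: str
    group: str
    phase: str
    events: pd.DataFrame     # trial-event table, absolute session times (ms)
    responses: pd.DataFrame
    eye: Optional[pd.DataFrame]
    gain: float


def _events_row(spec: TrialSpec, t0: int, cfg: StudyConfig) -> dict:
    tl = trial_timeline(spec, cue_ms=cfg.cue_ms, mask_ms=cfg.mask_ms)
    return {
        "trial_index": spec.trial_index, "phase": spec.phase,
        "task_level": spec.task_level, "duration_ms": spec.stimulus_duration_ms,
        "central_identity": spec.central_identity,
        "peripheral_location": ("" if spec.peripheral_location is None
                                else spec.peripheral_location),
        "distractor_kind": spec.distractor_kind,
        "cue_on_ms": t0 + tl.cue_on_ms, "stim_on_ms": t0 + tl.stim_on_ms,
        "mask_on_ms": t0 + tl.mask_on_ms, "probe_on_ms": t0 + tl.probe_on_ms,
    }


def _simulate_trials(specs: list[TrialSpec], subject: SubjectContext,
                     cfg: StudyConfig, observer: ObserverParams,
                     amps: Mapping[int, float], gain: float,
                     resp_rng: np.random.Generator,
                     eye_key: tuple[int, ...], with_eye: bool,
                     responses: list | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, Optional[pd.DataFrame]]:
    """Shared clock loop: events + responses (+ eye) for a trial list.

    ``responses`` may carry pre-simulated response records (training
    blocks, where responses drive the staircase); otherwise they are
    drawn here.  Eye streams use one keyed rng per trial so that
    generating a subset of sessions never perturbs the others.
    """
    gen = replace(cfg.pupil.gen, load_amplitude_pct=dict(amps))
    ev_rows, resp_rows, eye_parts = [], [], []
    clock = 0
    for k, spec in enumerate(specs):
        tl = trial_timeline(spec, cue_ms=cfg.cue_ms, mask_ms=cfg.mask_ms)
        ev_rows.append(_events_row(spec, clock, cfg))
        rec = responses[k] if responses is not None else simulate_response(
            spec, observer, trained=False, rng=resp_rng)
        resp_rows.append({
            "trial_index": spec.trial_index, "task_level": spec.task_level,
            "central_correct": int(rec.central_correct),
            "peripheral_correct": ("" if rec.peripheral_correct is None
                                   else int(rec.peripheral_correct)),
            "rt_s": rec.rt_s,
        })
        if with_eye:
            rng_eye = keyed_rng(cfg.master_seed, _K_EYE, *eye_key, k)
            eye_parts.append(simulate_trial_eye(spec, gen, rng_eye, gain=gain,
                                                timeline=tl, t0_ms=clock))
        clock += int(round(tl.probe_on_ms)) + int(round(rec.rt_s * 1000)) + cfg.iti_ms
    eye = pd.concat(eye_parts, ignore_index=True) if eye_parts else None
    return pd.DataFrame(ev_rows), pd.DataFrame(resp_rows), eye


def simulate_test_session(subject: SubjectContext, phase: str,
                          cfg: StudyConfig, *, with_eye: bool = True) -> SessionData:
    """One baseline or posttest session: fixed 200-ms schedule, task level
    cycling every ``set_size`` trials."""
    if phase not in ("baseline", "posttest"):
        raise ValueError(f"test phase must be baseline/posttest, got {phase!r}")
    pcode = PHASE_CODE[phase]
    trained_now = phase == "posttest" and subject.group == "trained"
    sched_rng = keyed_rng(cfg.master_seed, _K_SCHED, subject.index, pcode)
    specs = paradigm.build_test_schedule(
        cfg.n_sets, cfg.set_size, sched_rng, phase=phase,
        n_locations=cfg.n_locations)
    observer = _observer_for(
        subject, cfg,
        threshold_shift=cfg.observer.base.training_shift if trained_now else 1.0,
        rt_factor=cfg.observer.rt_practice_factor if phase == "posttest" else 1.0)
    base_amps = (_amp_map(cfg.pupil.amplitudes_post_trained) if trained_now
                 else _amp_map(cfg.pupil.amplitudes_pre))
    sess_rng = keyed_rng(cfg.master_seed, _K_SESS, subject.index, pcode)
    amps = _session_amplitudes(subject, cfg, base_amps, sess_rng)
    gain = draw_session_gain(cfg.pupil.gen, keyed_rng(cfg.master_seed, _K_GAIN,
                                                      subject.index, pcode))
    resp_rng = keyed_rng(cfg.master_seed, _K_RESP, subject.index, pcode)
    events, responses, eye = _simulate_trials(
        specs, subject, cfg, observer, amps, gain, resp_rng,
        eye_key=(subject.index, pcode, 0, 0), with_eye=with_eye)
    return SessionData(subject.subject_id, subject.group, phase,
                       events, responses, eye, gain)


def simulate_training_block(subject: SubjectContext, day: int, block: int,
                            cfg: StudyConfig, *, with_eye: bool) -> tuple[SessionData, pd.DataFrame]:
    """One adaptive training block (1-based ``day``/``block``).

    Returns the session data plus the staircase trace table.
    """
    if subject.group != "trained":
        raise ValueError(f"{subject.subject_id} is a control subject: no training")
    pcode = PHASE_CODE["training"]
    sc = cfg.staircase
    observer = _observer_for(subject, cfg,
                             threshold_shift=training_threshold_shift(cfg, day, block))
    trace = staircase.run_training_block(
        observer, cfg.trials_per_block,
        keyed_rng(cfg.master_seed, _K_TRAIN, subject.index, day, block),
        ladder=sc.ladder(), check_every=sc.check_every,
        start_level=sc.start_level, start_duration_ms=sc.start_duration_ms,
        up_threshold_pct=sc.up_threshold_pct,
        down_threshold_pct=sc.down_threshold_pct,
        n_locations=cfg.n_locations)
    base_amps = training_day_amplitudes(cfg, day)
    sess_rng = keyed_rng(cfg.master_seed, _K_SESS, subject.index, pcode, day, block)
    amps = _session_amplitudes(subject, cfg, base_amps, sess_rng)
    gain = draw_session_gain(cfg.pupil.gen,
                             keyed_rng(cfg.master_seed, _K_GAIN, subject.index,
                                       pcode, day, block))
    from .observer import ResponseRecord
    specs = [r.spec for r in trace]
    recs = [ResponseRecord(r.central_correct, r.peripheral_correct, r.rt_s)
            for r in trace]
    events, responses, eye = _simulate_trials(
        specs, subject, cfg, observer, amps, gain,
        resp_rng=None, eye_key=(subject.index, pcode, day, block),
        with_eye=with_eye, responses=recs)
    sess = SessionData(subject.subject_id, subject.group, "training",
                       events, responses, eye, gain)
    return sess, staircase.trace_to_frame(trace, sc.ladder())


# ---------------------------------------------------------------------------
# on-disk study

def generate_study(cfg: StudyConfig, out_dir, *, seed: int | None = None) -> dict:
    """Write the full synthetic study to ``out_dir`` and return the manifest.

    Per subject: baseline and posttest trial/response/eye files; for
    trained subjects, per-block staircase traces and (per
    ``cfg.training_eye``) training eye streams.
    """
    if seed is not None:
        cfg = replace(cfg, master_seed=int(seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": cfg.master_seed, "subjects": {}}
    for subject in assign_subjects(cfg):
        sdir = out / subject.subject_id
        sdir.mkdir(exist_ok=True)
        entry: dict = {"group": subject.group, "phases": {}}
        for phase in ("baseline", "posttest"):
            sess = simulate_test_session(subject, phase, cfg, with_eye=True)
            paths = _write_session(sess, sdir, phase, cfg)
            entry["phases"][phase] = paths
        if subject.group == "trained":
            tr: dict = {}
            for day in range(1, cfg.n_training_days + 1):
                for block in range(1, cfg.blocks_per_day + 1):
                    with_eye = (cfg.training_eye == "all"
                                or (cfg.training_eye == "first_block" and block == 1))
                    sess, trace = simulate_training_block(subject, day, block, cfg,
                                                          with_eye=with_eye)
                    key = f"day{day}_block{block}"
                    paths = _write_session(sess, sdir, f"training_{key}", cfg)
                    trace_path = sdir / f"training_{key}_trace.tsv"
                    trace.to_csv(trace_path, sep="\t", index=False)
                    paths["trace"] = str(trace_path)
                    tr[key] = paths
            entry["phases"]["training"] = tr
        manifest["subjects"][subject.subject_id] = entry
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _write_session(sess: SessionData, sdir: Path, tag: str,
                   cfg: StudyConfig) -> dict:
    ev_path = sdir / f"{tag}_trials.csv"
    resp_path = sdir / f"{tag}_responses.tsv"
    sess.events.to_csv(ev_path, index=False)
    sess.responses.to_csv(resp_path, sep="\t", index=False)
    paths = {"trials": str(ev_path), "responses": str(resp_path)}
    if sess.eye is not None:
        eye_path = sdir / f"{tag}_eye.tsv"
        write_eye_samples(sess.eye, eye_path,
                          meta={"subject": sess.subject_id, "phase": tag,
                                "group": sess.group,
                                "master_seed": cfg.master_seed,
                                "gain": f"{sess.gain:.6f}"})
        paths["eye"] = str(eye_path)
    return paths
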