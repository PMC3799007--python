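"""Adaptive processing-speed-training staircase.

Training starts every block at Task 1 with a 200-ms stimulus.  Every fourth
trial a performance check counts the central and (for levels >= 2)
peripheral responses of the preceding four trials independently:

* windowed accuracy strictly above 75%  -> harder (shorter duration; if
  already at the shortest duration, advance a task level, except at Task 4
  which saturates),
* strictly below 37.5%                  -> easier (longer duration; if at
  the longest, drop a task level, except at Task 1),
* otherwise                             -> unchanged.

A task-level transition preserves the current duration; duration and level
never both move in the same check.  The window counters reset after every
check, so consecutive checks use disjoint 4-trial windows.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Optional

import numpy as np

from .paradigm import TrialSpec, assign_stimuli, distractor_for_level

if TYPE_CHECKING:  # pragma: no cover
    from .observer import ObserverParams

#: Permissible stimulus durations, easiest (longest) first.
DEFAULT_LADDER_MS = (306.0, 259.0, 200.0, 153.0, 106.0, 82.0, 59.0, 35.0, 24.0)

UP_THRESHOLD_PCT = 75.0
DOWN_THRESHOLD_PCT = 37.5
CHECK_EVERY = 4
START_LEVEL = 1
START_DURATION_MS = 200.0


@dataclass(frozen=True)
class DurationLadder:
    durations_ms: tuple[float, ...] = DEFAULT_LADDER_MS

    def __post_init__(self) -> None:
        d = self.durations_ms
        if len(d) < 1 or any(b >= a for a, b in zip(d, d[1:])):
            raise ValueError("duration ladder must be strictly decreasing")

    def index_of(self, duration_ms: float) -> int:
        try:
            return self.durations_ms.index(float(duration_ms))
        except ValueError:
            raise ValueError(f"{duration_ms} ms is not on the ladder") from None

    def __len__(self) -> int:
        return len(self.durations_ms)


class CheckDecision(str, enum.Enum):
    HARDER = "harder"
    EASIER = "easier"
    SAME = "same"


@dataclass(frozen=True)
class StaircaseState:
    """Current difficulty plus the rolling 4-trial response window."""

    level: int = START_LEVEL
    ladder_index: int = 2  # 200 ms on the default ladder
    trials_since_check: int = 0
    window_correct: int = 0
    window_total: int = 0

    def duration_ms(self, ladder: DurationLadder) -> float:
        return ladder.durations_ms[self.ladder_index]


def initial_state(ladder: DurationLadder = DurationLadder(),
                  start_level: int = START_LEVEL,
                  start_duration_ms: float = START_DURATION_MS) -> StaircaseState:
    return StaircaseState(level=start_level,
                          ladder_index=ladder.index_of(start_duration_ms))


def responses_per_trial(level: int) -> int:
    """1 response at Task 1 (central only), 2 at Tasks 2-4 (central and
    peripheral counted independently)."""
    if level not in (1, 2, 3, 4):
        raise ValueError(f"task level must be 1-4, got {level!r}")
    return 1 if level == 1 else 2


def window_accuracy(correct: int, total: int) -> float:
    """Windowed accuracy in percent (e.g. 6 of 8 -> 75.0)."""
    if total <= 0:
        raise ValueError("window must contain at least one response")
    if not (0 <= correct <= total):
        raise ValueError(f"correct must be in [0, {total}], got {correct}")
    return 100.0 * correct / total


def evaluate_window(correct: int, total: int,
                    up_threshold_pct: float = UP_THRESHOLD_PCT,
                    down_threshold_pct: float = DOWN_THRESHOLD_PCT) -> CheckDecision:
    """Map windowed accuracy to a difficulty decision.

    Thresholds are strict: exactly 75% (6 of 8) or exactly 37.5% (3 of 8)
    leave the task unchanged.
    """
    acc = window_accuracy(correct, total)
    if acc > up_threshold_pct:
        return CheckDecision.HARDER
    if acc < down_threshold_pct:
        return CheckDecision.EASIER
    return CheckDecision.SAME


def apply_decision(state: StaircaseState, decision: CheckDecision,
                   ladder: DurationLadder = DurationLadder()) -> StaircaseState:
    """Apply one check decision, saturating at both extremes.

    Harder at the shortest duration advances the task level (duration
    stays at the minimum) except at Task 4; easier at the longest duration
    drops the level except at Task 1.  Window counters always reset.
    """
    level, idx = state.level, state.ladder_index
    if decision is CheckDecision.HARDER:
        if idx < len(ladder) - 1:
            idx += 1
        elif level < 4:
            level += 1
    elif decision is CheckDecision.EASIER:
        if idx > 0:
            idx -= 1
        elif level > 1:
            level -= 1
    return StaircaseState(level=level, ladder_index=idx,
                          trials_since_check=0, window_correct=0, window_total=0)


@dataclass(frozen=True)
class TrainingTrialRecord:
    """One row of a training trace: the trial as presented, the simulated
    responses, and the post-check staircase state."""

    trial_index: int
    spec: TrialSpec
    central_correct: bool
    peripheral_correct: Optional[bool]
    rt_s: float
    check_performed: bool
    decision: Optional[CheckDecision]
    post_state: StaircaseState


def record_trial(state: StaircaseState, central_correct: bool,
                 peripheral_correct: Optional[bool],
                 ladder: DurationLadder = DurationLadder(),
                 check_every: int = CHECK_EVERY,
                 up_threshold_pct: float = UP_THRESHOLD_PCT,
                 down_threshold_pct: float = DOWN_THRESHOLD_PCT,
                 ) -> tuple[StaircaseState, bool, Optional[CheckDecision]]:
    """Fold one trial's responses into the state; run a check if due.

    Returns ``(new_state, check_performed, decision)``.
    """
    n_resp = responses_per_trial(state.level)
    if (peripheral_correct is None) != (n_resp == 1):
        raise ValueError("peripheral response must be present iff level >= 2")
    correct = int(central_correct) + (int(peripheral_correct) if n_resp == 2 else 0)
    state = replace(state,
                    trials_since_check=state.trials_since_check + 1,
                    window_correct=state.window_correct + correct,
                    window_total=state.window_total + n_resp)
    if state.trials_since_check < check_every:
        return state, False, None
    decision = evaluate_window(state.window_correct, state.window_total,
                               up_threshold_pct, down_threshold_pct)
    return apply_decision(state, decision, ladder), True, decision


def run_training_block(observer: "ObserverParams", n_trials: int,
                       seed: int | np.random.Generator,
                       *, ladder: DurationLadder = DurationLadder(),
                       check_every: int = CHECK_EVERY,
                       start_level: int = START_LEVEL,
                       start_duration_ms: float = START_DURATION_MS,
                       up_threshold_pct: float = UP_THRESHOLD_PCT,
                       down_threshold_pct: float = DOWN_THRESHOLD_PCT,
                       trained: bool = False,
                       n_locations: int = 8) -> list[TrainingTrialRecord]:
    """Simulate one adaptive training block of ``n_trials`` trials.

    Trials are generated on the fly from the current staircase state; the
    observer model supplies responses.  Bit-reproducible for a fixed seed.
    """
    from .observer import simulate_response  # local import to avoid a cycle

    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = initial_state(ladder, start_level, start_duration_ms)
    trace: list[TrainingTrialRecord] = []
    for i in range(n_trials):
        identity, location = assign_stimuli(state.level, rng, n_locations)
        spec = TrialSpec(trial_index=i, phase="training", task_level=state.level,
                         stimulus_duration_ms=state.duration_ms(ladder),
                         central_identity=identity, peripheral_location=location,
                         distractor_kind=distractor_for_level(state.level))
        resp = simulate_response(spec, observer, trained=trained, rng=rng)
        state, checked, decision = record_trial(
            state, resp.central_correct, resp.peripheral_correct, ladder,
            check_every, up_threshold_pct, down_threshold_pct)
        trace.append(TrainingTrialRecord(
            trial_index=i, spec=spec, central_correct=resp.central_correct,
            peripheral_correct=resp.peripheral_correct, rt_s=resp.rt_s,
            check_performed=checked, decision=decision, post_state=state))
    return trace


def trace_to_frame(trace: list[TrainingTrialRecord],
                   ladder: DurationLadder = DurationLadder()):
    """Training trace as a tidy table (one row per trial)."""
    import pandas as pd

    rows = []
    for r in trace:
        rows.append({
            "trial_index": r.trial_index,
            "level": r.spec.task_level,
            "duration_ms": r.spec.stimulus_duration_ms,
            "central_correct": int(r.central_correct),
            "peripheral_correct": ("" if r.peripheral_correct is None
                                   else int(r.peripheral_correct)),
            "check_performed": int(r.check_performed),
            "decision": r.decision.value if r.decision else "",
            "post_level": r.post_state.level,
            "post_duration_ms": r.post_state.duration_ms(ladder),
        })
    return pd.DataFrame(rows)
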