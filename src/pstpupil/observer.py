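"""Psychometric simulated observer for the UFOV paradigm.

Per-response accuracy follows a logistic psychometric function of
log stimulus duration with a guessing floor and a lapse-limited ceiling:

    p(d) = g + (1 - g - lambda) * logistic(beta * (log d - log theta_level))

where g is the guessing floor (0.5 for the 2AFC central car/truck
identification, 1/8 for the 8-location peripheral localization), lambda
the lapse rate, beta the slope on log-duration, and theta_level the
level-specific threshold (duration at which p is midway between floor and
ceiling).  Training multiplies thresholds by ``training_shift`` <= 1.

Default thresholds are calibrated so that a 200-ms stimulus yields
whole-session accuracies in the low-to-high 80s percent across levels,
matching the high pre-training performance typical of young adults on
this task.  Response times are a convenience model (truncated normal)
centred near 1 s, since only mean RT is analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .paradigm import TrialSpec

DEFAULT_THRESHOLDS_MS: Mapping[int, float] = {1: 15.0, 2: 20.0, 3: 24.0, 4: 30.0}

GUESS_FLOOR_CENTRAL = 0.5      # 2AFC car vs truck
GUESS_FLOOR_PERIPHERAL = 0.125  # 8 candidate locations


@dataclass(frozen=True)
class ObserverParams:
    threshold_ms: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS_MS))
    slope: float = 3.0
    lapse_rate: float = 0.10
    guess_floor_central: float = GUESS_FLOOR_CENTRAL
    guess_floor_peripheral: float = GUESS_FLOOR_PERIPHERAL
    training_shift: float = 0.7
    rt_mean_s: float = 0.95
    rt_sd_s: float = 0.25
    rt_min_s: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.lapse_rate < 0.5):
            raise ValueError(f"lapse rate must be in [0, 0.5), got {self.lapse_rate!r}")
        for g in (self.guess_floor_central, self.guess_floor_peripheral):
            if not (0 <= g < 1 - self.lapse_rate):
                raise ValueError("guess floor must satisfy 0 <= g < 1 - lapse_rate")
        if not (0 < self.training_shift <= 1):
            raise ValueError(f"training shift must be in (0, 1], got {self.training_shift!r}")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        for lv in (1, 2, 3, 4):
            if lv not in self.threshold_ms or not (self.threshold_ms[lv] > 0):
                raise ValueError("threshold_ms must map levels 1-4 to positive durations")
        if self.rt_mean_s <= 0 or self.rt_sd_s <= 0 or self.rt_min_s < 0:
            raise ValueError("rt parameters must be positive")

    def guess_floor(self, response_kind: str) -> float:
        if response_kind == "central":
            return self.guess_floor_central
        if response_kind == "peripheral":
            return self.guess_floor_peripheral
        raise ValueError(f"response kind must be central/peripheral, got {response_kind!r}")


def p_correct(duration_ms: float, level: int, response_kind: str,
              observer: ObserverParams, trained: bool = False) -> float:
    """Probability of a correct response of the given kind.

    Monotone non-decreasing in duration; tends to the guess floor as
    d -> 0 and to 1 - lapse_rate as d -> infinity.
    """
    if level not in (1, 2, 3, 4):
        raise ValueError(f"task level must be 1-4, got {level!r}")
    if not (duration_ms > 0):
        raise ValueError(f"duration must be positive, got {duration_ms!r}")
    g = observer.guess_floor(response_kind)
    shift = observer.training_shift if trained else 1.0
    theta = observer.threshold_ms[level] * shift
    z = observer.slope * (np.log(duration_ms) - np.log(theta))
    logistic = 1.0 / (1.0 + np.exp(-z))
    return float(g + (1.0 - g - observer.lapse_rate) * logistic)


@dataclass(frozen=True)
class ResponseRecord:
    central_correct: bool
    peripheral_correct: Optional[bool]  # None at level 1
    rt_s: float


def _truncated_normal(mean: float, sd: float, lo: float,
                      rng: np.random.Generator) -> float:
    # rejection sampling; the truncation point is far in the lower tail for
    # the default parameters so this almost never iterates
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lo:
            return float(x)
    return lo


def simulate_response(spec: TrialSpec, observer: ObserverParams,
                      trained: bool = False,
                      rng: np.random.Generator | None = None) -> ResponseRecord:
    """Draw one trial's dual responses and response time.

    Central and peripheral responses are independent Bernoulli draws with
    their own psychometric probabilities; the peripheral field is absent
    at level 1.
    """
    if rng is None:
        rng = np.random.default_rng()
    d, lv = spec.stimulus_duration_ms, spec.task_level
    central = bool(rng.random() < p_correct(d, lv, "central", observer, trained))
    peripheral = None
    if lv >= 2:
        peripheral = bool(rng.random() < p_correct(d, lv, "peripheral", observer, trained))
    rt = _truncated_normal(observer.rt_mean_s, observer.rt_sd_s, observer.rt_min_s, rng)
    return ResponseRecord(central_correct=central, peripheral_correct=peripheral, rt_s=rt)
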