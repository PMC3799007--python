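"""Trial structure of the modified useful-field-of-view (UFOV) test.

The test presents a central car/truck identification target and, at task
levels 2-4, a simultaneous peripheral localization target at one of eight
equally spaced locations 5.7 degrees from fixation.  Level 3 adds easily
rejected triangle distractors; level 4 adds target-like distractors.  Each
trial runs cue (fixation cross, 506 ms) -> stimulus (variable duration) ->
white-noise mask (1000 ms) -> unspeeded memory probe.

During test phases the stimulus duration is fixed at 200 ms and the task
level is incremented every ``set_size`` trials, cycling 1, 2, 3, 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CUE_MS = 506
MASK_MS = 1000
TEST_DURATION_MS = 200
N_LOCATIONS = 8
ECCENTRICITY_DEG = 5.7

#: distractor kind implied by each task level
DISTRACTOR_BY_LEVEL = {1: "none", 2: "none", 3: "triangle", 4: "target_like"}

VALID_IDENTITIES = ("car", "truck")
VALID_PHASES = ("baseline", "training", "posttest")


def distractor_for_level(level: int) -> str:
    if level not in DISTRACTOR_BY_LEVEL:
        raise ValueError(f"task level must be 1-4, got {level!r}")
    return DISTRACTOR_BY_LEVEL[level]


@dataclass(frozen=True)
class TrialSpec:
    """Condition of a single trial.

    ``peripheral_location`` is an index into the peripheral layout and is
    ``None`` exactly when ``task_level == 1`` (no peripheral target).
    """

    trial_index: int
    phase: str
    task_level: int
    stimulus_duration_ms: float
    central_identity: str
    peripheral_location: Optional[int] = None
    distractor_kind: str = "none"

    def __post_init__(self) -> None:
        if self.phase not in VALID_PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.task_level not in (1, 2, 3, 4):
            raise ValueError(f"task level must be 1-4, got {self.task_level!r}")
        if not (self.stimulus_duration_ms > 0):
            raise ValueError(
                f"stimulus duration must be positive, got {self.stimulus_duration_ms!r}"
            )
        if self.central_identity not in VALID_IDENTITIES:
            raise ValueError(f"central identity must be car/truck, got {self.central_identity!r}")
        if (self.peripheral_location is None) != (self.task_level == 1):
            raise ValueError("peripheral location must be present iff task level >= 2")
        if self.peripheral_location is not None and not (0 <= self.peripheral_location):
            raise ValueError("peripheral location must be a non-negative index")
        expected = distractor_for_level(self.task_level)
        if self.distractor_kind != expected:
            raise ValueError(
                f"task level {self.task_level} implies distractor {expected!r}, "
                f"got {self.distractor_kind!r}"
            )


@dataclass(frozen=True)
class TrialTimeline:
    """Segment boundaries of one trial, in ms relative to cue onset.

    Segments are half-open ``[onset, offset)`` and contiguous; the probe is
    open-ended (``offset`` is ``None``) because responses are unspeeded.
    """

    cue_on_ms: float
    stim_on_ms: float
    mask_on_ms: float
    probe_on_ms: float

    @property
    def segments(self) -> list[tuple[str, float, Optional[float]]]:
        return [
            ("cue", self.cue_on_ms, self.stim_on_ms),
            ("stimulus", self.stim_on_ms, self.mask_on_ms),
            ("mask", self.mask_on_ms, self.probe_on_ms),
            ("probe", self.probe_on_ms, None),
        ]

    @property
    def stimulus_duration_ms(self) -> float:
        return self.mask_on_ms - self.stim_on_ms


def trial_timeline(spec: TrialSpec | float, *, cue_ms: float = CUE_MS,
                   mask_ms: float = MASK_MS) -> TrialTimeline:
    """Timeline for one trial: cue, stimulus, mask, probe onset.

    Accepts either a :class:`TrialSpec` or a bare stimulus duration in ms.
    """
    d = spec.stimulus_duration_ms if isinstance(spec, TrialSpec) else float(spec)
    if not (d > 0):
        raise ValueError(f"stimulus duration must be positive, got {d!r}")
    return TrialTimeline(
        cue_on_ms=0.0,
        stim_on_ms=float(cue_ms),
        mask_on_ms=float(cue_ms) + d,
        probe_on_ms=float(cue_ms) + d + float(mask_ms),
    )


@dataclass(frozen=True)
class LayoutSpec:
    """Peripheral stimulus geometry: n equally spaced locations on a circle.

    Location 0 sits at 12 o'clock and indices run clockwise (an arbitrary
    but fixed convention; the study never renders stimuli, so the layout is
    abstract geometry in degrees of visual angle).
    """

    n_locations: int
    eccentricity_deg: float
    angles_rad: tuple[float, ...] = field(default=())

    def xy_deg(self, location: int) -> tuple[float, float]:
        a = self.angles_rad[location]
        return (self.eccentricity_deg * math.cos(a), self.eccentricity_deg * math.sin(a))


def peripheral_layout(n_locations: int = N_LOCATIONS,
                      eccentricity_deg: float = ECCENTRICITY_DEG) -> LayoutSpec:
    if n_locations < 1:
        raise ValueError(f"n_locations must be >= 1, got {n_locations!r}")
    if not (eccentricity_deg > 0):
        raise ValueError(f"eccentricity must be positive, got {eccentricity_deg!r}")
    # 12 o'clock = pi/2; clockwise = decreasing angle
    angles = tuple((math.pi / 2 - 2 * math.pi * k / n_locations) % (2 * math.pi)
                   for k in range(n_locations))
    return LayoutSpec(n_locations=n_locations, eccentricity_deg=eccentricity_deg,
                      angles_rad=angles)


def assign_stimuli(level: int, rng: np.random.Generator,
                   n_locations: int = N_LOCATIONS) -> tuple[str, Optional[int]]:
    """Draw one trial's central identity and peripheral location.

    Identity is Bernoulli(0.5) car/truck; the location is uniform over the
    layout for levels >= 2 and absent for level 1.
    """
    if level not in (1, 2, 3, 4):
        raise ValueError(f"task level must be 1-4, got {level!r}")
    identity = VALID_IDENTITIES[int(rng.integers(0, 2))]
    location = None if level == 1 else int(rng.integers(0, n_locations))
    return identity, location


def _balanced_identities(n: int, rng: np.random.Generator) -> list[str]:
    # exactly floor(n/2) cars; any odd remainder assigned at random
    half = n // 2
    ids = ["car"] * half + ["truck"] * half
    if n % 2:
        ids.append(VALID_IDENTITIES[int(rng.integers(0, 2))])
    perm = rng.permutation(n)
    return [ids[i] for i in perm]


def build_test_schedule(n_sets: int, set_size: int, seed: int | np.random.Generator,
                        *, phase: str = "baseline",
                        duration_ms: float = TEST_DURATION_MS,
                        n_locations: int = N_LOCATIONS) -> list[TrialSpec]:
    """Fixed test-phase schedule: ``n_sets`` cycles of ``set_size``-trial
    blocks at levels 1, 2, 3, 4 in order, all at ``duration_ms``.

    Central identities are exactly balanced within each level block (seeded
    shuffle); peripheral locations are uniform for levels >= 2.  With the
    study configuration (5 sets of 25) this yields the 500-trial test.
    """
    if n_sets < 1 or set_size < 1:
        raise ValueError(f"n_sets and set_size must be >= 1, got {n_sets}, {set_size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    idx = 0
    for _ in range(n_sets):
        for level in (1, 2, 3, 4):
            identities = _balanced_identities(set_size, rng)
            for identity in identities:
                location = None if level == 1 else int(rng.integers(0, n_locations))
                trials.append(TrialSpec(
                    trial_index=idx, phase=phase, task_level=level,
                    stimulus_duration_ms=float(duration_ms),
                    central_identity=identity, peripheral_location=location,
                    distractor_kind=distractor_for_level(level)))
                idx += 1
    return trials
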