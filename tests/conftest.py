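import dataclasses

import numpy as np
import pytest

from pstpupil import ObserverParams, PupilGenParams, StudyConfig
from pstpupil.study import PupilStudyConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def perfect_observer():
    """Responds correctly on every trial (psychometric ceiling, no lapses)."""
    return ObserverParams(threshold_ms={1: 1e-6, 2: 1e-6, 3: 1e-6, 4: 1e-6},
                          slope=5.0, lapse_rate=0.0)


@pytest.fixture
def hopeless_observer():
    """Responds incorrectly on every trial (floor, zero guessing)."""
    return ObserverParams(threshold_ms={1: 1e9, 2: 1e9, 3: 1e9, 4: 1e9},
                          slope=5.0, lapse_rate=0.0,
                          guess_floor_central=0.0, guess_floor_peripheral=0.0)


@pytest.fixture
def clean_pupil():
    """Noise-free, blink-free stream generator with unit gain."""
    return PupilGenParams(sample_noise_au=0.0, blink_rate_hz=0.0,
                          saccade_rate_hz=0.0, fixation_jitter_deg=0.0,
                          gain_jitter_pct=0.0)


def small_study_config(**overrides) -> StudyConfig:
    """A scaled-down study used where full problem sizes are unnecessary."""
    defaults = dict(n_per_group=2, n_sets=1, set_size=4,
                    n_training_days=2, blocks_per_day=2, trials_per_block=40)
    defaults.update(overrides)
    return StudyConfig(**defaults)


def clean_study_config(amplitudes, **overrides) -> StudyConfig:
    """Scaled study with all stochastic nuisance terms disabled and a
    given injected amplitude map (exact-recovery conditions)."""
    gen = PupilGenParams(sample_noise_au=0.0, blink_rate_hz=0.0,
                         gain_jitter_pct=0.0)
    pup = PupilStudyConfig(gen=gen, amplitudes_pre=dict(amplitudes),
                           amplitudes_post_trained=dict(amplitudes),
                           subject_amp_sd_pct=0.0, session_amp_sd_pct=0.0)
    return dataclasses.replace(small_study_config(**overrides), pupil=pup)
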