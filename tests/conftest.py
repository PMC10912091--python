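import dataclasses

import numpy as np
import pytest

from adspect.containers import EpochSet
from adspect.pipeline import default_bank, extract_cohort_features
from adspect.synth import CohortSpec, EffectSpec, NoiseSpec, generate_cohort

TINY_GROUPS = {"SCD": 2, "naMCI": 2, "aMCI": 2, "AD": 2}


def tiny_spec(**overrides) -> CohortSpec:
    """A miniature cohort cheap enough for unit tests: 8 subjects at 128 Hz."""
    base = dict(
        group_sizes=dict(TINY_GROUPS),
        sampling_rate=128.0,
        n_sessions=2,
        trials_per_session=4,
        resting_duration=10.0,
        seed=42,
    )
    base.update(overrides)
    return CohortSpec(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(tiny_spec())


@pytest.fixture(scope="session")
def tiny_tables(tiny_cohort):
    return extract_cohort_features(
        tiny_cohort, states=("resting", "enc1", "enc2"), n_freqs=8
    )


@pytest.fixture
def small_bank():
    return default_bank(128.0, n_freqs=8)


def sinusoid_epochs(
    freq_hz: float,
    fs: float = 128.0,
    n_trials: int = 1,
    amplitude: float = 1.0,
    phases=None,
    tmin_ms: float = -500.0,
    duration_s: float = 2.5,
    n_channels: int = 1,
) -> EpochSet:
    """Stimulus-locked sinusoid trials, optionally with per-trial phases."""
    n = int(round(duration_s * fs))
    times = tmin_ms + np.arange(n) * 1000.0 / fs
    t = np.arange(n) / fs
    if phases is None:
        phases = np.zeros(n_trials)
    data = np.stack(
        [
            np.tile(amplitude * np.sin(2 * np.pi * freq_hz * t + ph), (n_channels, 1))
            for ph in phases
        ]
    )
    names = tuple(f"ch{i}" for i in range(n_channels))
    return EpochSet(data, times, fs, names)


def one_effect_spec(effect: EffectSpec, **overrides) -> CohortSpec:
    """Noise-free single-effect spec for exact-realization checks."""
    base = dict(
        group_sizes={"SCD": 1},
        sampling_rate=128.0,
        n_sessions=1,
        trials_per_session=4,
        resting_duration=6.0,
        effects=[effect],
        noise=NoiseSpec(alpha=1.0, rms=0.0),
        subject_sigma=0.0,
        seed=7,
    )
    base.update(overrides)
    return CohortSpec(**base)


def replace(spec: CohortSpec, **kw) -> CohortSpec:
    return dataclasses.replace(spec, **kw)
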