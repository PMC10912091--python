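"""In-memory containers for continuous EEG, stimulus-locked epochs, and TF power."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError


@dataclass
class ContinuousRecording:
    """Channels x samples EEG in microvolts with a sampling rate and channel names."""

    data: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ParameterError("continuous data must be 2-D (channels x samples)")
        if self.data.shape[1] < 1:
            raise ParameterError("recording must contain at least one sample")
        if len(self.channel_names) != self.data.shape[0]:
            raise ParameterError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if self.sampling_rate <= 0:
            raise ParameterError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class EpochSet:
    """Trials x channels x samples stimulus-locked data with a ms time axis.

    ``times`` is relative to stimulus onset; the canonical encoding window is
    [-500, 2000) ms. ``baseline_window`` records the window already used for
    baseline correction (None if uncorrected, as for resting pseudo-trials).
    """

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...]
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 3:
            raise ParameterError("epoch data must be 3-D (trials x channels x samples)")
        if self.times.shape != (self.data.shape[2],):
            raise ParameterError("time axis length must match the sample dimension")
        if len(self.channel_names) != self.data.shape[1]:
            raise ParameterError("channel names must match the channel dimension")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling rate must be positive")
        step = 1000.0 / self.sampling_rate
        if self.times.size > 1:
            diffs = np.diff(self.times)
            if not np.allclose(diffs, step, rtol=1e-9, atol=1e-9):
                raise ParameterError("time axis must be uniform with step 1000/fs ms")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class TFPower:
    """Activity-tagged channels x frequencies x times power array (µV²)."""

    activity: str
    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.activity not in ("total", "evoked", "induced"):
            raise ParameterError(f"unknown activity {self.activity!r}")
        if self.power.ndim != 3:
            raise ParameterError("power must be 3-D (channels x freqs x times)")
        if self.power.shape[1] != self.freqs.size or self.power.shape[2] != self.times.size:
            raise ParameterError("power dimensions must match freq/time axes")


@dataclass
class SubjectRecord:
    """One subject: diagnostic label, resting recording, and encoding sessions."""

    subject_id: str
    group: str
    resting: ContinuousRecording
    sessions: list[EpochSet] = field(default_factory=list)
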