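"""Synthetic EEG cohort generator for the AD-spectrum pipeline.

Emulates the study conditions the analysis assumes: four diagnostic groups
(20 SCD / 10 naMCI / 18 aMCI / 10 AD), per subject a 3-min eyes-open resting
recording and three stimulus-locked encoding sessions of nine 2.5-s trials
(-500..2000 ms around word onset) at 512 Hz on a 36-electrode montage.

Group structure is injected through :class:`EffectSpec` entries: *evoked*
effects are fixed-latency Hanning-windowed oscillations identical in phase
across trials; *induced* effects carry a fresh uniform random phase per trial;
both are scaled by a per-group gain and an independent log-normal per-subject
jitter. The background is 1/f Gaussian noise, independent across channels and
subjects. All randomness flows from a single seed through a documented
``SeedSequence`` splitting scheme (subject index, then stream, then session).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .containers import ContinuousRecording, EpochSet, SubjectRecord
from .errors import SpecificationError
from .schemes import BANDS, CLASS_ORDER, MONTAGE, REGIONS, band_center

DEFAULT_GROUP_SIZES: dict[str, int] = {"SCD": 20, "naMCI": 10, "aMCI": 18, "AD": 10}


@dataclass(frozen=True)
class EffectSpec:
    """A group-dependent spectral effect injected into one region/band/window.

    ``per_group_gain`` multiplies ``amplitude`` (µV); ``state`` selects which
    recordings receive the effect — resting recordings accept induced effects
    only, realized as a continuous oscillation with a random per-subject phase.
    """

    kind: str                        # 'evoked' | 'induced'
    band: str                        # one of the six bands
    region: str                      # one of the seven region codes
    window: tuple[float, float]      # (start_ms, end_ms) within the trial
    per_group_gain: dict[str, float]
    amplitude: float = 5.0           # base amplitude, µV
    state: str = "encoding"          # 'encoding' | 'resting'

    def validate(self, trial_window_ms: tuple[float, float]) -> None:
        if self.kind not in ("evoked", "induced"):
            raise SpecificationError(f"unknown effect kind {self.kind!r}")
        if self.band not in BANDS:
            raise SpecificationError(f"unknown band {self.band!r}")
        if self.region not in REGIONS:
            raise SpecificationError(f"unknown region {self.region!r}")
        if self.state not in ("encoding", "resting"):
            raise SpecificationError(f"unknown effect state {self.state!r}")
        if self.state == "resting" and self.kind != "induced":
            raise SpecificationError("resting effects must be induced (no event to lock to)")
        lo, hi = self.window
        if self.state == "encoding" and not (
            trial_window_ms[0] <= lo < hi <= trial_window_ms[1]
        ):
            raise SpecificationError(
                f"effect window {self.window} outside trial window {trial_window_ms}"
            )
        for group, gain in self.per_group_gain.items():
            if group not in CLASS_ORDER:
                raise SpecificationError(f"unknown group label {group!r}")
            if gain <= 0:
                raise SpecificationError(f"gain for {group} must be > 0, got {gain}")
        if self.amplitude < 0:
            raise SpecificationError("effect amplitude must be >= 0")


def default_effects() -> list[EffectSpec]:
    """Default group-separability structure.

    Encoding carries the stronger, task-locked effects (a graded decline of
    the frontal evoked theta response, an amnestic drop of induced posterior
    alpha, and a naMCI/aMCI 'compensatory' right-temporal beta2 increase);
    resting carries only the classic slowing signature — posterior alpha
    decreasing and frontal theta increasing with disease severity — with a
    deliberately smaller gain spread. Gains are free parameters of the
    artifact, not estimates of real data.
    """
    return [
        EffectSpec(
            "evoked", "theta", "FM", (0.0, 400.0),
            {"SCD": 1.8, "naMCI": 1.4, "aMCI": 1.0, "AD": 0.6}, amplitude=6.0,
        ),
        EffectSpec(
            "induced", "alpha", "PM", (400.0, 1200.0),
            {"SCD": 1.6, "naMCI": 1.4, "aMCI": 1.0, "AD": 0.7}, amplitude=6.0,
        ),
        EffectSpec(
            "induced", "beta2", "RT", (600.0, 1400.0),
            {"SCD": 1.0, "naMCI": 1.7, "aMCI": 1.3, "AD": 0.8}, amplitude=5.0,
        ),
        EffectSpec(
            "induced", "alpha", "PM", (0.0, 2000.0),
            {"SCD": 1.3, "naMCI": 1.15, "aMCI": 1.0, "AD": 0.85},
            amplitude=4.0, state="resting",
        ),
        EffectSpec(
            "induced", "theta", "FM", (0.0, 2000.0),
            {"SCD": 0.85, "naMCI": 1.0, "aMCI": 1.15, "AD": 1.3},
            amplitude=4.0, state="resting",
        ),
    ]


@dataclass
class NoiseSpec:
    """1/f^alpha Gaussian background noise; ``rms`` is the per-channel RMS in µV."""

    alpha: float = 1.0
    rms: float = 12.0


@dataclass
class CohortSpec:
    """Full specification of a synthetic cohort."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    sampling_rate: float = 512.0
    montage: tuple[str, ...] = MONTAGE
    n_sessions: int = 3
    trials_per_session: int = 9
    resting_duration: float = 180.0
    trial_window: tuple[float, float] = (-0.5, 2.0)
    effects: list[EffectSpec] = field(default_factory=default_effects)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    subject_sigma: float = 0.15   # log-normal sigma of per-subject, per-effect gain jitter
    seed: int = 0

    def validate(self) -> None:
        for group, count in self.group_sizes.items():
            if group not in CLASS_ORDER:
                raise SpecificationError(f"unknown group label {group!r}")
            if count < 0:
                raise SpecificationError(f"group size for {group} must be >= 0")
        if self.sampling_rate <= 0:
            raise SpecificationError("sampling rate must be positive")
        if len(set(self.montage)) != len(self.montage):
            raise SpecificationError("montage electrode names must be unique")
        if self.n_sessions <= 0 or self.trials_per_session <= 0:
            raise SpecificationError("session and trial counts must be positive")
        if self.resting_duration <= 0:
            raise SpecificationError("resting duration must be positive")
        tmin, tmax = self.trial_window
        if not (tmin < 0 < tmax):
            raise SpecificationError("trial window must satisfy start < 0 < end")
        if self.noise.rms < 0 or self.subject_sigma < 0:
            raise SpecificationError("noise rms and subject_sigma must be >= 0")
        window_ms = (tmin * 1000.0, tmax * 1000.0)
        for eff in self.effects:
            eff.validate(window_ms)

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    @property
    def trial_times_ms(self) -> np.ndarray:
        tmin, tmax = self.trial_window
        n = int(round((tmax - tmin) * self.sampling_rate))
        return tmin * 1000.0 + np.arange(n) * 1000.0 / self.sampling_rate


# --- noise and component synthesis -------------------------------------------


def one_over_f_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    sampling_rate: float,
    alpha: float = 1.0,
    rms: float = 1.0,
) -> np.ndarray:
    """1/f^alpha Gaussian noise synthesized in the frequency domain.

    Amplitude spectrum proportional to f^(-alpha/2) (power ~ 1/f^alpha), zero
    DC, each channel rescaled to the target RMS.
    """
    if rms == 0 or n_samples < 2:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sampling_rate)
    weights = np.zeros_like(freqs)
    weights[1:] = freqs[1:] ** (-alpha / 2.0)
    spectrum = weights * (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    )
    x = np.fft.irfft(spectrum, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x * (rms / std)


def windowed_oscillation(
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
    freq_hz: float,
    phase: float = 0.0,
) -> np.ndarray:
    """Hanning-windowed unit-amplitude sinusoid inside ``window_ms`` ([lo, hi))."""
    lo, hi = window_ms
    mask = (times_ms >= lo) & (times_ms < hi)
    out = np.zeros(times_ms.size)
    n_in = int(mask.sum())
    if n_in == 0:
        return out
    t_rel = (times_ms[mask] - lo) / 1000.0
    out[mask] = np.hanning(n_in) * np.sin(2.0 * np.pi * freq_hz * t_rel + phase)
    return out


# --- cohort generation --------------------------------------------------------


def _subject_gains(eff: EffectSpec, group: str, jitter: float) -> float:
    return eff.per_group_gain.get(group, 1.0) * jitter


def _generate_subject(
    spec: CohortSpec, subject_id: str, group: str, ss: np.random.SeedSequence
) -> SubjectRecord:
    streams = ss.spawn(2 + spec.n_sessions)
    jitter_rng = np.random.default_rng(streams[0])
    rest_rng = np.random.default_rng(streams[1])
    jitters = np.exp(spec.subject_sigma * jitter_rng.standard_normal(len(spec.effects)))

    n_ch = len(spec.montage)
    chan_index = {name: i for i, name in enumerate(spec.montage)}

    # resting: 1/f background plus continuous induced oscillations
    n_rest = int(round(spec.resting_duration * spec.sampling_rate))
    rest = one_over_f_noise(
        rest_rng, n_ch, n_rest, spec.sampling_rate, spec.noise.alpha, spec.noise.rms
    )
    t_rest = np.arange(n_rest) / spec.sampling_rate
    for eff, jit in zip(spec.effects, jitters):
        if eff.state != "resting":
            continue
        gain = _subject_gains(eff, group, jit)
        phase = rest_rng.uniform(0.0, 2.0 * np.pi)
        wave = eff.amplitude * gain * np.sin(
            2.0 * np.pi * band_center(eff.band) * t_rest + phase
        )
        for ch in REGIONS[eff.region]:
            if ch in chan_index:
                rest[chan_index[ch]] += wave
    resting = ContinuousRecording(rest, spec.sampling_rate, spec.montage)

    # encoding sessions: per-trial 1/f noise plus evoked/induced components
    times_ms = spec.trial_times_ms
    n_samp = times_ms.size
    sessions = []
    for k in range(spec.n_sessions):
        rng = np.random.default_rng(streams[2 + k])
        data = one_over_f_noise(
            rng,
            spec.trials_per_session * n_ch,
            n_samp,
            spec.sampling_rate,
            spec.noise.alpha,
            spec.noise.rms,
        ).reshape(spec.trials_per_session, n_ch, n_samp)
        for eff, jit in zip(spec.effects, jitters):
            if eff.state != "encoding":
                continue
            gain = _subject_gains(eff, group, jit)
            fc = band_center(eff.band)
            chans = [chan_index[c] for c in REGIONS[eff.region] if c in chan_index]
            if eff.kind == "evoked":
                wave = eff.amplitude * gain * windowed_oscillation(times_ms, eff.window, fc)
                data[:, chans, :] += wave
            else:
                phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.trials_per_session)
                for t, phase in enumerate(phases):
                    wave = eff.amplitude * gain * windowed_oscillation(
                        times_ms, eff.window, fc, phase
                    )
                    data[t, chans, :] += wave
        sessions.append(
            EpochSet(data, times_ms, spec.sampling_rate, spec.montage, baseline_window=None)
        )
    return SubjectRecord(subject_id, group, resting, sessions)


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate a synthetic cohort; deterministic given ``spec.seed``.

    Subjects are ordered group by group along the clinical ordering
    SCD, naMCI, aMCI, AD and assigned ids ``sub001`` ... ``subNNN``.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    seqs = root.spawn(max(spec.n_subjects, 1))
    cohort: list[SubjectRecord] = []
    idx = 0
    for group in CLASS_ORDER:
        for _ in range(spec.group_sizes.get(group, 0)):
            subject_id = f"sub{idx + 1:03d}"
            cohort.append(_generate_subject(spec, subject_id, group, seqs[idx]))
            idx += 1
    return cohort


def generate_null_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """As :func:`generate_cohort` but with every per-group gain forced to 1.

    Labels are retained, so feature distributions are group-exchangeable:
    a negative control for selection and classification.
    """
    null_effects = [
        dataclasses.replace(eff, per_group_gain={g: 1.0 for g in CLASS_ORDER})
        for eff in spec.effects
    ]
    null_spec = dataclasses.replace(spec, effects=null_effects)
    return generate_cohort(null_spec)


# --- YAML config --------------------------------------------------------------


def spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "group_sizes": dict(spec.group_sizes),
        "sampling_rate": spec.sampling_rate,
        "montage": list(spec.montage),
        "n_sessions": spec.n_sessions,
        "trials_per_session": spec.trials_per_session,
        "resting_duration": spec.resting_duration,
        "trial_window": list(spec.trial_window),
        "effects": [
            {
                "kind": e.kind,
                "band": e.band,
                "region": e.region,
                "window": list(e.window),
                "per_group_gain": dict(e.per_group_gain),
                "amplitude": e.amplitude,
                "state": e.state,
            }
            for e in spec.effects
        ],
        "noise": {"alpha": spec.noise.alpha, "rms": spec.noise.rms},
        "subject_sigma": spec.subject_sigma,
        "seed": spec.seed,
    }


def spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    effects = [
        EffectSpec(
            kind=e["kind"],
            band=e["band"],
            region=e["region"],
            window=tuple(e["window"]),
            per_group_gain=dict(e["per_group_gain"]),
            amplitude=e.get("amplitude", 5.0),
            state=e.get("state", "encoding"),
        )
        for e in d.pop("effects", [])
    ]
    noise = NoiseSpec(**d.pop("noise", {}))
    if "montage" in d:
        d["montage"] = tuple(d["montage"])
    if "trial_window" in d:
        d["trial_window"] = tuple(d["trial_window"])
    return CohortSpec(effects=effects, noise=noise, **d)


def save_spec(spec: CohortSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_spec(path) -> CohortSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
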