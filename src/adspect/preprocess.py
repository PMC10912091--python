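"""Filtering, referencing, epoching, baseline correction, resting segmentation.

All filters are zero-phase (forward-backward) and shape preserving. The
band-pass is a 4th-order Butterworth applied as second-order sections; the
notch is an IIR biquad with Q=30. Epoch windows follow the half-open
convention [tmin, tmax), so a 2.5-s window at 512 Hz has exactly 1280 samples.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import ContinuousRecording, EpochSet
from .errors import EpochingError, ParameterError


def bandpass_filter(
    rec: ContinuousRecording, low_hz: float, high_hz: float, order: int = 4
) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass, applied per channel."""
    nyquist = rec.sampling_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ParameterError(
            f"cutoffs must satisfy 0 < {low_hz} < {high_hz} < Nyquist ({nyquist} Hz)"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.sampling_rate,
                        output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return ContinuousRecording(out, rec.sampling_rate, rec.channel_names)


def notch_filter(
    rec: ContinuousRecording, freq_hz: float = 60.0, quality: float = 30.0
) -> ContinuousRecording:
    """Zero-phase IIR notch (biquad, Q=30) to reject line noise."""
    if not (0.0 < freq_hz < rec.sampling_rate / 2.0):
        raise ParameterError(f"notch frequency {freq_hz} Hz outside (0, Nyquist)")
    b, a = signal.iirnotch(freq_hz, quality, fs=rec.sampling_rate)
    out = signal.filtfilt(b, a, rec.data, axis=1)
    return ContinuousRecording(out, rec.sampling_rate, rec.channel_names)


def average_reference(rec: ContinuousRecording) -> ContinuousRecording:
    """Subtract the instantaneous mean across channels (common average reference)."""
    if rec.n_channels < 2:
        raise ParameterError("average reference requires at least 2 channels")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return ContinuousRecording(out, rec.sampling_rate, rec.channel_names)


def average_reference_epochs(ep: EpochSet) -> EpochSet:
    """Common average reference applied within each trial."""
    if ep.n_channels < 2:
        raise ParameterError("average reference requires at least 2 channels")
    out = ep.data - ep.data.mean(axis=1, keepdims=True)
    return EpochSet(out, ep.times, ep.sampling_rate, ep.channel_names, ep.baseline_window)


def epoch(
    rec: ContinuousRecording,
    onsets: np.ndarray,
    tmin: float = -0.5,
    tmax: float = 2.0,
) -> EpochSet:
    """Cut stimulus-locked trials at the given onset sample indices.

    Each trial covers samples ``[onset + tmin*fs, onset + tmax*fs)``; every
    window must lie inside the recording.
    """
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size == 0:
        raise ParameterError("at least one onset is required")
    fs = rec.sampling_rate
    start_off = int(round(tmin * fs))
    n_samp = int(round((tmax - tmin) * fs))
    trials = []
    for i, onset in enumerate(onsets):
        lo = onset + start_off
        hi = lo + n_samp
        if lo < 0 or hi > rec.n_samples:
            raise EpochingError(
                f"trial {i} window [{lo}, {hi}) outside recording of {rec.n_samples} samples"
            )
        trials.append(rec.data[:, lo:hi])
    times = tmin * 1000.0 + np.arange(n_samp) * 1000.0 / fs
    return EpochSet(np.stack(trials), times, fs, rec.channel_names, baseline_window=None)


def baseline_correct(
    ep: EpochSet, window: tuple[float, float] = (-500.0, 0.0)
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window [lo, hi) ms.

    Idempotent, and commutes with average referencing.
    """
    mask = (ep.times >= window[0]) & (ep.times < window[1])
    if not mask.any():
        raise ParameterError(f"epoch time axis does not cover baseline window {window}")
    baseline = ep.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(
        ep.data - baseline, ep.times, ep.sampling_rate, ep.channel_names,
        baseline_window=window,
    )


def resting_middle_segment(
    rec: ContinuousRecording, keep: float = 120.0
) -> ContinuousRecording:
    """Centered ``keep``-second window of a resting recording.

    A 3-min recording yields the middle 2-min interval, samples [30 s, 150 s).
    """
    n_keep = int(round(keep * rec.sampling_rate))
    if n_keep > rec.n_samples:
        raise ParameterError(
            f"recording of {rec.duration:.1f} s shorter than keep={keep} s"
        )
    start = (rec.n_samples - n_keep) // 2
    return ContinuousRecording(
        rec.data[:, start : start + n_keep], rec.sampling_rate, rec.channel_names
    )


def resting_pseudotrials(rec: ContinuousRecording, length: float = 2.0) -> EpochSet:
    """Cut a continuous resting recording into non-overlapping ``length``-s trials.

    Trials carry a 0..length time axis (ms) and no baseline window; a trailing
    remainder shorter than ``length`` is discarded.
    """
    n_trial = int(round(length * rec.sampling_rate))
    if n_trial < 1 or n_trial > rec.n_samples:
        raise ParameterError(f"recording shorter than pseudo-trial length {length} s")
    n_trials = rec.n_samples // n_trial
    data = rec.data[:, : n_trials * n_trial]
    trials = data.reshape(rec.n_channels, n_trials, n_trial).transpose(1, 0, 2)
    times = np.arange(n_trial) * 1000.0 / rec.sampling_rate
    return EpochSet(trials.copy(), times, rec.sampling_rate, rec.channel_names, None)


# --- real-data ingest ---------------------------------------------------------


def _recording_from_raw(raw, target_rate: float = 512.0) -> ContinuousRecording:
    """Convert an mne Raw object to a ContinuousRecording at ``target_rate`` Hz.

    Channel names are matched case-insensitively against the 36-electrode
    montage; channels outside the montage are kept under their given names.
    Data are converted from volts to microvolts and resampled (polyphase)
    when the native rate differs.
    """
    from .schemes import MONTAGE

    canonical = {name.lower(): name for name in MONTAGE}
    if abs(raw.info["sfreq"] - target_rate) > 1e-9:
        raw = raw.copy().resample(target_rate)
    names = tuple(canonical.get(ch.lower(), ch) for ch in raw.ch_names)
    data = raw.get_data() * 1e6
    return ContinuousRecording(data, target_rate, names)


def read_raw_recording(path, target_rate: float = 512.0) -> ContinuousRecording:
    """Read a continuous EDF or BioSemi BDF file.

    Note: this ingest path performs no artifact correction (no ICA); it is
    intended for clean or pre-cleaned recordings.
    """
    import mne

    path = str(path)
    if path.lower().endswith(".bdf"):
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return _recording_from_raw(raw, target_rate)
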