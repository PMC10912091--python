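"""HDF5 cohort container and NPZ fixtures.

Layout::

    /                      attrs: sampling_rate, montage
    /subjects/<id>         attrs: group
    /subjects/<id>/resting             channels x samples
    /subjects/<id>/session<k>          trials x channels x samples, attr tmin_ms
    /subjects/<id>/tf/<state>/<act>    channels x freqs x times, attrs freqs, times
"""

from __future__ import annotations

import h5py
import numpy as np

from .containers import ContinuousRecording, EpochSet, SubjectRecord, TFPower


def write_cohort(path, cohort: list[SubjectRecord]) -> None:
    with h5py.File(path, "w") as fh:
        if cohort:
            fh.attrs["sampling_rate"] = cohort[0].resting.sampling_rate
            fh.attrs["montage"] = list(cohort[0].resting.channel_names)
        subjects = fh.create_group("subjects")
        for record in cohort:
            grp = subjects.create_group(record.subject_id)
            grp.attrs["group"] = record.group
            grp.create_dataset("resting", data=record.resting.data)
            for k, session in enumerate(record.sessions, start=1):
                ds = grp.create_dataset(f"session{k}", data=session.data)
                ds.attrs["tmin_ms"] = float(session.times[0])


def read_cohort(path) -> list[SubjectRecord]:
    cohort: list[SubjectRecord] = []
    with h5py.File(path, "r") as fh:
        if "subjects" not in fh:
            return cohort
        fs = float(fh.attrs["sampling_rate"])
        montage = tuple(
            name.decode() if isinstance(name, bytes) else str(name)
            for name in fh.attrs["montage"]
        )
        for subject_id in sorted(fh["subjects"]):
            grp = fh["subjects"][subject_id]
            resting = ContinuousRecording(grp["resting"][()], fs, montage)
            sessions = []
            k = 1
            while f"session{k}" in grp:
                data = grp[f"session{k}"][()]
                tmin = float(grp[f"session{k}"].attrs["tmin_ms"])
                times = tmin + np.arange(data.shape[2]) * 1000.0 / fs
                sessions.append(EpochSet(data, times, fs, montage, None))
                k += 1
            cohort.append(SubjectRecord(subject_id, str(grp.attrs["group"]), resting, sessions))
    return cohort


def write_subject_tf(path, subject_id: str, state: str, tfs: dict[str, TFPower]) -> None:
    """Append a subject's TF decomposition to an existing cohort file."""
    with h5py.File(path, "a") as fh:
        base = fh.require_group(f"subjects/{subject_id}/tf/{state}")
        for activity, tf in tfs.items():
            if activity in base:
                del base[activity]
            ds = base.create_dataset(activity, data=tf.power)
            ds.attrs["freqs"] = tf.freqs
            ds.attrs["times"] = tf.times


def save_subject_npz(path, record: SubjectRecord) -> None:
    """Flat NPZ export of one subject (fixture-friendly)."""
    arrays = {
        "resting": record.resting.data,
        "sampling_rate": np.array(record.resting.sampling_rate),
        "montage": np.array(record.resting.channel_names),
        "group": np.array(record.group),
    }
    for k, session in enumerate(record.sessions, start=1):
        arrays[f"session{k}"] = session.data
        arrays[f"session{k}_times"] = session.times
    np.savez_compressed(path, **arrays)
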