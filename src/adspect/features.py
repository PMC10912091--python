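"""Canonical feature assembly: regions x activity x ratio x bands x time epochs.

A subject/state pair yields one feature row ordered by the canonical key order
(region, activity, ratio, band, epoch): 7·3·2·6·9 = 2268 features for the
resting state, 7·3·2·6·11 = 2772 per encoding session. Absolute power (AP) is
mean TF power over a band/window cell; relative power (RP) is each band's
percentage of the six-band AP budget, computed per channel before region
averaging; difference epochs subtract the preceding 400-ms window at region
level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import TFPower
from .errors import (
    AlignmentError,
    DegenerateInputError,
    MappingError,
    ParameterError,
)
from .schemes import (
    ACTIVITIES,
    BAND_ORDER,
    RATIOS,
    REGION_ORDER,
    REGIONS,
    band_mask,
    epoch_scheme,
)


@dataclass(frozen=True, order=True)
class FeatureKey:
    """One feature coordinate; ordered lexicographically in canonical axis order."""

    region: str
    activity: str
    ratio: str
    band: str
    epoch: str

    def __str__(self) -> str:
        return f"{self.region}.{self.activity}.{self.ratio}.{self.band}.{self.epoch}"


def feature_keys(state: str) -> list[FeatureKey]:
    """Canonical ordered key list for a state (2268 resting / 2772 encoding)."""
    scheme = epoch_scheme("resting" if state == "resting" else "encoding")
    return [
        FeatureKey(region, activity, ratio, band, epoch)
        for region in REGION_ORDER
        for activity in ACTIVITIES
        for ratio in RATIOS
        for band in BAND_ORDER
        for epoch in scheme.labels
    ]


# --- elementary operations ----------------------------------------------------


def band_epoch_power(tf: TFPower, band, window: tuple[float, float]) -> np.ndarray:
    """Mean TF power per channel over a band and a [start, end) ms window."""
    if isinstance(band, str):
        fmask = band_mask(tf.freqs, band)
    else:
        lo, hi = band
        fmask = (tf.freqs >= lo) & (tf.freqs < hi)
    tmask = (tf.times >= window[0]) & (tf.times < window[1])
    if not fmask.any() or not tmask.any():
        raise ParameterError(f"empty band/window intersection for {band}, {window}")
    return tf.power[:, fmask][:, :, tmask].mean(axis=(1, 2))


def relative_power(ap_by_band: np.ndarray) -> np.ndarray:
    """Convert per-band absolute power (band axis first) to percentages of the six-band sum."""
    ap = np.asarray(ap_by_band, dtype=float)
    if np.any(ap < 0):
        raise ParameterError("absolute power must be non-negative")
    totals = ap.sum(axis=0, keepdims=True)
    if np.any(totals <= 0):
        raise DegenerateInputError("six-band power sum is zero; relative power undefined")
    return ap / totals * 100.0


def region_average(
    values: np.ndarray, channel_names, regions: dict[str, tuple[str, ...]] = REGIONS
) -> np.ndarray:
    """Average per-channel values (channel axis first) over each region's electrodes."""
    index = {name: i for i, name in enumerate(channel_names)}
    rows = []
    for region, electrodes in regions.items():
        try:
            idx = [index[ch] for ch in electrodes]
        except KeyError as exc:
            raise MappingError(
                f"electrode {exc.args[0]!r} of region {region} missing from channels"
            ) from None
        rows.append(np.asarray(values)[idx].mean(axis=0))
    return np.stack(rows)


def epoch_differences(base_values: np.ndarray) -> np.ndarray:
    """Consecutive differences value(w_i) - value(w_{i-1}) along the last axis."""
    base_values = np.asarray(base_values)
    if base_values.shape[-1] < 2:
        raise ParameterError("difference epochs require at least 2 base windows")
    return base_values[..., 1:] - base_values[..., :-1]


# --- row assembly -------------------------------------------------------------


def assemble_features(
    tfs: dict[str, TFPower], state: str, channel_names
) -> tuple[np.ndarray, list[FeatureKey]]:
    """Assemble one subject/state feature row in canonical key order.

    ``tfs`` must provide TFPower for all three activities on a shared
    time/frequency grid. Per activity: channel-level AP per (band, base
    window), per-channel RP within each window, region averaging of both,
    then difference epochs at region level.
    """
    for activity in ACTIVITIES:
        if activity not in tfs:
            raise ParameterError(f"missing activity {activity!r} in TF set")
    scheme = epoch_scheme("resting" if state == "resting" else "encoding")
    keys = feature_keys(state)

    per_activity: dict[str, dict[str, np.ndarray]] = {}
    for activity in ACTIVITIES:
        tf = tfs[activity]
        n_ch = tf.power.shape[0]
        ap = np.empty((n_ch, len(BAND_ORDER), len(scheme.base)))
        for wi, (_, window) in enumerate(scheme.base):
            for bi, band in enumerate(BAND_ORDER):
                ap[:, bi, wi] = band_epoch_power(tf, band, window)
        try:
            rp = np.moveaxis(relative_power(np.moveaxis(ap, 1, 0)), 0, 1)
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"{activity} activity: {exc}") from None
        reg_ap = region_average(ap, channel_names)
        reg_rp = region_average(rp, channel_names)
        per_activity[activity] = {
            "absolute": np.concatenate([reg_ap, epoch_differences(reg_ap)], axis=-1),
            "relative": np.concatenate([reg_rp, epoch_differences(reg_rp)], axis=-1),
        }

    row = np.empty(len(keys))
    pos = 0
    epoch_index = {label: i for i, label in enumerate(scheme.labels)}
    for ri, _region in enumerate(REGION_ORDER):
        for activity in ACTIVITIES:
            for ratio in RATIOS:
                block = per_activity[activity][ratio]
                for bi, _band in enumerate(BAND_ORDER):
                    for label in scheme.labels:
                        row[pos] = block[ri, bi, epoch_index[label]]
                        pos += 1
    assert pos == len(keys)
    return row, keys


# --- feature tables -----------------------------------------------------------


@dataclass
class FeatureTable:
    """Subjects x features matrix with state-tagged canonical keys and group labels."""

    values: pd.DataFrame          # index: subject ids; columns: '<state>.<key>'
    labels: pd.Series             # group per subject, same index
    state: str                    # 'resting', 'enc1', 'enc2', 'enc3', or 'encoding'

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise AlignmentError("feature values and labels must share the subject index")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ParameterError("feature table contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path, state: str) -> "FeatureTable":
        df = pd.read_csv(path, index_col="subject_id")
        labels = df.pop("label")
        return cls(df, labels, state)


def make_table(
    rows: np.ndarray, keys: list[FeatureKey], subject_ids, labels, state: str
) -> FeatureTable:
    columns = [f"{state}.{key}" for key in keys]
    values = pd.DataFrame(np.asarray(rows), index=list(subject_ids), columns=columns)
    return FeatureTable(values, pd.Series(list(labels), index=list(subject_ids)), state)


def concat_states(tables: list[FeatureTable], state: str = "encoding") -> FeatureTable:
    """Column-wise concatenation of per-state tables over identical subjects."""
    if not tables:
        raise ParameterError("at least one table is required")
    if len(tables) == 1:
        return tables[0]
    first = tables[0]
    for table in tables[1:]:
        if table.subject_ids != first.subject_ids:
            raise AlignmentError("tables must share an identical subject ordering")
        if not table.labels.equals(first.labels):
            raise AlignmentError("tables must share identical labels")
    values = pd.concat([t.values for t in tables], axis=1)
    if values.columns.duplicated().any():
        raise AlignmentError("concatenated tables must have distinct state tags")
    return FeatureTable(values, first.labels, state)
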