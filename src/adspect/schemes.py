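"""Canonical feature-space schemes: electrode regions, frequency bands, time epochs.

The feature space is the Cartesian product

    region (7) x activity (3) x ratio (2) x band (6) x epoch (11 encoding / 9 resting)

giving 2772 features per encoding session and 2268 for the resting state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

# --- Electrode regions -------------------------------------------------------
# Seven scalp regions over a 36-electrode subset of the 10/20 extended montage.
REGIONS: dict[str, tuple[str, ...]] = {
    "FM": ("FPz", "AFz", "Fz", "FP1", "FP2"),          # frontal medial
    "LT": ("F5", "F7", "FC5", "FT7", "C5", "T7"),      # left temporal
    "RT": ("F6", "F8", "FC6", "FT8", "C6", "T8"),      # right temporal
    "CM": ("FCz", "Cz", "C1", "C2", "CPz"),            # centro medial
    "LP": ("CP1", "CP3", "CP5", "P3", "P5"),           # left posterior
    "RP": ("CP2", "CP4", "CP6", "P4", "P6"),           # right posterior
    "PM": ("Pz", "P1", "P2", "POz"),                   # posterior medial
}

REGION_ORDER: tuple[str, ...] = tuple(REGIONS)

#: The 36-channel montage, ordered region by region.
MONTAGE: tuple[str, ...] = tuple(ch for region in REGION_ORDER for ch in REGIONS[region])

# --- Frequency bands ---------------------------------------------------------
# Half-open [lo, hi) everywhere except the last band, which closes at 40 Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (7.0, 12.0),
    "beta1": (12.0, 19.0),
    "beta2": (19.0, 30.0),
    "gamma": (30.0, 40.0),
}

BAND_ORDER: tuple[str, ...] = tuple(BANDS)


def band_center(band: str) -> float:
    """Geometric center frequency of a named band (Hz)."""
    lo, hi = BANDS[band]
    return math.sqrt(lo * hi)


def band_mask(freqs, band: str):
    """Boolean mask of bank frequencies belonging to ``band``.

    Membership is half-open [lo, hi); the top band is closed at its upper
    edge so 40 Hz content is not dropped from the feature space.
    """
    import numpy as np

    lo, hi = BANDS[band]
    freqs = np.asarray(freqs, dtype=float)
    if band == BAND_ORDER[-1]:
        return (freqs >= lo) & (freqs <= hi)
    return (freqs >= lo) & (freqs < hi)


# --- Activities, ratios, groups ----------------------------------------------
ACTIVITIES: tuple[str, ...] = ("total", "induced", "evoked")
RATIOS: tuple[str, ...] = ("absolute", "relative")

#: Clinical ordering of the four diagnostic groups along the AD spectrum.
CLASS_ORDER: tuple[str, ...] = ("SCD", "naMCI", "aMCI", "AD")

# --- Temporal epochs ----------------------------------------------------------


@dataclass(frozen=True)
class EpochScheme:
    """Base 400-ms windows plus consecutive-difference windows for one state.

    ``base`` holds ``(label, (start_ms, end_ms))`` pairs; ``diffs`` holds
    ``(label, i, i-1)`` index pairs into ``base``. ``labels`` concatenates
    base labels then difference labels, which is the canonical epoch order.
    """

    state: str
    base: tuple[tuple[str, tuple[float, float]], ...]
    diffs: tuple[tuple[str, int, int], ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for lbl, _ in self.base) + tuple(lbl for lbl, _, _ in self.diffs)

    @property
    def n_epochs(self) -> int:
        return len(self.base) + len(self.diffs)


_ENC_BASE = (
    ("pre", (-400.0, 0.0)),
    ("0to4", (0.0, 400.0)),
    ("4to8", (400.0, 800.0)),
    ("8to12", (800.0, 1200.0)),
    ("12to16", (1200.0, 1600.0)),
    ("16to20", (1600.0, 2000.0)),
)

_REST_BASE = _ENC_BASE[1:]


def _diffs(base) -> tuple[tuple[str, int, int], ...]:
    return tuple(
        (f"{base[i][0]}-{base[i - 1][0]}", i, i - 1) for i in range(1, len(base))
    )


ENCODING_EPOCHS = EpochScheme("encoding", _ENC_BASE, _diffs(_ENC_BASE))
RESTING_EPOCHS = EpochScheme("resting", _REST_BASE, _diffs(_REST_BASE))


def epoch_scheme(state: str) -> EpochScheme:
    """Return the temporal epoch scheme for ``'resting'`` or ``'encoding'``.

    Encoding keeps the -400..0 ms pre-stimulus window (pre-stimulus activity
    carries information about encoding success); resting starts at 0 ms since
    there is no stimulus to precede, giving 6+5=11 vs 5+4=9 epochs.
    """
    if state == "encoding":
        return ENCODING_EPOCHS
    if state == "resting":
        return RESTING_EPOCHS
    raise ValueError(f"unknown state {state!r}; expected 'resting' or 'encoding'")
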