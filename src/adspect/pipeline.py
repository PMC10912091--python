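"""End-to-end orchestration: cohort -> preprocessing -> TF power -> feature tables.

Synthetic cohorts are generated band-limited at the target rate, so the
ingest-only steps (band-pass, notch, resampling) are skipped here; the
preprocessing applied per state mirrors the study flow otherwise: common
average reference everywhere, baseline correction for stimulus-locked trials,
middle-2-minute segmentation and 2-s non-overlapping pseudo-trials for rest.
"""

from __future__ import annotations

import numpy as np

from .containers import SubjectRecord
from .errors import ParameterError
from .evaluate import EvaluationReport, run_experiment
from .features import FeatureTable, assemble_features, concat_states, make_table
from .preprocess import (
    average_reference,
    average_reference_epochs,
    baseline_correct,
    resting_middle_segment,
    resting_pseudotrials,
)
from .synth import CohortSpec, generate_cohort, generate_null_cohort
from .timefreq import WaveletBank, make_bank, tf_all

ENCODING_STATES = ("enc1", "enc2", "enc3")


def default_bank(sampling_rate: float, n_freqs: int = 42) -> WaveletBank:
    """The 2-60 Hz log-spaced bank with 3->10 log-spaced cycles."""
    return make_bank(2.0, 60.0, n_freqs, 3.0, 10.0, sampling_rate)


def extract_state_row(record: SubjectRecord, state: str, bank: WaveletBank):
    """One subject's feature row for 'resting' or 'enc<k>'."""
    if state == "resting":
        rec = record.resting
        keep = min(120.0, rec.duration)
        segment = average_reference(resting_middle_segment(rec, keep))
        ep = resting_pseudotrials(segment, 2.0)
        tfs = tf_all(ep, bank)
        return assemble_features(tfs, "resting", ep.channel_names)
    if state.startswith("enc"):
        k = int(state[3:])
        if k < 1 or k > len(record.sessions):
            raise ParameterError(f"subject {record.subject_id} has no session {k}")
        ep = average_reference_epochs(record.sessions[k - 1])
        if ep.times[0] < 0:
            ep = baseline_correct(ep, (-500.0, 0.0))
        tfs = tf_all(ep, bank)
        return assemble_features(tfs, "encoding", ep.channel_names)
    raise ParameterError(f"unknown state {state!r}")


def extract_cohort_features(
    cohort: list[SubjectRecord],
    states=("resting",) + ENCODING_STATES,
    bank: WaveletBank | None = None,
    n_freqs: int = 42,
) -> dict[str, FeatureTable]:
    """Per-state feature tables for a cohort (one row per subject)."""
    if not cohort:
        raise ParameterError("cohort is empty")
    if bank is None:
        bank = default_bank(cohort[0].resting.sampling_rate, n_freqs)
    tables: dict[str, FeatureTable] = {}
    ids = [rec.subject_id for rec in cohort]
    labels = [rec.group for rec in cohort]
    for state in states:
        rows, keys = [], None
        for record in cohort:
            row, keys = extract_state_row(record, state, bank)
            rows.append(row)
        tables[state] = make_table(np.stack(rows), keys, ids, labels, state)
    return tables


def encoding_table(tables: dict[str, FeatureTable]) -> FeatureTable:
    """Concatenate the three encoding sessions into one 3x2772-column table."""
    return concat_states([tables[s] for s in ENCODING_STATES if s in tables], "encoding")


def run_cohort_analysis(
    spec: CohortSpec,
    models=("cKNN",),
    states=("resting", "encoding"),
    mode: str = "nested",
    n_freqs: int = 42,
    null: bool = False,
    seed: int | None = None,
) -> dict[tuple[str, str], EvaluationReport]:
    """Generate a cohort from ``spec``, extract features, and run the LOSO loop.

    ``seed`` (defaults to ``spec.seed``) drives the stochastic classifiers;
    cohort generation is governed by ``spec.seed`` alone.
    """
    cohort = generate_null_cohort(spec) if null else generate_cohort(spec)
    needed = set()
    for state in states:
        needed.update(ENCODING_STATES if state == "encoding" else (state,))
    tables = extract_cohort_features(cohort, states=sorted(needed), n_freqs=n_freqs)
    run_tables = {}
    for state in states:
        run_tables[state] = encoding_table(tables) if state == "encoding" else tables[state]
    return run_experiment(
        run_tables, models=models, mode=mode,
        seed=spec.seed if seed is None else seed,
    )
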