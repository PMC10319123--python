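"""Preprocessing of continuous EEG and alignment of the fixation stream.

Chain applied to every recording: re-reference to the channel average,
zero-phase 0.5 Hz high-pass (4th-order Butterworth), zero-phase notch
filters at the line frequency and its first harmonic (2 Hz bandwidth IIR).
Condition segments are then cut around each condition's start/end markers
with a 2 s pad, and baseline-corrected over the 200 ms before stimulus
onset.  Fixations are assigned to conditions by their absolute timestamps
and re-expressed relative to each condition's stimulus onset — both streams
are aligned through the same condition markers, with no drift correction in
between.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import (
    ConditionSegment,
    Recording,
    empty_fixation_log,
    validate_fixation_log,
)

logger = logging.getLogger(__name__)


def average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous channel mean from every sample."""
    return data - data.mean(axis=0, keepdims=True)


def preprocess_recording(
    rec: Recording, hp_cutoff: float = 0.5, notch_freqs=(50.0, 100.0)
) -> Recording:
    """Average reference + high-pass + notch, zero-phase throughout.

    Zero-phase (forward-backward) application preserves the latencies of
    fixation-locked responses.  Sample count is unchanged.
    """
    nyq = rec.fs / 2.0
    if notch_freqs and max(notch_freqs) >= nyq:
        raise ValueError(
            f"notch frequency {max(notch_freqs)} Hz at or above Nyquist ({nyq} Hz)"
        )
    data = average_reference(rec.data)
    sos = sps.butter(4, hp_cutoff, btype="highpass", fs=rec.fs, output="sos")
    data = sps.sosfiltfilt(sos, data, axis=1)
    for f0 in notch_freqs:
        b, a = sps.iirnotch(f0, Q=f0 / 2.0, fs=rec.fs)  # 2 Hz bandwidth
        data = sps.filtfilt(b, a, data, axis=1)
    return replace(rec, data=data)


def _baseline_window(fs: float):
    """Half-open [-200, 0) ms window as sample offsets."""
    return int(np.ceil(-0.2 * fs)), 0


def extract_condition_segments(rec: Recording, pad: float = 2.0) -> list:
    """Cut one padded segment per condition and baseline-correct it.

    Each segment spans ``[start - pad, end + pad]`` (clipped to the
    recording); the per-channel mean over the 200 ms before stimulus onset
    is subtracted.  Raises if a condition is missing its start or end
    marker.
    """
    starts, ends = {}, {}
    for s, code in rec.events:
        c, kind = divmod(code, 10)
        (starts if kind == 1 else ends)[c] = s
    conditions = sorted(set(starts) | set(ends))
    segments = []
    for c in conditions:
        if c not in starts or c not in ends:
            missing = "start" if c not in starts else "end"
            raise ValueError(f"condition {c}: missing {missing} marker")
        pad_n = int(round(pad * rec.fs))
        lo = max(0, starts[c] - pad_n)
        hi = min(rec.n_samples, ends[c] + pad_n + 1)
        data = rec.data[:, lo:hi].copy()
        onset = starts[c] - lo
        b0, b1 = _baseline_window(rec.fs)
        blo, bhi = max(0, onset + b0), onset + b1
        if blo < bhi:
            data -= data[:, blo:bhi].mean(axis=1, keepdims=True)
        segments.append(
            ConditionSegment(
                data=data,
                fs=rec.fs,
                stimulus_onset_sample=onset,
                condition=c,
                participant=rec.participant,
                trial_end_sample=ends[c] - lo,
            )
        )
    return segments


def load_fixations(fixations, condition_windows: dict) -> pd.DataFrame:
    """Assign fixations to conditions and re-express onsets relative to each
    condition's stimulus onset.

    Parameters
    ----------
    fixations : DataFrame or path
        Table with absolute ``onset_ms`` (shared clock with the EEG event
        markers), ``duration_ms``, ``x``, ``y``.
    condition_windows : dict
        condition id -> (start_ms, end_ms) of the condition, absolute.

    Fixations outside every window are dropped; the count is logged.
    """
    if not isinstance(fixations, pd.DataFrame):
        try:
            fixations = pd.read_csv(fixations)
        except Exception as exc:  # pragma: no cover - I/O failure path
            raise ValueError(f"cannot parse fixation log: {exc}") from exc
    required = ["onset_ms", "duration_ms", "x", "y"]
    missing = [c for c in required if c not in fixations.columns]
    if missing:
        raise ValueError(f"fixation log missing columns: {missing}")
    bad = fixations[required].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"unparseable fixation rows: {list(fixations.index[bad])}")

    if len(fixations) == 0:
        logger.warning("empty fixation log")
        return empty_fixation_log()

    out = []
    n_dropped = 0
    for t, row in zip(fixations["onset_ms"].to_numpy(), fixations.itertuples()):
        assigned = None
        for c, (s_ms, e_ms) in condition_windows.items():
            if s_ms <= t <= e_ms:
                assigned = (c, s_ms)
                break
        if assigned is None:
            n_dropped += 1
            continue
        c, s_ms = assigned
        out.append(
            {
                "onset_ms": t - s_ms,
                "duration_ms": row.duration_ms,
                "x": row.x,
                "y": row.y,
                "condition": c,
            }
        )
    if n_dropped:
        logger.info("dropped %d fixations outside all condition windows", n_dropped)
    if not out:
        logger.warning("no fixations fell inside any condition window")
        return empty_fixation_log()
    df = pd.DataFrame(out).sort_values(["condition", "onset_ms"], kind="stable")
    df = df.reset_index(drop=True)
    df.attrs["n_dropped"] = n_dropped
    return validate_fixation_log(df)
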