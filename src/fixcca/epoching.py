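"""Single-trial fixation-related potentials (sFRPs) and concatenation.

An sFRP is the EEG epoch in the half-open window [-200, +500) ms around one
fixation onset, baseline-corrected by the per-channel mean over [-200, 0) ms.
The sample grid is the set of integer offsets k with
``-0.2*fs <= k < 0.5*fs`` (179 samples at 256 Hz).  Per participant and
condition the retained epochs are horizontally concatenated into the data
matrix X used by the covariance machinery; cross-participant column
alignment truncates every participant to the group-wide minimum epoch
count, keeping the earliest epochs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ConcatMatrix, ConditionSegment, FRPSet

logger = logging.getLogger(__name__)

WINDOW_MS = (-200.0, 500.0)


def epoch_sample_offsets(fs: float) -> np.ndarray:
    """Integer sample offsets k with -0.2*fs <= k < 0.5*fs."""
    return np.arange(int(np.ceil(-0.2 * fs)), int(np.ceil(0.5 * fs)))


def epoch_length(fs: float) -> int:
    return epoch_sample_offsets(fs).size


def epoch_at_fixations(seg: ConditionSegment, fixations: pd.DataFrame) -> FRPSet:
    """Epoch a condition segment at every fixation onset.

    Fixation onsets (ms relative to the segment's stimulus onset) are mapped
    to the nearest EEG sample.  Fixations whose full window would overrun the
    segment are dropped and counted.  Each epoch's baseline (mean over
    [-200, 0) ms, per channel) is subtracted.
    """
    if len(fixations) and "condition" in fixations.columns:
        conds = set(fixations["condition"].unique())
        if conds - {seg.condition}:
            raise ValueError(
                f"fixations from conditions {sorted(conds)} do not match "
                f"segment condition {seg.condition}"
            )
    offs = epoch_sample_offsets(seg.fs)
    t_len = offs.size
    n_base = np.count_nonzero(offs < 0)
    d = seg.data.shape[0]
    epochs, n_dropped = [], 0
    onsets = fixations["onset_ms"].to_numpy() if len(fixations) else np.empty(0)
    for onset_ms in onsets:
        center = seg.stimulus_onset_sample + int(np.round(onset_ms / 1000.0 * seg.fs))
        lo, hi = center + offs[0], center + offs[-1] + 1
        if lo < 0 or hi > seg.n_samples:
            n_dropped += 1
            continue
        ep = seg.data[:, lo:hi].copy()
        ep -= ep[:, :n_base].mean(axis=1, keepdims=True)
        epochs.append(ep)
    if not epochs:
        logger.warning(
            "no epochs for participant %s condition %s", seg.participant, seg.condition
        )
        stack = np.empty((d, t_len, 0))
    else:
        stack = np.stack(epochs, axis=2)
    return FRPSet(
        epochs=stack,
        fs=seg.fs,
        window_ms=WINDOW_MS,
        participant=seg.participant,
        condition=seg.condition,
        n_dropped=n_dropped,
    )


def concatenate_epochs(frps: FRPSet, f_common: int) -> ConcatMatrix:
    """Concatenate the first ``f_common`` epochs into X (D x T*f_common)."""
    if f_common <= 0 or f_common > frps.n_fixations:
        raise ValueError(
            f"f_common={f_common} invalid for participant {frps.participant} "
            f"condition {frps.condition} with F={frps.n_fixations}"
        )
    sel = frps.epochs[:, :, :f_common]  # (D, T, F)
    x = sel.transpose(0, 2, 1).reshape(frps.n_channels, -1)
    return ConcatMatrix(
        X=x,
        n_times=frps.n_times,
        f_used=f_common,
        participant=frps.participant,
        condition=frps.condition,
    )


def common_fixation_count(frp_sets: list) -> int:
    """Group-wide minimum epoch count (the column-alignment truncation)."""
    if not frp_sets:
        raise ValueError("empty FRPSet list")
    empty = [f.participant for f in frp_sets if f.n_fixations == 0]
    if empty:
        raise ValueError(f"participants with zero epochs: {empty}")
    return min(f.n_fixations for f in frp_sets)
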