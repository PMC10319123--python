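"""Core in-memory containers shared across the pipeline.

EEG is carried as plain ``channels x samples`` float arrays with a small
amount of metadata; fixation logs are pandas DataFrames.  Condition start/end
markers use integer event codes ``10*c + 1`` (start) and ``10*c + 2`` (end)
for condition ``c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical condition ids of the serial naming task: phonologically
#: (rime) vs visually confusable letter matrices, confusable vs not.
CONDITION_NAMES = {
    1: "rime_confusable",
    2: "rime_nonconfusable",
    3: "visual_confusable",
    4: "visual_nonconfusable",
}

#: condition -> (modality, confusability) factors for the repeated-measures
#: comparison.
CONDITION_FACTORS = {
    1: ("rime", "confusable"),
    2: ("rime", "nonconfusable"),
    3: ("visual", "confusable"),
    4: ("visual", "nonconfusable"),
}

FIXATION_COLUMNS = ["onset_ms", "duration_ms", "x", "y", "condition"]


def start_code(condition: int) -> int:
    return 10 * condition + 1


def end_code(condition: int) -> int:
    return 10 * condition + 2


@dataclass
class Recording:
    """Continuous multichannel EEG with an event table.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    events : list of (int, int)
        ``(sample_index, marker_code)`` pairs, sample indices within range.
    participant : str
    """

    data: np.ndarray
    fs: float
    channel_names: list = field(default_factory=list)
    events: list = field(default_factory=list)
    participant: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("Recording.data must be (n_channels>=2, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        n = self.data.shape[1]
        for s, _code in self.events:
            if not (0 <= s < n):
                raise ValueError(f"event sample {s} outside recording [0, {n})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def condition_windows_ms(self) -> dict:
        """Map condition id -> (start_ms, end_ms) from the event table."""
        starts, ends = {}, {}
        for s, code in self.events:
            c, kind = divmod(code, 10)
            if kind == 1:
                starts[c] = s / self.fs * 1000.0
            elif kind == 2:
                ends[c] = s / self.fs * 1000.0
        return {c: (starts[c], ends[c]) for c in starts if c in ends}


@dataclass
class ConditionSegment:
    """One condition's EEG cut-out, padded around the task window.

    ``stimulus_onset_sample`` indexes the condition (stimulus) onset within
    ``data``; fixation onsets are expressed relative to this sample.
    """

    data: np.ndarray
    fs: float
    stimulus_onset_sample: int
    condition: int
    participant: str = ""
    trial_end_sample: int | None = None

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def empty_fixation_log() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in FIXATION_COLUMNS})


def validate_fixation_log(df: pd.DataFrame) -> pd.DataFrame:
    """Check the FixationLog contract: required columns, positive durations,
    non-decreasing onsets within each condition."""
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fixation log missing columns: {missing}")
    if len(df) and (df["duration_ms"] <= 0).any():
        raise ValueError("fixation durations must be positive")
    for c, sub in df.groupby("condition"):
        if not sub["onset_ms"].is_monotonic_increasing:
            raise ValueError(f"fixation onsets not sorted within condition {c}")
    return df


@dataclass
class FRPSet:
    """Stack of single-trial fixation-related potentials.

    ``epochs`` has shape (n_channels, n_times, n_fixations); every epoch is
    baseline-corrected over the pre-onset window.
    """

    epochs: np.ndarray
    fs: float
    window_ms: tuple = (-200.0, 500.0)
    participant: str = ""
    condition: int = 0
    n_dropped: int = 0

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_fixations(self) -> int:
        return self.epochs.shape[2]


@dataclass
class ConcatMatrix:
    """Horizontally concatenated epochs: X of shape (D, T * F_used)."""

    X: np.ndarray
    n_times: int
    f_used: int
    participant: str = ""
    condition: int = 0

    def to_epochs(self) -> np.ndarray:
        """Invert concatenation back to (D, T, F_used)."""
        d = self.X.shape[0]
        return self.X.reshape(d, self.f_used, self.n_times).transpose(0, 2, 1)
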