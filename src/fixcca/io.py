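"""Portable on-disk formats: EEG as a float array + JSON sidecar, fixation
logs as CSV.

The EEG container is deliberately simple — ``<stem>.npy`` holding the
channels x samples float array and ``<stem>.json`` with sampling rate,
channel names, participant id and the event table.  Reading standard raw
formats (BDF/EDF) is an adapter concern outside this package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FIXATION_COLUMNS, Recording


def save_recording(rec: Recording, stem) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(stem.with_suffix(".npy"), rec.data)
    sidecar = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "events": [[int(s), int(c)] for s, c in rec.events],
        "participant": rec.participant,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_recording(stem) -> Recording:
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return Recording(
        data=data,
        fs=meta["fs"],
        channel_names=meta["channel_names"],
        events=[tuple(e) for e in meta["events"]],
        participant=meta.get("participant", ""),
    )


def save_fixation_log(log: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    log[FIXATION_COLUMNS].to_csv(path, index=False)


def load_fixation_log(path) -> pd.DataFrame:
    return pd.read_csv(path)
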