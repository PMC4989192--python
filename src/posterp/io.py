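"""On-disk formats.

Events travel as a tab-separated table with columns ``onset_ms``,
``block``, ``trial``, ``category`` (go/nogo), ``stim_id``, ``response``
(1/0) and ``rt_ms`` (empty when no response); times are milliseconds from
recording start.  Continuous EEG is a flat little-endian 32-bit float
matrix (channels x samples, microvolts) next to a JSON sidecar
``{channels, sfreq_hz, unit, n_samples}``; sample indexing is 0-based.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .erp import ContinuousRecording

__all__ = ["write_events", "read_events", "write_recording",
           "read_recording"]

EVENT_COLUMNS = ["onset_ms", "block", "trial", "category", "stim_id",
                 "response", "rt_ms"]


def write_events(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False,
                                 float_format="%.6f", na_rep="")


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns {sorted(missing)}")
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    return df[EVENT_COLUMNS]


def write_recording(recording: ContinuousRecording, raw_path,
                    sidecar_path=None) -> None:
    """Write the voltage matrix as flat float32 LE plus a JSON sidecar."""
    raw_path = Path(raw_path)
    sidecar_path = (Path(sidecar_path) if sidecar_path is not None
                    else raw_path.with_suffix(".json"))
    recording.data.astype("<f4").tofile(raw_path)
    sidecar = {
        "channels": list(recording.channels),
        "sfreq_hz": recording.sfreq_hz,
        "unit": "uV",
        "n_samples": recording.n_samples,
        "sample_indexing": "0-based; sample k is at k / sfreq_hz seconds",
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_recording(raw_path, sidecar_path=None) -> ContinuousRecording:
    raw_path = Path(raw_path)
    sidecar_path = (Path(sidecar_path) if sidecar_path is not None
                    else raw_path.with_suffix(".json"))
    meta = json.loads(sidecar_path.read_text())
    data = np.fromfile(raw_path, dtype="<f4")
    n_ch = len(meta["channels"])
    if data.size != n_ch * meta["n_samples"]:
        raise ValueError(
            f"{raw_path}: expected {n_ch} x {meta['n_samples']} samples, "
            f"found {data.size} values")
    return ContinuousRecording(
        data=data.reshape(n_ch, meta["n_samples"]).astype(np.float64),
        channels=tuple(meta["channels"]), sfreq_hz=float(meta["sfreq_hz"]))
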