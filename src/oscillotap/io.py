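"""On-disk containers for recordings and epochs.

Continuous recordings are stored in a small, documented HDF5 layout:

    /data                channels x samples float32, uV
    /events/sample       int64 sample indices
    /events/condition    UTF-8 condition labels
    /events/rate         float64 BPM
    attrs: fs, participant_id, channel_labels (JSON list)

Epoch sets use the same idea with a ``trials x channels x samples`` cube and
the windowing metadata in JSON attrs.  Events can additionally be exported as
a plain TSV sidecar (onset_s, condition, rate).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import ContinuousRecording, Event

__all__ = [
    "write_recording",
    "read_recording",
    "write_events_tsv",
    "read_events_tsv",
    "write_epochs",
    "read_epochs",
]

_STR = h5py.string_dtype(encoding="utf-8")


def write_recording(recording: ContinuousRecording, path, dtype=np.float32) -> Path:
    """Write a recording to the HDF5 container; round-trips to float32 precision."""
    if recording.n_channels == 0:
        raise ValueError("cannot write a recording with zero channels")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data.astype(dtype))
        grp = f.create_group("events")
        grp.create_dataset("sample", data=np.array([ev.sample for ev in recording.events],
                                                   dtype=np.int64))
        grp.create_dataset("condition", data=[ev.condition for ev in recording.events],
                           dtype=_STR)
        grp.create_dataset("rate", data=np.array([ev.rate for ev in recording.events]))
        f.attrs["fs"] = float(recording.fs)
        f.attrs["participant_id"] = int(recording.participant_id)
        f.attrs["channel_labels"] = json.dumps(list(recording.channel_labels))
    return path


def read_recording(path) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        data = f["data"][()].astype(np.float64)
        labels = tuple(json.loads(f.attrs["channel_labels"]))
        conditions = [c.decode() if isinstance(c, bytes) else str(c)
                      for c in f["events/condition"][()]]
        events = tuple(
            Event(int(s), c, float(r))
            for s, c, r in zip(f["events/sample"][()], conditions, f["events/rate"][()])
        )
        return ContinuousRecording(
            data=data,
            fs=float(f.attrs["fs"]),
            channel_labels=labels,
            events=events,
            participant_id=int(f.attrs["participant_id"]),
        )


def write_events_tsv(recording: ContinuousRecording, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "onset_s": [ev.sample / recording.fs for ev in recording.events],
            "condition": [ev.condition for ev in recording.events],
            "rate": [ev.rate for ev in recording.events],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path, fs: float) -> tuple[Event, ...]:
    df = pd.read_csv(path, sep="\t")
    return tuple(
        Event(int(round(row.onset_s * fs)), str(row.condition), float(row.rate))
        for row in df.itertuples()
    )


def write_epochs(epochs, path) -> Path:
    """Serialize an EpochSet (see :mod:`oscillotap.epochs`) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("rejected", data=np.array(epochs.rejected, dtype=_STR))
        f.attrs["meta"] = json.dumps(
            {
                "fs": epochs.fs,
                "t0_offset_ms": epochs.t0_offset_ms,
                "epoch_length_ms": epochs.epoch_length_ms,
                "condition": epochs.condition,
                "rate": epochs.rate,
                "baseline_window": list(epochs.baseline_window)
                if epochs.baseline_window is not None else None,
                "channel_labels": list(epochs.channel_labels),
            }
        )
    return path


def read_epochs(path):
    from .epochs import EpochSet

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        rejected = [r.decode() if isinstance(r, bytes) else str(r)
                    for r in f["rejected"][()]]
        return EpochSet(
            data=f["data"][()].astype(np.float64),
            fs=meta["fs"],
            t0_offset_ms=meta["t0_offset_ms"],
            epoch_length_ms=meta["epoch_length_ms"],
            condition=meta["condition"],
            rate=meta["rate"],
            baseline_window=tuple(meta["baseline_window"])
            if meta["baseline_window"] is not None else None,
            channel_labels=tuple(meta["channel_labels"]),
            rejected=rejected,
        )
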