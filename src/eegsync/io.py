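"""Plain-text persistence: recordings as CSV + JSON sidecar, tensors as CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityTensor
from .recording import Recording

__all__ = [
    "save_recording_csv",
    "load_recording_csv",
    "save_tensor_csv",
    "load_tensor_csv",
]


def save_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write one recording as ``<path>.csv`` (rows = samples, columns =
    labelled channels, µV) plus ``<path>.json`` holding fs and metadata."""
    path = Path(path)
    df = pd.DataFrame(rec.samples.T, columns=list(rec.channel_labels))
    df.to_csv(path.with_suffix(".csv"), index=False, float_format="%.6g")
    meta = {
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "group": rec.group,
        "channel_labels": list(rec.channel_labels),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_recording_csv(path: str | Path) -> Recording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path.with_suffix(".csv"))
    labels = tuple(meta["channel_labels"])
    if tuple(df.columns) != labels:
        raise ValueError(f"{path}: CSV columns do not match sidecar labels")
    return Recording(
        samples=df.to_numpy().T,
        fs=float(meta["fs"]),
        channel_labels=labels,
        subject_id=meta.get("subject_id", path.stem),
        group=meta.get("group", "HC"),
    )


def save_tensor_csv(tensor: ConnectivityTensor, path: str | Path) -> None:
    """Long-format tensor CSV: subject_id, group, band, chan_a, chan_b, value."""
    tensor.to_dataframe().to_csv(path, index=False, float_format="%.6g")


def load_tensor_csv(path: str | Path, metric: str = "PLI") -> ConnectivityTensor:
    df = pd.read_csv(path)
    sids = list(dict.fromkeys(df["subject_id"]))
    bands = tuple(dict.fromkeys(df["band"]))
    # recover channel ordering from first subject/band block
    first = df[(df.subject_id == sids[0]) & (df.band == bands[0])]
    labels: list[str] = []
    for a, b in zip(first.chan_a, first.chan_b):
        if a not in labels:
            labels.append(a)
        if b not in labels:
            labels.append(b)
    n_pairs = len(labels) * (len(labels) - 1) // 2
    values = df["value"].to_numpy().reshape(len(sids), len(bands), n_pairs)
    groups = tuple(
        df[df.subject_id == sid]["group"].iloc[0] for sid in sids
    )
    return ConnectivityTensor(
        values=values,
        metric=metric,
        subject_ids=tuple(sids),
        groups=groups,
        band_names=bands,
        channel_labels=tuple(labels),
    )
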