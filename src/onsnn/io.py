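"""Reading and writing delimited segment data.

A dataset on disk is a directory of delimited numeric matrices (CSV or
TSV, one row per channel, one column per timepoint) plus a labels CSV
with columns ``file,label`` giving the stream order. This is the format
``onsnn simulate`` writes and ``onsnn run`` reads. EDF/BDF parsing is an
extension point, not implemented: preprocessed numeric exports are the
expected input.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .aer import EEGSegment
from .network import StreamSample

__all__ = ["read_segment", "write_segment", "read_stream", "write_stream"]


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_segment(path, sampling_rate: float = 256.0,
                 channel_names: Sequence[str] = ()) -> EEGSegment:
    """Load one channels x timepoints matrix from a delimited file."""
    path = Path(path)
    values = np.loadtxt(path, delimiter=_delimiter(path), ndmin=2)
    return EEGSegment(values=values, sampling_rate=sampling_rate,
                      channel_names=tuple(channel_names))


def write_segment(segment: EEGSegment, path) -> None:
    path = Path(path)
    np.savetxt(path, segment.values, delimiter=_delimiter(path), fmt="%.6g")


def read_stream(data_dir, labels_file, sampling_rate: float = 256.0,
                channel_names: Sequence[str] = ()) -> list[StreamSample]:
    """Load a labeled stream: labels CSV rows (file,label) in stream order.

    A ``stream_meta.json`` sidecar (written by :func:`write_stream`)
    supplies channel names and sampling rate when present; explicit
    arguments override it.
    """
    data_dir = Path(data_dir)
    meta_path = data_dir / "stream_meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        channel_names = channel_names or meta.get("channel_names", ())
        sampling_rate = meta.get("sampling_rate", sampling_rate)
    labels = pd.read_csv(labels_file)
    for col in ("file", "label"):
        if col not in labels.columns:
            raise ValueError(f"labels file must have a {col!r} column")
    stream = []
    for i, row in labels.iterrows():
        seg = read_segment(data_dir / row["file"], sampling_rate, channel_names)
        stream.append(StreamSample(segment=seg, label=str(row["label"]), index=i))
    return stream


def write_stream(stream: Sequence[StreamSample], out_dir) -> None:
    """Write per-sample CSV matrices and a labels.csv into ``out_dir``."""
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for s in stream:
        fname = f"sample_{s.index:04d}.csv"
        write_segment(s.segment, out_dir / fname)
        rows.append({"file": fname, "label": s.label})
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)
    first = stream[0].segment
    (out_dir / "stream_meta.json").write_text(json.dumps({
        "channel_names": list(first.channel_names),
        "sampling_rate": first.sampling_rate,
    }))
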