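"""Plain-text I/O: CSV signals with JSON sidecars, event tables, manifests.

A recording is stored as a two-column CSV (``time_s, voltage``) next to a
JSON sidecar (same path with ``.json`` suffix) holding the sampling rate,
seed and generator/analysis parameters.  Ground-truth and detected events
are CSV tables; run manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .filtering import ContractError, LfpRecording
from .swr import RippleEvent

__all__ = [
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_manifest",
    "sidecar_path",
]


def sidecar_path(csv_path: "str | Path") -> Path:
    return Path(csv_path).with_suffix(".json")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_recording(
    path: "str | Path",
    rec: LfpRecording,
    params: Optional[dict] = None,
    seed: Optional[int] = None,
) -> Path:
    """Write a recording as CSV plus a JSON sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame({"time_s": rec.times(), "voltage": rec.samples})
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "fs": rec.fs,
        "channel_id": rec.channel_id,
        "seed": seed,
        "trial": _jsonable(rec.trial) if rec.trial else None,
        "params": _jsonable(params or {}),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_recording(path: "str | Path", fs: Optional[float] = None) -> LfpRecording:
    """Read a CSV recording; fs comes from the sidecar unless given."""
    path = Path(path)
    df = pd.read_csv(path)
    if "voltage" not in df.columns:
        raise ContractError(f"{path} lacks a 'voltage' column")
    channel_id = "ch0"
    sidecar = sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = meta.get("fs") if fs is None else fs
        channel_id = meta.get("channel_id", channel_id)
    if fs is None:
        if "time_s" not in df.columns or len(df) < 2:
            raise ContractError(f"cannot infer fs for {path}; pass fs explicitly")
        fs = 1.0 / float(np.median(np.diff(df["time_s"].to_numpy())))
    return LfpRecording(
        samples=df["voltage"].to_numpy(dtype=np.float64),
        fs=float(fs),
        channel_id=channel_id,
    )


def write_events(
    path: "str | Path",
    events: Sequence[RippleEvent],
    channel_id: str = "ch0",
    trial: str = "",
) -> Path:
    df = pd.DataFrame(
        [
            {
                "channel_id": channel_id,
                "trial": trial,
                "start_s": ev.start_s,
                "end_s": ev.end_s,
                "duration_ms": ev.duration_ms,
                "peak_z": ev.peak_z,
                "integral_z": ev.integral_z,
            }
            for ev in events
        ],
        columns=[
            "channel_id",
            "trial",
            "start_s",
            "end_s",
            "duration_ms",
            "peak_z",
            "integral_z",
        ],
    )
    df.to_csv(path, index=False, float_format="%.9g")
    return Path(path)


def read_events(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(path: "str | Path", params: dict, seed: Optional[int] = None) -> Path:
    """JSON run manifest: all parameter values, package version, seed."""
    manifest = {
        "version": __version__,
        "seed": seed,
        "params": _jsonable(params),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return Path(path)
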