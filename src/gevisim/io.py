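"""File formats: TIFF movies, CSV traces and spike tables, JSON manifests."""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FormatError",
    "read_movie",
    "write_movie",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_manifest",
]


class FormatError(ValueError):
    """A data file is not in the expected format."""


def write_movie(movie: np.ndarray, path) -> None:
    """Write a T x H x W movie as a multi-frame 32-bit float TIFF."""
    arr = np.asarray(movie)
    if arr.ndim != 3:
        raise FormatError(f"movie must be T x H x W, got shape {arr.shape}")
    tifffile.imwrite(path, arr.astype(np.float32, copy=False), photometric="minisblack")


def read_movie(path) -> np.ndarray:
    """Read a multi-frame TIFF into a T x H x W float32 array."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"movie file not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"not a readable TIFF movie: {path} ({exc})") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"expected a T x H x W movie, got shape {arr.shape}")
    return arr.astype(np.float32, copy=False)


def write_spikes_csv(spikes_by_neuron: Dict[int, Sequence[int]], path) -> None:
    """Ground-truth or inferred spikes as tidy CSV (neuron_id, spike_frame)."""
    rows = [
        {"neuron_id": nid, "spike_frame": int(f)}
        for nid, frames in spikes_by_neuron.items()
        for f in frames
    ]
    pd.DataFrame(rows, columns=["neuron_id", "spike_frame"]).to_csv(path, index=False)


def read_spikes_csv(path) -> Dict[int, np.ndarray]:
    df = pd.read_csv(path)
    missing = {"neuron_id", "spike_frame"} - set(df.columns)
    if missing:
        raise FormatError(f"spike CSV missing column(s) {sorted(missing)}: {path}")
    return {
        int(nid): np.sort(grp["spike_frame"].to_numpy(dtype=int))
        for nid, grp in df.groupby("neuron_id")
    }


def write_trace_csv(trace: np.ndarray, path, frame_rate_hz: Optional[float] = None) -> None:
    df = pd.DataFrame({"frame": np.arange(len(trace)), "intensity": np.asarray(trace, dtype=float)})
    if frame_rate_hz is not None:
        df["time_s"] = df["frame"] / frame_rate_hz
    df.to_csv(path, index=False)


def read_trace_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "intensity" not in df.columns:
        raise FormatError(f"trace CSV missing 'intensity' column: {path}")
    return df["intensity"].to_numpy(dtype=float)


def write_manifest(path, *, command: str, inputs: Dict[str, str], seed: int,
                   config_hash: Optional[str] = None, outputs: Optional[Dict[str, str]] = None,
                   extra: Optional[dict] = None) -> None:
    """Machine-readable record sufficient to reproduce a CLI run's outputs."""
    import gevisim

    manifest = {
        "command": command,
        "inputs": inputs,
        "outputs": outputs or {},
        "seed": seed,
        "config_hash": config_hash,
        "versions": {
            "gevisim": gevisim.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
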