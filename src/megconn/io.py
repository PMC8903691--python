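"""On-disk containers: HDF5 arrays with JSON sidecars, plus cohort manifests.

A Recording is stored as ``<subject>.h5`` (the channels x samples x trials
array, trigger indices, channel positions) and ``<subject>.json`` (sampling
rate, group label, clinical covariates, channel positions, and — for
synthetic data — the generator's ground truth).  A ``manifest.csv`` indexes a
cohort directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import Recording

__all__ = [
    "save_arrays",
    "load_arrays",
    "write_recording",
    "read_recording",
    "import_recording",
    "write_manifest",
    "read_manifest",
]


def save_arrays(path: Path | str, arrays: dict[str, np.ndarray], attrs: dict | None = None) -> None:
    """Write named arrays (plus scalar attrs) to one HDF5 file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for name, arr in arrays.items():
            f.create_dataset(name, data=np.asarray(arr))
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_arrays(path: Path | str) -> tuple[dict[str, np.ndarray], dict]:
    with h5py.File(path, "r") as f:
        arrays = {name: f[name][()] for name in f}
        attrs = dict(f.attrs)
    return arrays, attrs


def write_recording(rec: Recording, directory: Path | str) -> Path:
    """Write one Recording as <subject_id>.h5 + <subject_id>.json; returns the h5 path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    h5_path = directory / f"{rec.subject_id}.h5"
    save_arrays(
        h5_path,
        {
            "data": rec.data,
            "trigger_sample": rec.trigger_sample,
            "channel_positions": rec.channel_positions,
        },
    )
    sidecar = {
        "sfreq": rec.sfreq,
        "group": rec.group,
        "clinical": rec.clinical,
        "subject_id": rec.subject_id,
        "channel_positions": rec.channel_positions.tolist(),
        "ground_truth": rec.ground_truth,
    }
    (directory / f"{rec.subject_id}.json").write_text(json.dumps(sidecar, indent=1))
    return h5_path


def read_recording(h5_path: Path | str, sidecar_path: Path | str | None = None) -> Recording:
    h5_path = Path(h5_path)
    if sidecar_path is None:
        sidecar_path = h5_path.with_suffix(".json")
    return import_recording(h5_path, sidecar_path)


def import_recording(path: Path | str, sidecar: Path | str | dict) -> Recording:
    """Load and validate a recording container + sidecar into a Recording.

    Rejects non-positive sampling rates, shape mismatches, and non-finite
    data with actionable messages; missing clinical covariates are accepted
    as nulls and flagged downstream.
    """
    arrays, _ = load_arrays(path)
    if isinstance(sidecar, (str, Path)):
        meta = json.loads(Path(sidecar).read_text())
    else:
        meta = dict(sidecar)
    sfreq = float(meta.get("sfreq", 0))
    if sfreq <= 0:
        raise ValueError(f"sidecar sfreq must be positive, got {meta.get('sfreq')!r}")
    data = np.asarray(arrays["data"], dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError(f"data must be channels x samples x trials, got shape {data.shape}")
    chan_pos = np.asarray(
        arrays.get("channel_positions", meta.get("channel_positions")), dtype=float
    )
    if chan_pos.shape != (data.shape[0], 3):
        raise ValueError(
            f"channel_positions shape {chan_pos.shape} does not match "
            f"{data.shape[0]} channels"
        )
    clinical = meta.get("clinical") or {}
    return Recording(
        data=data,
        sfreq=sfreq,
        trigger_sample=np.asarray(arrays["trigger_sample"], dtype=int),
        channel_positions=chan_pos,
        group=meta.get("group", "unknown"),
        clinical=clinical,
        subject_id=str(meta.get("subject_id", Path(path).stem)),
        ground_truth=meta.get("ground_truth", {}),
    )


def write_manifest(directory: Path | str, recordings: list[Recording]) -> Path:
    """Index a cohort directory with one manifest row per subject."""
    directory = Path(directory)
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group,
            "n_channels": r.n_channels,
            "n_trials": r.n_trials,
            "sfreq": r.sfreq,
            "pattern_present": r.ground_truth.get("pattern_present"),
            "file": f"{r.subject_id}.h5",
        }
        for r in recordings
    ]
    path = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_manifest(directory: Path | str) -> pd.DataFrame:
    return pd.read_csv(Path(directory) / "manifest.csv")
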