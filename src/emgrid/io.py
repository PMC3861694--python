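"""Reading and writing of recordings, maps and results.

Two recording dialects are supported, selected by file extension:

* ``.csv`` — the canonical text fixture format. Header row of channel
  identifiers (plus a final ``force`` column when a force channel is
  present); one row per sample. Metadata lives in a sidecar JSON file
  ``<stem>.meta.json`` (fs, subject/task/anatomy, ground truth when
  synthetic).
* ``.h5`` — HDF5 with datasets ``data`` and optionally ``force`` and
  the same sidecar JSON. Datasets are written with
  ``track_times=False`` so byte-identical reruns stay byte-identical.

Amplitude and label maps are exported as CSV matrices aligned to the
grid, invalid cells left empty.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .errors import InvalidSpecError
from .grid import GridLayout
from .mapping import AmplitudeMap, LocalizationResult
from .synthetic import Recording, RecordingMeta

__all__ = [
    "sidecar_path",
    "save_recording",
    "load_recording",
    "save_map_csv",
    "save_labels_csv",
    "save_result_json",
]


def sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".meta.json")


def _write_sidecar(recording: Recording, path: Path) -> None:
    doc = {
        "fs": recording.fs,
        "has_force": recording.force is not None,
        "meta": recording.meta.to_dict(),
    }
    sidecar_path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _read_sidecar(path: Path) -> dict:
    sp = sidecar_path(path)
    if not sp.exists():
        raise InvalidSpecError(f"missing sidecar metadata {sp}")
    return json.loads(sp.read_text())


def save_recording(recording: Recording, path: str | Path, layout: GridLayout) -> Path:
    """Write a recording (.csv or .h5) plus its sidecar JSON."""
    path = Path(path)
    if recording.n_channels != layout.n_channels:
        raise InvalidSpecError(
            f"recording has {recording.n_channels} channels, layout "
            f"{layout.n_channels}"
        )
    if path.suffix == ".csv":
        cols = list(layout.channels)
        arr = recording.data
        if recording.force is not None:
            cols = cols + ["force"]
            arr = np.column_stack([arr, recording.force])
        with open(path, "w") as f:
            f.write(",".join(cols) + "\n")
            np.savetxt(f, arr, delimiter=",", fmt="%.9g")
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=recording.data, track_times=False)
            if recording.force is not None:
                f.create_dataset("force", data=recording.force, track_times=False)
    else:
        raise InvalidSpecError(f"unsupported recording format {path.suffix!r}")
    _write_sidecar(recording, path)
    return path


def load_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`save_recording`."""
    path = Path(path)
    doc = _read_sidecar(path)
    meta = RecordingMeta.from_dict(doc.get("meta", {}))
    fs = float(doc["fs"])
    if path.suffix == ".csv":
        with open(path) as f:
            header = f.readline().strip().split(",")
            arr = np.loadtxt(f, delimiter=",", ndmin=2)
        force = None
        if header and header[-1] == "force":
            force = arr[:, -1]
            arr = arr[:, :-1]
        return Recording(data=arr, fs=fs, force=force, meta=meta)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            force = f["force"][()] if "force" in f else None
        return Recording(data=data, fs=fs, force=force, meta=meta)
    raise InvalidSpecError(f"unsupported recording format {path.suffix!r}")


def _grid_csv(grid: np.ndarray, valid: np.ndarray, fmt) -> str:
    lines = []
    for r in range(grid.shape[0]):
        cells = [
            fmt(grid[r, c]) if valid[r, c] else "" for c in range(grid.shape[1])
        ]
        lines.append(",".join(cells))
    return "\n".join(lines) + "\n"


def save_map_csv(amap: AmplitudeMap, path: str | Path) -> Path:
    """Amplitude map as a grid-aligned CSV (invalid cells empty)."""
    path = Path(path)
    path.write_text(
        _grid_csv(amap.to_grid(), amap.valid_mask, lambda v: f"{v:.9g}")
    )
    return path


def save_labels_csv(labels: np.ndarray, layout: GridLayout, path: str | Path) -> Path:
    """Cluster-label map as a grid-aligned CSV (invalid cells empty)."""
    path = Path(path)
    grid = layout.to_grid(np.asarray(labels, dtype=float), fill=np.nan)
    path.write_text(_grid_csv(grid, layout.valid_mask, lambda v: str(int(v))))
    return path


def save_result_json(
    result: LocalizationResult, path: str | Path, config_hash: str | None = None
) -> Path:
    """LocalizationResult as JSON; embeds the producing config hash."""
    path = Path(path)
    doc = result.to_dict()
    if config_hash is not None:
        doc["config_hash"] = config_hash
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path
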