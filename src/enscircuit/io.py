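"""Readers and writers for movies, 3D masks and result tables.

Movies travel as multi-page TIFF (uint16) with a ``<stem>.meta.json``
sidecar, or as HDF5 with the metadata embedded in attributes.  Required
metadata keys: frame_rate_hz, pixel_size_um, stim_epochs, electrode_xy,
oral_axis.  When both embedded attributes and a sidecar are present the
sidecar wins.  Tables are plain CSV with a stable field order.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .transients import RecordingMovie, RoiEllipse, StimEpoch

__all__ = [
    "read_movie",
    "write_movie",
    "read_mask",
    "write_mask",
    "write_table",
    "read_table",
    "read_roi_table",
    "write_roi_table",
]

REQUIRED_KEYS = ("frame_rate_hz", "pixel_size_um", "stim_epochs", "electrode_xy", "oral_axis")


def _meta_from_movie(movie: RecordingMovie) -> dict:
    return {
        "frame_rate_hz": movie.frame_rate_hz,
        "pixel_size_um": movie.pixel_size_um,
        "stim_epochs": [dataclasses.asdict(e) for e in movie.stim_epochs],
        "electrode_xy": list(movie.electrode_xy),
        "oral_axis": list(movie.oral_axis),
    }


def _movie_from_meta(frames: np.ndarray, meta: dict) -> RecordingMovie:
    for key in REQUIRED_KEYS:
        if key not in meta:
            raise KeyError(f"movie metadata is missing required key {key!r}")
    return RecordingMovie(
        frames=frames,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        stim_epochs=[StimEpoch(**e) for e in meta["stim_epochs"]],
        electrode_xy=tuple(float(v) for v in meta["electrode_xy"]),
        oral_axis=tuple(float(v) for v in meta["oral_axis"]),
    )


def write_movie(movie: RecordingMovie, path: str | Path) -> Path:
    path = Path(path)
    meta = _meta_from_movie(movie)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=movie.frames, compression="gzip")
            for k, v in meta.items():
                f.attrs[k] = json.dumps(v) if k == "stim_epochs" else v
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, movie.frames)
        sidecar = path.parent / (path.stem + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=2))
    else:
        raise ValueError(f"unsupported movie format {path.suffix!r}")
    return path


def read_movie(path: str | Path) -> RecordingMovie:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            frames = f["frames"][...]
            meta = {}
            for k in f.attrs:
                v = f.attrs[k]
                meta[k] = json.loads(v) if k == "stim_epochs" else (
                    v.tolist() if isinstance(v, np.ndarray) else v
                )
    elif path.suffix in (".tif", ".tiff"):
        frames = tifffile.imread(path)
        sidecar = path.parent / (path.stem + ".meta.json")
        if not sidecar.exists():
            raise FileNotFoundError(f"metadata sidecar {sidecar} not found")
        meta = json.loads(sidecar.read_text())
    else:
        raise ValueError(f"unreadable movie format {path.suffix!r}")
    if frames.ndim == 2:
        frames = frames[None]
    return _movie_from_meta(frames, meta)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    mask = np.asarray(mask)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("mask", data=mask.astype(np.uint8), compression="gzip")
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, mask.astype(np.uint8))
    else:
        raise ValueError(f"unsupported mask format {path.suffix!r}")
    return path


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return f["mask"][...]
    if path.suffix in (".tif", ".tiff"):
        return tifffile.imread(path)
    raise ValueError(f"unreadable mask format {path.suffix!r}")


def write_table(records, path: str | Path, columns: list[str] | None = None) -> Path:
    """Write a collection of dataclass records (or dicts) to CSV.

    An empty collection is allowed only with explicit ``columns`` (header-only
    output).  Field order is the dataclass field order, stable across runs.
    """
    path = Path(path)
    records = list(records) if not isinstance(records, pd.DataFrame) else records
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, index=False)
        return path
    if not records:
        if columns is None:
            raise ValueError("empty record list requires explicit columns")
        pd.DataFrame(columns=columns).to_csv(path, index=False)
        return path
    rows = [
        dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r) for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)


def write_roi_table(rois: list[RoiEllipse], path: str | Path) -> Path:
    rows = [
        {
            "id": r.id,
            "cx_um": r.center_xy[0],
            "cy_um": r.center_xy[1],
            "long_um": r.long_axis,
            "short_um": r.short_axis,
            "ganglion_id": r.ganglion_id,
        }
        for r in rois
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_roi_table(path: str | Path) -> list[RoiEllipse]:
    df = read_table(path)
    rois = []
    for _, row in df.iterrows():
        gid = row.get("ganglion_id")
        rois.append(
            RoiEllipse(
                id=int(row["id"]),
                center_xy=(float(row["cx_um"]), float(row["cy_um"])),
                long_axis=float(row["long_um"]),
                short_axis=float(row["short_um"]),
                ganglion_id=None if gid is None or pd.isna(gid) else int(gid),
            )
        )
    return rois
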