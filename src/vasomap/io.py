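"""NIfTI-1 and table I/O helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "save_volume",
    "load_volume",
    "sha256_array",
    "write_tsv",
    "write_json",
    "read_json",
]


def _affine(voxel_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_mm
    return aff


def save_volume(path, data: np.ndarray, voxel_mm: float, tr: float | None = None) -> Path:
    """Write a 3D/4D array as NIfTI-1 (float32 for float data)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(data)
    if arr.dtype.kind == "f":
        arr = arr.astype(np.float32)
    img = nib.Nifti1Image(arr, _affine(voxel_mm))
    zooms = [voxel_mm] * 3
    if arr.ndim == 4:
        zooms.append(tr if tr else 1.0)
        img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(zooms[: arr.ndim])
    nib.save(img, str(path))
    return path


def load_volume(path):
    """Read a NIfTI volume; returns (data, voxel_mm)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(img.header.get_zooms()[0])


def sha256_array(arr: np.ndarray) -> str:
    arr = np.ascontiguousarray(arr)
    return hashlib.sha256(arr.tobytes()).hexdigest()


def write_tsv(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
    return path


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
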