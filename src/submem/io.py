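"""File I/O helpers: NIfTI volumes, TSV tables, ground-truth JSON."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "read_bold",
    "write_volume",
    "read_volume",
    "read_table",
    "write_table",
    "read_truth",
]


def read_bold(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4D BOLD NIfTI volume and its world-coordinate affine."""
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    return data, img.affine


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI volume and its affine."""
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    return data, img.affine


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), path)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
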