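"""NIfTI-1 volume I/O with spacing-aware headers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_volume", "write_volume", "read_mask"]


def write_volume(grid: np.ndarray, spacing_mm, path: str | Path) -> None:
    """Write a 3D scalar grid as NIfTI-1 with the voxel spacing in the header."""
    grid = np.asarray(grid)
    affine = np.diag([*spacing_mm, 1.0])
    img = nib.Nifti1Image(grid, affine)
    img.header.set_zooms(tuple(float(s) for s in spacing_mm))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI-1 volume; returns (data, spacing_mm) from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume in {path}, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a mask volume, binarizing at > 0.5 (any foreground label counts)."""
    data, spacing = read_volume(path)
    return data > 0.5, spacing
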