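"""NIfTI-1 reading/writing for metric maps and masks (thin nibabel layer)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .config import GridSpec

__all__ = ["save_volume", "load_volume", "grid_affine"]


def grid_affine(grid: GridSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = grid.voxel_mm
    return aff


def save_volume(data: np.ndarray, grid: GridSpec, path) -> Path:
    path = Path(path)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), grid_affine(grid))
    img.header.set_zooms((grid.voxel_mm,) * 3)
    nib.save(img, str(path))
    return path


def load_volume(path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    grid = GridSpec(shape=tuple(data.shape), voxel_mm=float(zooms[0]))
    return data, grid
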