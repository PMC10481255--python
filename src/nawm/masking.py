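"""NAWM mask construction: subtraction, erosion, volume.

The normal-appearing white matter mask is the white-matter mask minus the
hyperintensity (lesion) mask, eroded by one voxel so that partial-volume
voxels at mask boundaries do not contaminate the summary metrics.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .config import ErosionSpec

log = logging.getLogger(__name__)

__all__ = ["subtract_masks", "erode_mask", "make_nawm_mask", "mask_volume_ml"]


def subtract_masks(wm: np.ndarray, wmh: np.ndarray) -> np.ndarray:
    """Voxels in WM and not in WMH.

    Lesion voxels outside WM (possible when the two masks come from
    different segmentation algorithms) are tolerated: they cannot appear in
    the output anyway, and their count is logged as a warning.
    """
    wm = np.asarray(wm, dtype=bool)
    wmh = np.asarray(wmh, dtype=bool)
    if wm.shape != wmh.shape:
        raise ValueError(
            f"grid mismatch: WM mask {wm.shape} vs WMH mask {wmh.shape}"
        )
    stray = int(np.count_nonzero(wmh & ~wm))
    if stray:
        log.warning("%d WMH voxels lie outside the WM mask", stray)
    return wm & ~wmh


def _structure(connectivity: int) -> np.ndarray:
    # 6-connectivity = face neighbours (cross element); 26 = full cube
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def erode_mask(mask: np.ndarray, spec: ErosionSpec = ErosionSpec()) -> np.ndarray:
    """Morphological erosion; voxels beyond the grid count as background."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("erode_mask expects a 3-D mask")
    if spec.radius == 0:
        return mask.copy()
    return ndimage.binary_erosion(
        mask, structure=_structure(spec.connectivity), iterations=spec.radius,
        border_value=0,
    )


def make_nawm_mask(
    wm: np.ndarray, wmh: np.ndarray, spec: ErosionSpec = ErosionSpec()
) -> np.ndarray:
    """WM minus WMH, then eroded — the participant-specific NAWM mask."""
    return erode_mask(subtract_masks(wm, wmh), spec)


def mask_volume_ml(mask: np.ndarray, voxel_mm: float) -> float:
    """Voxel count x voxel volume (mm^3) / 1000."""
    return float(np.count_nonzero(mask)) * float(voxel_mm) ** 3 / 1000.0
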