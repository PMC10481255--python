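"""Synthetic 3-D diffusion-metric maps on a common grid.

All subjects of a cohort share one template grid (a smooth white-matter blob
with a central ventricle-like cavity and smooth per-metric mean fields), so
voxel-wise cross-subject statistics need no registration.  A subject's map is

    template mean field
    + scale_m * L_m                (uniform within WM; L from the cohort table)
    - direction_m * penumbra(d)    (optional graded degradation near lesions)
    + N(0, sigma_vox)              (voxel noise)

clipped to the metric's legal range.  FA/NDI/ODI live in [0, 1]; MD in
mm^2/s at order 1e-3.  ``scale_m`` converts one latent SD into metric units;
voxel noise defaults to 0.2 x scale so the latent signal dominates the
z-scored summary (see docs/methods.md for the calibration budget).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import METRICS, GridSpec, PenumbraConfig

__all__ = [
    "Template",
    "make_template",
    "place_lesions",
    "render_subject_maps",
    "render_cohort_maps",
    "LATENT_SCALE",
    "METRIC_RANGE",
]

#: metric units per latent SD (uniform-in-WM shift)
LATENT_SCALE = {"FA": 0.03, "MD": 3.0e-5, "NDI": 0.04, "ODI": 0.03}
#: voxel-noise SD as a fraction of the latent scale
NOISE_RATIO = 0.2
#: template mean level in WM and spatial SD of the smooth mean field
_FIELD_LEVEL = {"FA": (0.45, 0.05), "MD": (8.0e-4, 5.0e-5), "NDI": (0.60, 0.05), "ODI": (0.25, 0.04)}
METRIC_RANGE = {
    "FA": (0.0, 1.0),
    "MD": (0.0, np.inf),
    "NDI": (0.0, 1.0),
    "ODI": (0.0, 1.0),
}
#: sign of the degradation direction: FA/NDI fall, MD/ODI rise
_DEGRADE_SIGN = {"FA": -1.0, "MD": 1.0, "NDI": -1.0, "ODI": 1.0}


@dataclass
class Template:
    """Common-grid template: WM mask and smooth per-metric mean fields."""

    grid: GridSpec
    wm_mask: np.ndarray  # bool, grid.shape
    mean_fields: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def wm_volume_ml(self) -> float:
        return float(self.wm_mask.sum()) * self.grid.voxel_volume_ml


def make_template(
    shape: tuple[int, int, int] = (32, 32, 32),
    voxel_mm: float = 2.5,
    seed: int = 0,
) -> Template:
    """Smooth connected WM blob (ellipsoid shell around a ventricle cavity)
    with per-metric smooth mean fields (correlation length >= 2 voxels)."""
    if any(s < 8 for s in shape):
        raise ValueError(f"each grid dimension must be >= 8, got {shape}")
    grid = GridSpec(shape=tuple(shape), voxel_mm=float(voxel_mm))
    rng = np.random.default_rng(seed)
    coords = np.indices(shape, dtype=float)
    centre = (np.asarray(shape, dtype=float) - 1) / 2
    u = [(coords[i] - centre[i]) / shape[i] for i in range(3)]  # in [-0.5, 0.5]

    # smooth radial perturbation keeps the boundary organic but connected
    perturb = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    perturb = 0.05 * perturb / max(perturb.std(), 1e-9)
    r_outer = np.sqrt((u[0] / 0.42) ** 2 + (u[1] / 0.42) ** 2 + (u[2] / 0.42) ** 2)
    r_vent = np.sqrt((u[0] / 0.14) ** 2 + (u[1] / 0.10) ** 2 + (u[2] / 0.18) ** 2)
    wm = (r_outer < 1.0 + perturb) & (r_vent > 1.0)

    # keep the largest connected component (the perturbation may shed crumbs)
    labels, nlab = ndimage.label(wm)
    if nlab > 1:
        sizes = ndimage.sum_labels(wm, labels, index=np.arange(1, nlab + 1))
        wm = labels == (1 + int(np.argmax(sizes)))

    fields = {}
    for metric in METRICS:
        level, spatial_sd = _FIELD_LEVEL[metric]
        f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.5)
        f = f / max(f.std(), 1e-9)
        lo, hi = METRIC_RANGE[metric]
        fields[metric] = np.clip(level + spatial_sd * f, lo + 0.01 * level, min(hi, 1.0) - 0.01 if np.isfinite(hi) else None)
    return Template(grid=grid, wm_mask=wm, mean_fields=fields)


_NEIGHBOURS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def place_lesions(
    wm_mask: np.ndarray,
    target_wmhv_ml: float,
    voxel_mm: float = 2.5,
    seed: int = 0,
    periventricular_bias: bool = False,
) -> np.ndarray:
    """Grow contiguous lesion blobs inside WM to a target volume.

    The realised volume equals the closest achievable voxel count (within one
    voxel-volume of the target, exactly when WM has room).  Lesion centres
    are sampled uniformly in WM, or weighted toward the blob centroid when
    ``periventricular_bias`` is set; growth is randomized Dijkstra flooding,
    which yields rounded contiguous blobs.
    """
    if target_wmhv_ml < 0:
        raise ValueError("target WMH volume must be >= 0")
    voxel_ml = voxel_mm**3 / 1000.0
    wm_volume = float(wm_mask.sum()) * voxel_ml
    if target_wmhv_ml >= wm_volume:
        raise ValueError(
            f"target WMH volume {target_wmhv_ml:.2f} mL exceeds WM volume {wm_volume:.2f} mL"
        )
    lesion = np.zeros_like(wm_mask, dtype=bool)
    target_vox = int(round(target_wmhv_ml / voxel_ml))
    if target_vox == 0:
        return lesion

    rng = np.random.default_rng(seed)
    wm_idx = np.argwhere(wm_mask)
    n_centres = max(1, min(1 + rng.poisson(target_vox / 60.0), target_vox))
    if periventricular_bias:
        centroid = wm_idx.mean(axis=0)
        d = np.linalg.norm(wm_idx - centroid, axis=1)
        w = np.exp(-d / max(d.mean(), 1e-9))
        p = w / w.sum()
    else:
        p = None
    centres = wm_idx[rng.choice(len(wm_idx), size=n_centres, replace=False, p=p)]

    shape = wm_mask.shape
    heap = [(rng.exponential(), tuple(c)) for c in centres]
    heapq.heapify(heap)
    visited = set(tuple(c) for c in centres)
    count = 0
    while heap and count < target_vox:
        key, vox = heapq.heappop(heap)
        lesion[vox] = True
        count += 1
        for off in _NEIGHBOURS:
            nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
            if (
                0 <= nb[0] < shape[0]
                and 0 <= nb[1] < shape[1]
                and 0 <= nb[2] < shape[2]
                and wm_mask[nb]
                and nb not in visited
            ):
                visited.add(nb)
                heapq.heappush(heap, (key + rng.exponential(), nb))
    return lesion


def _penumbra_weight(lesion: np.ndarray, cfg: PenumbraConfig) -> np.ndarray:
    """Linear proximity ramp: cfg.amplitude at the lesion edge, 0 beyond."""
    if cfg.distance_vox <= 0 or cfg.amplitude == 0 or not lesion.any():
        return np.zeros(lesion.shape)
    d = ndimage.distance_transform_edt(~lesion)
    return cfg.amplitude * np.clip(1.0 - d / cfg.distance_vox, 0.0, 1.0)


def render_subject_maps(
    template: Template,
    latents: dict[str, float],
    lesion_mask: np.ndarray | None = None,
    penumbra: PenumbraConfig | None = None,
    seed: int = 0,
    noise_ratio: float = NOISE_RATIO,
) -> dict[str, np.ndarray]:
    """Render one subject's metric maps (see module docstring for the model)."""
    unknown = set(latents) - set(METRICS)
    if unknown:
        raise ValueError(f"unknown metrics in latents: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    pen = np.zeros(template.grid.shape)
    if penumbra is not None and lesion_mask is not None:
        pen = _penumbra_weight(lesion_mask, penumbra)
    out = {}
    for metric, L in latents.items():
        scale = LATENT_SCALE[metric]
        sigma = noise_ratio * scale
        # degradation direction: FA/NDI fall near lesions, MD/ODI rise
        vol = template.mean_fields[metric] + scale * (L + _DEGRADE_SIGN[metric] * pen)
        if sigma > 0:
            vol = vol + sigma * rng.standard_normal(template.grid.shape)
        lo, hi = METRIC_RANGE[metric]
        out[metric] = np.clip(vol, lo, hi if np.isfinite(hi) else None)
    return out


def render_cohort_maps(
    template: Template,
    latents: "np.ndarray | dict[str, np.ndarray]",
    seed: int = 0,
    noise_ratio: float = NOISE_RATIO,
    dtype=np.float32,
) -> dict[str, np.ndarray]:
    """Vectorized no-penumbra render: per metric an (n_subjects, n_voxels)
    array over the flattened grid.  Used by the replication machinery."""
    rng = np.random.default_rng(seed)
    nvox = int(np.prod(template.grid.shape))
    out = {}
    for metric in METRICS:
        L = np.asarray(latents[metric], dtype=float)
        scale = LATENT_SCALE[metric]
        base = template.mean_fields[metric].reshape(1, nvox).astype(dtype)
        maps = base + (scale * L)[:, None].astype(dtype)
        if noise_ratio > 0:
            maps = maps + (noise_ratio * scale) * rng.standard_normal(
                (len(L), nvox), dtype=dtype
            )
        lo, hi = METRIC_RANGE[metric]
        np.clip(maps, lo, hi if np.isfinite(hi) else None, out=maps)
        out[metric] = maps
    return out
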