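"""Normative voxel-wise reference model and standardized NAWM summaries.

A "healthy" reference is fitted from the subjects with very little lesion
load (WMH volume < 1 mL): at every voxel and for every diffusion metric the
mean and sample SD (n-1 denominator) are computed over the reference
subjects whose own NAWM mask covers that voxel.  Any subject's map is then
expressed voxel-wise as z = (value - mean) / SD, and the mean z over the
subject's NAWM mask is the standardized outcome used by the regression
battery.  Voxels with too few reference subjects (n < n_min) or an SD below
the floor are unusable and are excluded from subject means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import METRICS, GridSpec

log = logging.getLogger(__name__)

__all__ = ["select_reference", "NormativeReference", "mean_z_over_mask"]


def select_reference(wmhv_ml, threshold_ml: float = 1.0) -> np.ndarray:
    """Boolean selector of reference subjects: WMH volume strictly < threshold."""
    wmhv = np.asarray(wmhv_ml, dtype=float)
    sel = wmhv < threshold_ml
    if not sel.any():
        raise ValueError(
            f"no subject has WMH volume < {threshold_ml} mL; "
            "increase the reference threshold"
        )
    return sel


@dataclass
class NormativeReference:
    """Fitted voxel-wise healthy reference (mean/SD/coverage per metric).

    Arrays are flattened over the grid (length ``n_voxels``).  Build with
    :meth:`fit`; apply with :meth:`zscore` and :meth:`summarize`.
    """

    grid: GridSpec
    threshold_ml: float
    subject_ids: list[str]
    n_min: int = 10
    sd_floor: float = 1e-6
    mean: dict[str, np.ndarray] = field(default_factory=dict)
    sd: dict[str, np.ndarray] = field(default_factory=dict)
    n: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def fit(
        cls,
        maps: dict[str, np.ndarray],
        nawm_masks: np.ndarray,
        subject_ids,
        grid: GridSpec,
        threshold_ml: float = 1.0,
        n_min: int = 10,
        sd_floor: float = 1e-6,
    ) -> "NormativeReference":
        """Fit from reference subjects' maps.

        Parameters
        ----------
        maps : per metric an (n_ref, n_voxels) array (flattened grid).
        nawm_masks : (n_ref, n_voxels) boolean; each reference subject
            contributes only where its own NAWM mask covers.
        """
        nawm_masks = np.asarray(nawm_masks, dtype=bool)
        n_ref = nawm_masks.shape[0]
        if n_ref < 2:
            raise ValueError(f"need >= 2 reference subjects, got {n_ref}")
        self = cls(
            grid=grid,
            threshold_ml=threshold_ml,
            subject_ids=list(subject_ids),
            n_min=n_min,
            sd_floor=sd_floor,
        )
        m = nawm_masks.astype(np.float64)
        nv = m.sum(axis=0)
        for metric, stack in maps.items():
            if metric not in METRICS:
                raise ValueError(f"unknown metric {metric!r}")
            x = np.asarray(stack, dtype=np.float64)
            with np.errstate(invalid="ignore", divide="ignore"):
                s1 = np.einsum("sv,sv->v", m, x)
                s2 = np.einsum("sv,sv->v", m, x * x)
                mean = s1 / nv
                var = (s2 - nv * mean**2) / (nv - 1)
            var = np.where(nv >= 2, np.clip(var, 0.0, None), np.nan)
            self.mean[metric] = np.where(nv >= 1, mean, np.nan)
            self.sd[metric] = np.sqrt(var)
            self.n[metric] = nv.astype(np.int32)
        return self

    def usable(self, metric: str) -> np.ndarray:
        """Voxels with enough coverage and non-degenerate SD."""
        sd = self.sd[metric]
        with np.errstate(invalid="ignore"):
            return (self.n[metric] >= self.n_min) & (sd >= self.sd_floor)

    def zscore(self, values: np.ndarray, metric: str) -> np.ndarray:
        """Voxel-wise z-map; unusable voxels are NaN.

        ``values`` may be a single flattened map (n_voxels,) or a stack
        (n_subjects, n_voxels).
        """
        values = np.asarray(values, dtype=np.float64)
        if values.shape[-1] != int(np.prod(self.grid.shape)):
            raise ValueError(
                f"grid mismatch: map has {values.shape[-1]} voxels, "
                f"model grid {self.grid.shape}"
            )
        ok = self.usable(metric)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (values - self.mean[metric]) / self.sd[metric]
        return np.where(ok, z, np.nan)

    def summarize(
        self,
        maps: dict[str, np.ndarray],
        nawm_masks: np.ndarray,
        subject_ids,
    ) -> pd.DataFrame:
        """Per-subject mean NAWM z per metric plus voxel counts.

        Returns a DataFrame with columns ``subject_id``, ``nawm_voxel_count``,
        ``<metric>_z`` and ``<metric>_usable`` for each metric present.
        """
        nawm_masks = np.asarray(nawm_masks, dtype=bool)
        out = pd.DataFrame({"subject_id": list(subject_ids)})
        out["nawm_voxel_count"] = nawm_masks.sum(axis=1)
        for metric, stack in maps.items():
            # restrict to usable voxels up front: the (subjects x voxels)
            # arithmetic then runs on the usable submatrix only
            ok = self.usable(metric)
            x = np.asarray(stack)[:, ok]
            finite = np.isfinite(x)
            z = (x - self.mean[metric][ok]) / self.sd[metric][ok]
            valid = nawm_masks[:, ok] & finite
            usable = valid.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_z = np.where(
                    usable > 0,
                    np.einsum("sv,sv->s", valid.astype(np.float64), np.where(valid, z, 0.0))
                    / usable,
                    np.nan,
                )
            n_missing = int((usable == 0).sum())
            if n_missing:
                log.warning(
                    "%s: %d subjects have zero usable NAWM voxels; summary missing",
                    metric,
                    n_missing,
                )
            out[f"{metric.lower()}_z"] = mean_z
            out[f"{metric.lower()}_usable"] = usable
        return out

    # -- persistence --------------------------------------------------------

    def save(self, outdir) -> Path:
        """Persist as NIfTI volumes (mean/SD/n per metric) + JSON sidecar."""
        from .niftiio import save_volume

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for metric in self.mean:
            for kind, arr in (("mean", self.mean), ("sd", self.sd), ("n", self.n)):
                save_volume(
                    np.asarray(arr[metric]).reshape(self.grid.shape),
                    self.grid,
                    outdir / f"reference_{metric}_{kind}.nii.gz",
                )
        sidecar = {
            "threshold_ml": self.threshold_ml,
            "subject_ids": self.subject_ids,
            "n_min": self.n_min,
            "sd_floor": self.sd_floor,
            "shape": list(self.grid.shape),
            "voxel_mm": self.grid.voxel_mm,
            "metrics": sorted(self.mean),
        }
        with open(outdir / "reference_model.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
        return outdir

    @classmethod
    def load(cls, outdir) -> "NormativeReference":
        from .niftiio import load_volume

        outdir = Path(outdir)
        with open(outdir / "reference_model.json") as fh:
            sc = json.load(fh)
        grid = GridSpec(shape=tuple(sc["shape"]), voxel_mm=sc["voxel_mm"])
        self = cls(
            grid=grid,
            threshold_ml=sc["threshold_ml"],
            subject_ids=sc["subject_ids"],
            n_min=sc["n_min"],
            sd_floor=sc["sd_floor"],
        )
        nvox = int(np.prod(grid.shape))
        for metric in sc["metrics"]:
            self.mean[metric] = load_volume(outdir / f"reference_{metric}_mean.nii.gz")[0].reshape(nvox)
            self.sd[metric] = load_volume(outdir / f"reference_{metric}_sd.nii.gz")[0].reshape(nvox)
            self.n[metric] = load_volume(outdir / f"reference_{metric}_n.nii.gz")[0].reshape(nvox)
        return self


def mean_z_over_mask(zmap: np.ndarray, nawm_mask: np.ndarray) -> tuple[float, int]:
    """Arithmetic mean of z over usable NAWM voxels, with the usable count.

    Missing (NaN) voxels are excluded from numerator and denominator; if no
    usable voxel remains the summary is NaN (reason logged).
    """
    nawm_mask = np.asarray(nawm_mask, dtype=bool)
    if not nawm_mask.any():
        raise ValueError("NAWM mask is empty")
    vals = np.asarray(zmap, dtype=float)[nawm_mask]
    usable = int(np.isfinite(vals).sum())
    if usable == 0:
        log.warning("no usable voxels under the NAWM mask; mean z is missing")
        return float("nan"), 0
    return float(np.nanmean(vals)), usable
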