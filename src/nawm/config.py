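"""Configuration objects for the synthetic cohort and the pipeline.

The synthetic generator is organised around a per-metric latent integrity
factor ``L``: each subject's deviation from the healthy template, in SD units
of the cohort, is a linear combination of standardized predictors plus a
residual.  ``EffectConfig`` declares those standardized effects — SD of
outcome per SD of predictor — together with the marginal distributions of the
cohort (age, sex split, WMH volume, SUVR mixture, blood-pressure
trajectories).  Defaults reproduce the marginals of a British 1946 birth
cohort imaged at ~age 70 (n=362, ~49% female, age 70.6 +/- 0.7) and encode
the study-scale standardized associations between predictors and
white-matter integrity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

METRICS = ("FA", "MD", "NDI", "ODI")

#: analysis waves for the life-course vascular measures
WAVES = ("36", "43", "53", "60_64", "69")
#: nominal age at each wave (birth cohort: everyone is the same age at a wave)
WAVE_AGES = {"36": 36.0, "43": 43.0, "53": 53.0, "60_64": 62.0, "69": 69.0}

_CHANGE_INTERVALS = tuple(
    f"{a}_{b}" for a, b in zip(WAVES[:-1], WAVES[1:])
)  # 36_43, 43_53, 53_60_64, 60_64_69

#: predictors the latent-effect map may reference
KNOWN_PREDICTORS = (
    ("log_wmhv", "wbv", "abeta", "suvr", "tiv")
    + ("sex_female", "age", "childhood_cog", "education", "parental_sep", "apoe_e4")
    + ("pacc", "mmse", "logical_memory", "digit_symbol", "face_name")
    + tuple(f"fhs_{w}" for w in ("36", "53", "69"))
    + tuple(f"sbp_{w}" for w in WAVES)
    + tuple(f"dbp_{w}" for w in WAVES)
    + tuple(f"sbp_change_{i}" for i in _CHANGE_INTERVALS)
    + tuple(f"dbp_change_{i}" for i in _CHANGE_INTERVALS)
)


class ConfigurationError(ValueError):
    """Invalid generator or pipeline configuration."""


@dataclass(frozen=True)
class WaveParams:
    """Marginal distribution of one vascular wave."""

    sbp_mean_male: float
    sbp_mean_female: float
    sbp_sd: float
    dbp_mean_male: float
    dbp_mean_female: float
    dbp_sd: float
    bmi_mean: float
    bmi_sd: float
    smoking_prev: float
    diabetes_prev: float
    antihypertensive_prev: float


def _default_waves() -> dict[str, WaveParams]:
    # SBP/DBP means and SDs follow the cohort's published wave summaries;
    # smoking declines and treatment/diabetes rise across adulthood.
    return {
        "36": WaveParams(125.6, 113.7, 13.7, 81.2, 75.0, 9.9, 23.5, 3.0, 0.35, 0.01, 0.02),
        "43": WaveParams(129.0, 118.9, 14.0, 83.2, 77.4, 8.9, 24.5, 3.5, 0.30, 0.02, 0.04),
        "53": WaveParams(137.9, 128.6, 19.4, 86.6, 79.4, 11.9, 26.5, 4.0, 0.22, 0.04, 0.12),
        "60_64": WaveParams(138.3, 131.2, 17.0, 78.7, 75.1, 9.5, 27.0, 4.2, 0.14, 0.07, 0.25),
        "69": WaveParams(134.1, 130.3, 16.2, 74.1, 72.3, 10.2, 27.3, 4.2, 0.08, 0.10, 0.35),
    }


@dataclass(frozen=True)
class SuvrMixtureParams:
    """Two-component Gaussian SUVR mixture (low = amyloid-negative mode)."""

    mu_low: float = 1.0
    sigma_low: float = 0.03
    mu_high: float = 1.3
    sigma_high: float = 0.1
    pi_high: float = 0.16


# -- default standardized effects -------------------------------------------
# (predictor, metric) -> SD of latent integrity per SD of predictor.  These
# are the study-scale associations: WMH burden degrades FA/NDI and raises MD;
# late-life cardiovascular risk does the same at smaller magnitude; female sex
# and older age at scan carry nuisance-scale effects (models always adjust
# for both, so their exact size is immaterial to recovery of the others).
_DEFAULT_EFFECTS: dict[tuple[str, str], float] = {
    ("log_wmhv", "FA"): -0.09,
    ("log_wmhv", "NDI"): -0.17,
    ("log_wmhv", "MD"): 0.14,
    ("wbv", "FA"): 0.05,
    ("fhs_69", "FA"): -0.06,
    ("fhs_69", "NDI"): -0.10,
    ("fhs_69", "MD"): 0.09,
    ("sex_female", "FA"): -0.15,
    ("sex_female", "ODI"): 0.15,
    ("age", "FA"): -0.07,
    ("age", "NDI"): -0.07,
    ("age", "MD"): 0.07,
}

# male-only amyloid effect: (beta_male, beta_female)
_DEFAULT_SEX_EFFECTS: dict[tuple[str, str], tuple[float, float]] = {
    ("abeta", "FA"): (-0.04, 0.0),
    ("abeta", "MD"): (0.06, 0.0),
}


@dataclass(frozen=True)
class EffectConfig:
    """Declares the synthetic cohort: size, marginals and true effects.

    Parameters
    ----------
    n : cohort size.
    seed : RNG seed for :func:`nawm.cohort.draw_cohort`.
    effects : map ``(predictor, metric) -> beta`` of standardized effects on
        the latent integrity factor of that metric.
    sex_effects : map ``(predictor, metric) -> (beta_male, beta_female)``;
        overrides ``effects`` for that pair and lets slopes differ by sex.
    latent_corr : correlation of the residual integrity component across
        metrics (the four metrics index one underlying tissue state).
    noise_sign : +1 or -1; multiplies the latent residual.  Used by the
        antithetic replication design (see :func:`nawm.pipeline.replicate_study`).
    """

    n: int = 362
    seed: int = 0
    effects: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS)
    )
    sex_effects: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SEX_EFFECTS)
    )
    latent_corr: float = 0.7
    noise_sign: int = 1

    # cohort marginals
    female_frac: float = 179 / 362
    age_mean: float = 70.6
    age_sd: float = 0.7
    # log-normal WMH volume matched to median 2.9 mL (q1 1.6, q3 6.1)
    wmhv_log_mean: float = float(np.log(2.9))
    wmhv_log_sd: float = float((np.log(6.1) - np.log(1.6)) / (2 * 0.674489750196082))
    wbv_mean_male: float = 1158.5
    wbv_mean_female: float = 1051.6
    wbv_sd_male: float = 84.9
    wbv_sd_female: float = 80.8
    tiv_mean_male: float = 1522.6
    tiv_mean_female: float = 1343.5
    tiv_sd_male: float = 105.8
    tiv_sd_female: float = 94.4
    tiv_wbv_corr: float = 0.8
    suvr: SuvrMixtureParams = field(default_factory=SuvrMixtureParams)
    apoe_prev: float = 0.30
    sep_manual_prev: float = 0.43
    education_probs: tuple[float, float, float] = (0.16, 0.30, 0.54)

    # vascular trajectory structure
    waves: Mapping[str, WaveParams] = field(default_factory=_default_waves)
    bp_persistence: float = 0.5
    bmi_persistence: float = 0.7
    reading_noise_sd: float = 3.0

    def __post_init__(self) -> None:
        for key in list(self.effects) + list(self.sex_effects):
            pred, metric = key
            if metric not in METRICS:
                raise ConfigurationError(
                    f"unknown metric {metric!r} in effect key {key!r}; "
                    f"metrics are {METRICS}"
                )
            if pred not in KNOWN_PREDICTORS:
                raise ConfigurationError(
                    f"unknown predictor {pred!r} in effect key {key!r}"
                )
        if not 0 <= self.latent_corr < 1:
            raise ConfigurationError("latent_corr must be in [0, 1)")
        if self.noise_sign not in (-1, 1):
            raise ConfigurationError("noise_sign must be +1 or -1")
        missing = [w for w in WAVES if w not in self.waves]
        if missing:
            raise ConfigurationError(f"missing wave parameters for waves {missing}")

    def replace(self, **kw) -> "EffectConfig":
        return replace(self, **kw)

    @classmethod
    def null(cls, n: int = 362, seed: int = 0) -> "EffectConfig":
        """All true effects zero — for type-I calibration runs."""
        return cls(n=n, seed=seed, effects={}, sex_effects={})

    @classmethod
    def sex_interaction_scenario(cls, n: int = 362, seed: int = 0) -> "EffectConfig":
        """Female-only midlife systolic-BP effect on FA/NDI (and MD, reversed).

        The magnitude (|beta| = 0.5 SD/SD in women, 0 in men) is set by an
        a-priori power analysis so the qualitative pattern — significant
        interaction, negative female slope, null male slope — is reliably
        detectable at n=362 (see docs/methods.md).
        """
        cfg = cls(n=n, seed=seed)
        sx = dict(cfg.sex_effects)
        sx[("sbp_53", "FA")] = (0.0, -0.5)
        sx[("sbp_53", "NDI")] = (0.0, -0.5)
        sx[("sbp_53", "MD")] = (0.0, 0.5)
        return cfg.replace(sex_effects=sx)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["effects"] = {f"{p}:{m}": v for (p, m), v in self.effects.items()}
        d["sex_effects"] = {
            f"{p}:{m}": list(v) for (p, m), v in self.sex_effects.items()
        }
        d["waves"] = {w: dataclasses.asdict(wp) for w, wp in self.waves.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EffectConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["effects"] = {
            tuple(k.split(":")): float(v) for k, v in d.get("effects", {}).items()
        }
        d["sex_effects"] = {
            tuple(k.split(":")): tuple(v) for k, v in d.get("sex_effects", {}).items()
        }
        d["suvr"] = SuvrMixtureParams(**d["suvr"])
        d["waves"] = {w: WaveParams(**wp) for w, wp in d["waves"].items()}
        d["education_probs"] = tuple(d["education_probs"])
        return cls(**d)


@dataclass(frozen=True)
class PenumbraConfig:
    """Graded integrity degradation within ``distance_vox`` of lesion voxels.

    ``amplitude`` is in latent-SD units at the lesion boundary, decaying
    linearly to zero at ``distance_vox``; FA/NDI are lowered, MD raised,
    ODI raised.  ``distance_vox = 0`` disables the term.
    """

    distance_vox: float = 0.0
    amplitude: float = 0.0


@dataclass(frozen=True)
class GridSpec:
    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_mm: float = 2.5

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_mm**3 / 1000.0


@dataclass(frozen=True)
class ErosionSpec:
    """Morphological erosion: ``radius`` voxels with 6- or 26-connectivity."""

    radius: int = 1
    connectivity: int = 6

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ConfigurationError("erosion radius must be >= 0")
        if self.connectivity not in (6, 26):
            raise ConfigurationError("connectivity must be 6 or 26")


@dataclass(frozen=True)
class EMConfig:
    """EM settings for the two-component SUVR mixture."""

    n_restarts: int = 10
    tol: float = 1e-8
    max_iter: int = 500
    sigma_floor: float = 1e-6
    equal_variance: bool = False
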