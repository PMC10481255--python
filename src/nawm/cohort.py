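"""Synthetic cohort generator.

Draws subject tables with the statistical structure the downstream analysis
assumes: demographics and genetics of a single-birth-week cohort imaged at
~age 70, imaging scalars (WMH volume, whole-brain and intracranial volume,
amyloid SUVR), cognition, a five-wave adult blood-pressure history — and a
per-metric latent white-matter-integrity factor

    L_m = sum_j beta_(j,m) * z(x_j) + eps_m,     Var(L_m) = 1,

whose standardized effects ``beta`` are declared in
:class:`nawm.config.EffectConfig`.  Binary predictors enter as centred
indicators (so their beta is a group difference); continuous predictors as
empirical z-scores, matching how the regression battery standardizes them.
The latent residual ``eps`` is correlated across the four diffusion metrics
(one underlying tissue state) and is the hook for the antithetic replication
design (``noise_sign``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import METRICS, WAVES, ConfigurationError, EffectConfig, WaveParams
from .vascular import add_lifecourse_columns

__all__ = ["draw_cohort", "draw_vascular_history", "apply_mcar"]

# per-variable-family substreams: adding subjects must not reshuffle the
# values drawn for existing ones, so every family gets its own stream
_STREAMS = {
    "sex": 1,
    "age": 2,
    "education": 3,
    "sep": 4,
    "apoe": 5,
    "cognition": 6,
    "wmhv": 7,
    "volumes": 8,
    "suvr": 9,
    "vascular": 10,
    "latent": 11,
}


def _rng(seed: int, family: str, sub: int = 0) -> np.random.Generator:
    """One stream per (variable family, sub-draw).

    Each stream is consumed by exactly one array draw whose leading axis is
    the subject index, so growing the cohort never reshuffles the values
    already drawn for the first ``n`` subjects.
    """
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[family], sub))
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd < 1e-12:
        raise ConfigurationError("cannot standardize a constant predictor")
    return (x - np.mean(x)) / sd


_BINARY_PREDICTORS = {"sex_female", "abeta", "apoe_e4", "parental_sep"}

#: analysis-table column backing each latent predictor name
_PREDICTOR_SOURCE = {
    "log_wmhv": "wmhv_ml",
    "wbv": "wbv_ml",
    "tiv": "tiv_ml",
    "abeta": "abeta_true",
    "suvr": "suvr",
    "sex_female": "sex",
    "age": "age_at_scan",
    "childhood_cog": "childhood_cog",
    "education": "education",
    "parental_sep": "parental_sep",
    "apoe_e4": "apoe_e4",
    "pacc": "pacc",
    "mmse": "mmse",
    "logical_memory": "logical_memory",
    "digit_symbol": "digit_symbol",
    "face_name": "face_name",
}


def _predictor_value(name: str, df: pd.DataFrame) -> np.ndarray:
    """Centred-indicator or z-scored predictor values used inside L."""
    col = _PREDICTOR_SOURCE.get(name, name)  # vascular names map 1:1
    if col not in df.columns:
        raise ConfigurationError(f"latent predictor {name!r} has no source column")
    x = df[col].to_numpy(dtype=float)
    if name == "log_wmhv":
        x = np.log(x)
    if name in _BINARY_PREDICTORS:
        return x - x.mean()
    return _zscore(x)


# ---------------------------------------------------------------------------
# vascular history

def _draw_vascular(config: EffectConfig, sex: np.ndarray, seed: int) -> pd.DataFrame:
    """Five-wave BP/BMI/risk-factor history for the whole cohort.

    Continuous trajectories share a per-subject factor (persistence), binary
    risk factors use a shared-quantile construction so smoking only declines
    and diabetes/treatment only accrue as prevalences change across waves.
    """
    n = len(sex)
    out = {}
    female = sex == 1
    nw = len(WAVES)
    for sub, (measure, persistence) in enumerate(
        (("sbp", config.bp_persistence), ("dbp", config.bp_persistence))
    ):
        # column 0: subject factor; 1..nw: wave innovations; nw+1..: reading noise
        Z = _rng(seed, "vascular", sub).standard_normal((n, 1 + 2 * nw))
        u = Z[:, 0]
        for i, w in enumerate(WAVES):
            wp: WaveParams = config.waves[w]
            mean = np.where(
                female,
                getattr(wp, f"{measure}_mean_female"),
                getattr(wp, f"{measure}_mean_male"),
            )
            sd = getattr(wp, f"{measure}_sd")
            true = mean + sd * (
                np.sqrt(persistence) * u + np.sqrt(1 - persistence) * Z[:, 1 + i]
            )
            out[f"{measure}_{w}_r1"] = true
            out[f"{measure}_{w}_r2"] = true + config.reading_noise_sd * Z[:, 1 + nw + i]
    Zb = _rng(seed, "vascular", 2).standard_normal((n, 1 + nw))
    for i, w in enumerate(WAVES):
        wp = config.waves[w]
        out[f"bmi_{w}"] = np.clip(
            wp.bmi_mean
            + wp.bmi_sd
            * (
                np.sqrt(config.bmi_persistence) * Zb[:, 0]
                + np.sqrt(1 - config.bmi_persistence) * Zb[:, 1 + i]
            ),
            15.0,
            None,
        )
    U = _rng(seed, "vascular", 3).uniform(size=(n, 3))
    for j, (factor, attr) in enumerate(
        (
            ("smoking", "smoking_prev"),
            ("diabetes", "diabetes_prev"),
            ("antihtn", "antihypertensive_prev"),
        )
    ):
        for w in WAVES:
            prev = getattr(config.waves[w], attr)
            out[f"{factor}_{w}"] = (U[:, j] < prev).astype(int)
    return pd.DataFrame(out)


def draw_vascular_history(config: EffectConfig, sex: int, seed: int = 0) -> dict:
    """One subject's vascular history (thin wrapper over the cohort draw)."""
    df = _draw_vascular(config, np.asarray([sex]), seed)
    return {k: df[k].iloc[0] for k in df.columns}


# ---------------------------------------------------------------------------
# cohort

def draw_cohort(config: EffectConfig) -> pd.DataFrame:
    """Draw ``config.n`` subjects; deterministic for a fixed ``config.seed``.

    Returns a table with demographics, imaging scalars, raw vascular history
    (wave-suffixed, two readings per BP measure) and the generator-truth
    columns ``abeta_true`` and ``latent_<metric>``.
    """
    if config.n < 2:
        raise ConfigurationError("cohort size must be >= 2")
    n, seed = config.n, config.seed

    sex = (_rng(seed, "sex").uniform(size=n) < config.female_frac).astype(int)
    age = config.age_mean + config.age_sd * _rng(seed, "age").standard_normal(n)
    edu_u = _rng(seed, "education").uniform(size=n)
    cum = np.cumsum(config.education_probs)
    education = np.searchsorted(cum, edu_u).clip(0, 2)
    parental_sep = (_rng(seed, "sep").uniform(size=n) < config.sep_manual_prev).astype(int)
    apoe = (_rng(seed, "apoe").uniform(size=n) < config.apoe_prev).astype(int)

    Zc = _rng(seed, "cognition").standard_normal((n, 7))
    childhood = _zscore(Zc[:, 0])
    g = 0.5 * childhood + np.sqrt(0.75) * Zc[:, 1]
    # adult sub-test marginals follow the cohort's observed means/SDs
    subtests = {
        "mmse": (29.3, 0.9),
        "logical_memory": (11.6, 3.6),
        "digit_symbol": (48.7, 10.2),
        "face_name": (66.9, 17.1),
    }
    cog_cols = {}
    for j, (name, (mu, sd)) in enumerate(subtests.items()):
        cog_cols[name] = mu + sd * (0.6 * g + np.sqrt(1 - 0.36) * Zc[:, 2 + j])
    pacc = 0.1 + 0.7 * _zscore(0.85 * g + np.sqrt(1 - 0.85**2) * Zc[:, 6])

    wmhv = np.exp(
        config.wmhv_log_mean + config.wmhv_log_sd * _rng(seed, "wmhv").standard_normal(n)
    )

    Zv = _rng(seed, "volumes").standard_normal((n, 2))
    z_tiv = Zv[:, 0]
    r = config.tiv_wbv_corr
    z_wbv = r * z_tiv + np.sqrt(1 - r * r) * Zv[:, 1]
    female = sex == 1
    tiv = np.where(
        female,
        config.tiv_mean_female + config.tiv_sd_female * z_tiv,
        config.tiv_mean_male + config.tiv_sd_male * z_tiv,
    )
    wbv = np.where(
        female,
        config.wbv_mean_female + config.wbv_sd_female * z_wbv,
        config.wbv_mean_male + config.wbv_sd_male * z_wbv,
    )
    # guard the physical ordering TIV > WBV > 0 (violations are ~5-sigma events)
    wbv = np.clip(wbv, 1.0, tiv - 1.0)

    high = _rng(seed, "suvr", 0).uniform(size=n) < config.suvr.pi_high
    z_suvr = _rng(seed, "suvr", 1).standard_normal(n)
    suvr = np.where(
        high,
        config.suvr.mu_high + config.suvr.sigma_high * z_suvr,
        config.suvr.mu_low + config.suvr.sigma_low * z_suvr,
    )
    suvr = np.clip(suvr, 1e-3, None)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "sex": sex,
            "age_at_scan": age,
            "education": education,
            "parental_sep": parental_sep,
            "apoe_e4": apoe,
            "childhood_cog": childhood,
            "pacc": pacc,
            **cog_cols,
            "wmhv_ml": wmhv,
            "wbv_ml": wbv,
            "tiv_ml": tiv,
            "suvr": suvr,
            "abeta_true": high.astype(int),
        }
    )
    df = pd.concat([df, _draw_vascular(config, sex, seed)], axis=1)

    # latent integrity factors need the derived life-course predictors
    derived = add_lifecourse_columns(df)
    structural = {m: np.zeros(n) for m in METRICS}
    all_effects: dict[tuple[str, str], tuple[float, float]] = {
        key: (b, b) for key, b in config.effects.items()
    }
    all_effects.update(config.sex_effects)
    for (pred, metric), (b_male, b_female) in all_effects.items():
        v = _predictor_value(pred, derived)
        beta = np.where(female, b_female, b_male)
        structural[metric] = structural[metric] + beta * v

    Zl = _rng(seed, "latent").standard_normal((n, 1 + len(METRICS)))
    shared = Zl[:, 0]
    rho = config.latent_corr
    for k, metric in enumerate(METRICS):
        eps = np.sqrt(rho) * shared + np.sqrt(1 - rho) * Zl[:, 1 + k]
        if n > 2:
            eps = _zscore(eps)  # empirical unit variance keeps Var(L) on target
        explained = float(np.var(structural[metric], ddof=1)) if n > 1 else 0.0
        eps_sd = np.sqrt(max(1.0 - explained, 0.05))
        df[f"latent_{metric.lower()}"] = (
            structural[metric] + config.noise_sign * eps_sd * eps
        )
    return df


def apply_mcar(
    df: pd.DataFrame, n_available: dict[str, int], seed: int = 0
) -> pd.DataFrame:
    """Optional missing-completely-at-random mask.

    Blanks random entries of each named column so that exactly
    ``n_available[col]`` values remain, emulating per-variable availability
    in an available-case analysis.  Off by default everywhere.
    """
    out = df.copy()
    rng = np.random.default_rng(seed)
    for col, keep in n_available.items():
        if keep > len(df):
            raise ConfigurationError(
                f"n_available[{col!r}]={keep} exceeds cohort size {len(df)}"
            )
        drop = rng.choice(len(df), size=len(df) - keep, replace=False)
        out.loc[out.index[drop], col] = np.nan
    return out
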