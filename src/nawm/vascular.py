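"""Life-course cardiovascular predictors.

Blood pressure was measured twice per visit across five adult waves (ages
36, 43, 53, 60–64 and 69); the second reading is used for analysis unless
only one is available.  Early-adulthood readings from a random-zero
sphygmomanometer can be mapped to the later digital device with linear
conversion equations supplied as configuration.  From these the module
builds:

* sex-specific conditional BP *change residuals* — the residual of each
  later wave's BP regressed (OLS, with intercept) on all earlier waves'
  BP within sex, standardized to mean 0 / SD 1 within sex, representing
  change beyond what the earlier trajectory predicts;
* a Framingham-style 10-year cardiovascular risk percentage from a weighted
  sum of log age, log BMI, log SBP (treated/untreated), smoking and
  diabetes, with sex-specific coefficients shipped as a versioned YAML
  config (the office-based, non-laboratory profile).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .config import WAVES, WAVE_AGES, ConfigurationError

log = logging.getLogger(__name__)

#: waves with enough history to define a conditional change (everything after 36)
CHANGE_TARGET_WAVES = WAVES[1:]
#: waves at which the risk score is computed
RISK_WAVES = ("36", "53", "69")


# ---------------------------------------------------------------------------
# reading selection and device conversion

def select_reading(reading1, reading2):
    """Second reading if present, else the first; NaN if both missing.

    Accepts scalars or array-likes (element-wise).
    """
    r1 = np.asarray(reading1, dtype=float)
    r2 = np.asarray(reading2, dtype=float)
    out = np.where(np.isnan(r2), r1, r2)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class DeviceConversion:
    """Linear reading conversion ``a * bp + b`` for one measure."""

    a: float = 1.0
    b: float = 0.0

    def apply(self, bp):
        return self.a * np.asarray(bp, dtype=float) + self.b


def convert_device(bp, conversion: DeviceConversion | None):
    """Apply a linear device-conversion equation; identity if None."""
    if conversion is None:
        return np.asarray(bp, dtype=float)
    if not isinstance(conversion, DeviceConversion):
        raise ConfigurationError(
            "device conversion must be a DeviceConversion (a, b) or None"
        )
    return conversion.apply(bp)


# ---------------------------------------------------------------------------
# conditional change residuals

def conditional_change_residuals(
    bp: pd.DataFrame,
    sex: pd.Series,
    waves: tuple[str, ...] = WAVES,
    all_earlier: bool = True,
) -> pd.DataFrame:
    """Sex-specific standardized conditional change residuals.

    Parameters
    ----------
    bp : DataFrame with one column per wave (columns named by wave id,
        e.g. ``"36", "43", ...``), analysis-ready BP values.
    sex : binary series aligned to ``bp`` (female = 1).
    all_earlier : regress each target wave on *all* earlier waves (default)
        or only on the immediately preceding wave.

    Returns
    -------
    DataFrame with one column per interval, named ``change_<from>_<to>``
    (e.g. ``change_43_53`` for the wave-43 -> wave-53 interval).  Only
    subjects complete at all waves get values; others are NaN.
    """
    missing_cols = [w for w in waves if w not in bp.columns]
    if missing_cols:
        raise ConfigurationError(f"missing BP columns for waves {missing_cols}")
    complete = bp[list(waves)].notna().all(axis=1)
    out = pd.DataFrame(index=bp.index)
    for i, target in enumerate(waves[1:], start=1):
        earlier = list(waves[:i]) if all_earlier else [waves[i - 1]]
        col = f"change_{waves[i - 1]}_{target}"
        res = pd.Series(np.nan, index=bp.index)
        for s in (0, 1):
            rows = complete & (sex == s)
            nrow = int(rows.sum())
            if nrow < len(earlier) + 2:
                raise ConfigurationError(
                    f"sex stratum {s}: {nrow} complete subjects for wave {target} "
                    f"regression on {len(earlier)} earlier waves"
                )
            X = np.column_stack(
                [np.ones(nrow)] + [bp.loc[rows, w].to_numpy() for w in earlier]
            )
            y = bp.loc[rows, target].to_numpy()
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            sd = r.std(ddof=1)
            if sd < 1e-12:
                log.warning(
                    "wave %s, sex %d: residuals degenerate (perfect fit); "
                    "standardized change left missing",
                    target,
                    s,
                )
                continue
            res.loc[rows] = (r - r.mean()) / sd
        out[col] = res
    return out


# ---------------------------------------------------------------------------
# Framingham-style risk score

@dataclass(frozen=True)
class RiskStratum:
    s0: float
    lp_mean: float
    terms: Mapping[str, float]


@dataclass(frozen=True)
class RiskScoreConfig:
    """Sex-stratified weighted-sum 10-year risk model.

    ``risk% = 100 * (1 - s0 ** exp(lp - lp_mean))`` with
    ``lp = b_age*ln(age) + b_bmi*ln(bmi) + b_sbp(treated?)*ln(sbp)
    + b_smoke*smoker + b_diab*diabetes`` per sex stratum.
    """

    name: str
    male: RiskStratum
    female: RiskStratum

    def __post_init__(self) -> None:
        for st in (self.male, self.female):
            if not 0 < st.s0 < 1:
                raise ConfigurationError("baseline survival s0 must be in (0,1)")
            required = {
                "log_age",
                "log_bmi",
                "log_sbp_untreated",
                "log_sbp_treated",
                "smoker",
                "diabetes",
            }
            missing = required - set(st.terms)
            if missing:
                raise ConfigurationError(f"risk config missing terms {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "RiskScoreConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            name=d.get("name", "custom"),
            male=RiskStratum(**d["strata"]["male"]),
            female=RiskStratum(**d["strata"]["female"]),
        )

    @classmethod
    def default(cls) -> "RiskScoreConfig":
        return _default_risk_config()


@lru_cache(maxsize=1)
def _default_risk_config() -> "RiskScoreConfig":
    ref = resources.files("nawm.data").joinpath("framingham_office_2008.yaml")
    with resources.as_file(ref) as path:
        return RiskScoreConfig.from_yaml(path)


def framingham_risk(
    sex,
    age,
    sbp,
    antihypertensive,
    smoking,
    diabetes,
    bmi,
    config: RiskScoreConfig,
):
    """10-year cardiovascular event risk, percent, element-wise.

    Rows with any missing covariate get NaN (with a logged count).
    Output is strictly inside (0, 100).
    """
    sex = np.asarray(sex, dtype=float)
    age = np.asarray(age, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    treated = np.asarray(antihypertensive, dtype=float)
    smoking = np.asarray(smoking, dtype=float)
    diabetes = np.asarray(diabetes, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    bad = (
        np.isnan(sex)
        | np.isnan(age)
        | np.isnan(sbp)
        | np.isnan(treated)
        | np.isnan(smoking)
        | np.isnan(diabetes)
        | np.isnan(bmi)
    )
    n_bad = int(np.sum(bad))
    if n_bad:
        log.info("framingham_risk: %d subjects missing covariates -> NaN", n_bad)

    out = np.full(np.broadcast(sex, sbp).shape or (1,), np.nan)
    sexb = np.broadcast_to(sex, out.shape)
    for s, stratum in ((0, "male"), (1, "female")):
        st: RiskStratum = getattr(config, stratum)
        rows = (sexb == s) & ~np.broadcast_to(bad, out.shape)
        if not rows.any():
            continue
        b = st.terms
        sbp_beta = np.where(
            np.broadcast_to(treated, out.shape)[rows] > 0,
            b["log_sbp_treated"],
            b["log_sbp_untreated"],
        )
        lp = (
            b["log_age"] * np.log(np.broadcast_to(age, out.shape)[rows])
            + b["log_bmi"] * np.log(np.broadcast_to(bmi, out.shape)[rows])
            + sbp_beta * np.log(np.broadcast_to(sbp, out.shape)[rows])
            + b["smoker"] * np.broadcast_to(smoking, out.shape)[rows]
            + b["diabetes"] * np.broadcast_to(diabetes, out.shape)[rows]
        )
        risk = 100.0 * (1.0 - st.s0 ** np.exp(lp - st.lp_mean))
        out[rows] = np.clip(risk, np.nextafter(0, 1), np.nextafter(100, 0))
    if np.isscalar(antihypertensive) and out.shape == (1,):
        return float(out[0])
    return out


# ---------------------------------------------------------------------------
# table-level derivation

def add_lifecourse_columns(
    df: pd.DataFrame,
    risk_config: RiskScoreConfig | None = None,
    conversions: Mapping[str, DeviceConversion] | None = None,
    all_earlier: bool = True,
) -> pd.DataFrame:
    """Append analysis BP, change-residual and risk-score columns.

    Expects the wave-suffixed raw columns emitted by the cohort generator
    (``sbp_<w>_r1``, ``sbp_<w>_r2``, ``antihtn_<w>``, ``smoking_<w>``,
    ``diabetes_<w>``, ``bmi_<w>``).  Adds ``sbp_<w>``/``dbp_<w>`` (second
    reading, device-converted), ``sbp_change_<i>``/``dbp_change_<i>`` and
    ``fhs_36/53/69``.
    """
    if risk_config is None:
        risk_config = RiskScoreConfig.default()
    out = df.copy()
    for measure in ("sbp", "dbp"):
        for w in WAVES:
            sel = select_reading(df[f"{measure}_{w}_r1"], df[f"{measure}_{w}_r2"])
            conv = (conversions or {}).get(f"{measure}_{w}")
            out[f"{measure}_{w}"] = convert_device(sel, conv) if conv else sel
        bp = out[[f"{measure}_{w}" for w in WAVES]].copy()
        bp.columns = list(WAVES)
        changes = conditional_change_residuals(
            bp, out["sex"], all_earlier=all_earlier
        )
        for col in changes.columns:
            out[f"{measure}_{col}"] = changes[col]
    for w in RISK_WAVES:
        out[f"fhs_{w}"] = framingham_risk(
            out["sex"],
            WAVE_AGES[w],
            out[f"sbp_{w}"],
            out[f"antihtn_{w}"],
            out[f"smoking_{w}"],
            out[f"diabetes_{w}"],
            out[f"bmi_{w}"],
            risk_config,
        )
    return out
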