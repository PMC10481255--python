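"""Regression battery on the standardized NAWM summaries.

Reproduces the analysis structure of the study: per diffusion metric, OLS
blocks with mutual adjustment (concurrent imaging: WMH volume + whole-brain
volume + amyloid status together), age-at-scan and sex always adjusted,
continuous predictors entered as z-scores (WMH volume log-transformed
first), sex-by-predictor interactions with per-sex marginal slopes reported
when the interaction p < 0.1, and Benjamini–Hochberg FDR at 5% applied over
the (predictor, metric) family of a block.  Inference is t-based on the
residual degrees of freedom.

The modelling objects follow the fit/results idiom: :class:`BlockModel`
holds data + a :class:`ModelSpec`; ``fit()`` returns :class:`BlockResults`
with the term table, interaction tests and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import METRICS, WAVES

__all__ = [
    "standardize_predictor",
    "TermSpec",
    "ModelSpec",
    "BlockModel",
    "BlockResults",
    "bh_fdr",
    "battery_specs",
    "run_battery",
    "sensitivity_rerun",
    "BLOCKS",
]


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient (collinear terms listed)."""


def standardize_predictor(values, log: bool = False) -> np.ndarray:
    """(x - mean)/SD over the analysis sample (n-1 SD); optional natural log
    first (the WMH-volume path).  A constant column is an error."""
    x = np.asarray(values, dtype=float)
    if log:
        x = np.log(x)
    sd = np.nanstd(x, ddof=1)
    if not np.isfinite(sd) or sd < 1e-12:
        raise ValueError("cannot standardize a constant predictor")
    return (x - np.nanmean(x)) / sd


@dataclass(frozen=True)
class TermSpec:
    """One design term: analysis name, source column, transform."""

    name: str
    source: str
    transform: str = "z"  # z | log_z | binary | raw

    def build(self, data: pd.DataFrame) -> np.ndarray:
        x = data[self.source].to_numpy(dtype=float)
        if self.transform == "z":
            return standardize_predictor(x)
        if self.transform == "log_z":
            return standardize_predictor(x, log=True)
        if self.transform in ("binary", "raw"):
            return x
        raise ValueError(f"unknown transform {self.transform!r}")


AGE = TermSpec("age", "age_at_scan", "raw")
SEX = TermSpec("sex_female", "sex", "binary")


@dataclass(frozen=True)
class ModelSpec:
    """One regression model: outcome metric, focal predictors, covariates."""

    outcome: str
    predictors: tuple[TermSpec, ...]
    covariates: tuple[TermSpec, ...] = (AGE, SEX)
    interaction: str | None = None  # focal predictor name crossed with sex
    block: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in METRICS:
            raise ValueError(f"outcome must be one of {METRICS}, got {self.outcome!r}")
        names = [t.name for t in self.predictors + self.covariates]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate terms in spec: {names}")
        if self.interaction is not None:
            if self.interaction not in [t.name for t in self.predictors]:
                raise ValueError(
                    f"interaction predictor {self.interaction!r} not among predictors"
                )
            if "sex_female" not in names:
                raise ValueError("sex must be in the model to interact with it")

    @property
    def outcome_column(self) -> str:
        return f"{self.outcome.lower()}_z"

    def with_extra_covariates(self, extra: Sequence[TermSpec]) -> "ModelSpec":
        current = {t.name for t in self.predictors + self.covariates}
        add = tuple(t for t in extra if t.name not in current)
        return replace(self, covariates=self.covariates + add)


@dataclass
class BlockResults:
    """Fitted block: tidy term table + interaction/marginal results."""

    spec: ModelSpec
    terms: pd.DataFrame  # term, estimate, se, ci_lo, ci_hi, p, df_resid
    n_obs: int
    df_resid: int
    rsquared: float
    interaction_p: float | None = None
    marginal: pd.DataFrame | None = None  # sex, slope, se, ci_lo, ci_hi

    def term(self, name: str) -> pd.Series:
        row = self.terms.loc[self.terms["term"] == name]
        if row.empty:
            raise KeyError(f"no term {name!r} in results")
        return row.iloc[0]

    def summary(self) -> str:
        head = (
            f"OLS block {self.spec.block or '-'} / outcome {self.spec.outcome} "
            f"(mean NAWM z){': ' + self.spec.label if self.spec.label else ''}\n"
            f"n = {self.n_obs}, residual df = {self.df_resid}, "
            f"R^2 = {self.rsquared:.3f}\n"
        )
        body = self.terms.to_string(
            index=False,
            formatters={c: "{:.4f}".format for c in ("estimate", "se", "ci_lo", "ci_hi")},
        )
        tail = ""
        if self.interaction_p is not None:
            tail = f"\nsex x {self.spec.interaction} interaction p = {self.interaction_p:.4g}"
            if self.marginal is not None:
                tail += "\n" + self.marginal.to_string(index=False)
        return head + body + tail


class BlockModel:
    """OLS over complete cases of one :class:`ModelSpec`."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        cols = [spec.outcome_column] + [
            t.source for t in spec.predictors + spec.covariates
        ]
        missing = [c for c in dict.fromkeys(cols) if c not in data.columns]
        if missing:
            raise KeyError(f"data lacks columns {missing}")
        self.data = data[list(dict.fromkeys(cols))].dropna().reset_index(drop=True)
        if spec.interaction is not None:
            sex_src = next(
                t.source for t in spec.predictors + spec.covariates if t.name == "sex_female"
            )
            if self.data[sex_src].nunique() < 2:
                raise ValueError("single-sex data: cannot test a sex interaction")
        n_terms = len(spec.predictors) + len(spec.covariates)
        if len(self.data) <= n_terms + 2:
            raise ValueError(
                f"only {len(self.data)} complete cases for {n_terms} terms"
            )

    def _design(self, with_interaction: bool) -> pd.DataFrame:
        spec = self.spec
        X = pd.DataFrame({"const": np.ones(len(self.data))})
        for t in spec.predictors + spec.covariates:
            X[t.name] = t.build(self.data)
        if with_interaction:
            sex = X["sex_female"].to_numpy()
            if len(np.unique(sex)) < 2:
                raise ValueError("single-sex data: cannot test a sex interaction")
            X[f"{spec.interaction}:sex_female"] = X[spec.interaction] * sex
        self._check_rank(X)
        return X

    @staticmethod
    def _check_rank(X: pd.DataFrame) -> None:
        arr = X.to_numpy()
        rank = np.linalg.matrix_rank(arr)
        if rank < X.shape[1]:
            # flag columns with negligible independent contribution via QR
            _, R = np.linalg.qr(arr)
            diag = np.abs(np.diag(R))
            bad = [c for c, d in zip(X.columns, diag) if d < 1e-8 * diag.max()]
            raise RankDeficientError(
                f"design matrix rank {rank} < {X.shape[1]}; "
                f"collinear terms: {bad or 'undetermined'}"
            )

    def fit(self) -> BlockResults:
        spec = self.spec
        y = self.data[spec.outcome_column].to_numpy(dtype=float)
        X = self._design(with_interaction=False)
        res = sm.OLS(y, X).fit()
        ci = res.conf_int(alpha=0.05)
        rows = []
        for name in X.columns:
            if name == "const":
                continue
            rows.append(
                {
                    "term": name,
                    "estimate": res.params[name],
                    "se": res.bse[name],
                    "ci_lo": ci.loc[name, 0],
                    "ci_hi": ci.loc[name, 1],
                    "p": res.pvalues[name],
                }
            )
        out = BlockResults(
            spec=spec,
            terms=pd.DataFrame(rows),
            n_obs=int(res.nobs),
            df_resid=int(res.df_resid),
            rsquared=float(res.rsquared),
        )
        if spec.interaction is not None:
            out.interaction_p, out.marginal = self._fit_interaction(y)
        return out

    def _fit_interaction(self, y: np.ndarray) -> tuple[float, pd.DataFrame]:
        spec = self.spec
        X = self._design(with_interaction=True)
        res = sm.OLS(y, X).fit()
        xname, iname = spec.interaction, f"{spec.interaction}:sex_female"
        p_int = float(res.pvalues[iname])
        cov = res.cov_params()
        tcrit = float(stats_t_ppf(0.975, res.df_resid))
        rows = []
        # sex coded female=1: male slope is the main effect, female adds the
        # interaction; Var(b + bi) = Var(b) + Var(bi) + 2 Cov(b, bi)
        for sexname, slope, var in (
            ("male", res.params[xname], cov.loc[xname, xname]),
            (
                "female",
                res.params[xname] + res.params[iname],
                cov.loc[xname, xname]
                + cov.loc[iname, iname]
                + 2 * cov.loc[xname, iname],
            ),
        ):
            se = float(np.sqrt(var))
            rows.append(
                {
                    "sex": sexname,
                    "slope": float(slope),
                    "se": se,
                    "ci_lo": float(slope - tcrit * se),
                    "ci_hi": float(slope + tcrit * se),
                }
            )
        return p_int, pd.DataFrame(rows)


def stats_t_ppf(q: float, df: float) -> float:
    from scipy import stats

    return float(stats.t.ppf(q, df))


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up: flag the k smallest p-values, where k is
    the largest rank with p_(k) <= k q / m."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    flags = np.zeros(m, dtype=bool)
    if passed.any():
        k = int(np.max(np.nonzero(passed)[0])) + 1
        flags[order[:k]] = True
    return flags


# ---------------------------------------------------------------------------
# the study's analysis blocks

LOG_WMHV = TermSpec("log_wmhv", "wmhv_ml", "log_z")
WBV = TermSpec("wbv", "wbv_ml", "z")
ABETA = TermSpec("abeta", "abeta_pos", "binary")
TIV = TermSpec("tiv", "tiv_ml", "z")

BLOCKS = ("concurrent_imaging", "cognition", "demographics", "cardiovascular")

_CHANGE_INTERVALS = tuple(f"{a}_{b}" for a, b in zip(WAVES[:-1], WAVES[1:]))
_CARDIO_EXPOSURES = (
    [f"fhs_{w}" for w in ("36", "53", "69")]
    + [f"sbp_{w}" for w in WAVES]
    + [f"dbp_{w}" for w in WAVES]
    + [f"sbp_change_{i}" for i in _CHANGE_INTERVALS]
    + [f"dbp_change_{i}" for i in _CHANGE_INTERVALS]
)


def battery_specs(block: str, metrics: Sequence[str] = METRICS) -> list[ModelSpec]:
    """The study's model specifications for one analysis block."""
    specs: list[ModelSpec] = []
    if block == "concurrent_imaging":
        # pathology measures mutually adjusted, + age, sex, TIV
        for m in metrics:
            specs.append(
                ModelSpec(
                    outcome=m,
                    predictors=(LOG_WMHV, WBV, ABETA),
                    covariates=(AGE, SEX, TIV),
                    block=block,
                    label="WMHV + WBV + amyloid, mutually adjusted",
                )
            )
    elif block == "cognition":
        subtests = ("mmse", "logical_memory", "digit_symbol", "face_name")
        for m in metrics:
            specs.append(
                ModelSpec(
                    outcome=m,
                    predictors=(TermSpec("pacc", "pacc", "z"),),
                    block=block,
                    label="PACC composite",
                )
            )
            specs.append(
                ModelSpec(
                    outcome=m,
                    predictors=tuple(TermSpec(s, s, "z") for s in subtests),
                    block=block,
                    label="four sub-tests, mutually adjusted",
                )
            )
    elif block == "demographics":
        for m in metrics:
            specs.append(
                ModelSpec(
                    outcome=m,
                    predictors=(
                        SEX,
                        AGE,
                        TermSpec("edu_16", "edu_16", "binary"),
                        TermSpec("edu_17plus", "edu_17plus", "binary"),
                        TermSpec("parental_sep", "parental_sep", "binary"),
                        TermSpec("childhood_cog", "childhood_cog", "z"),
                        TermSpec("apoe_e4", "apoe_e4", "binary"),
                    ),
                    covariates=(),
                    block=block,
                    label="demographics, mutually adjusted",
                )
            )
    elif block == "cardiovascular":
        for exposure in _CARDIO_EXPOSURES:
            for m in metrics:
                specs.append(
                    ModelSpec(
                        outcome=m,
                        predictors=(TermSpec(exposure, exposure, "z"),),
                        block=block,
                        label=f"{exposure} (separate model)",
                    )
                )
    else:
        raise ValueError(f"unknown block {block!r}; blocks are {BLOCKS}")
    return specs


def _prepare(data: pd.DataFrame) -> pd.DataFrame:
    """Derive dummy-coded education once for the demographics block."""
    out = data.copy()
    if "education" in out.columns and "edu_16" not in out.columns:
        out["edu_16"] = (out["education"] == 1).astype(float)
        out["edu_17plus"] = (out["education"] == 2).astype(float)
    return out


def run_battery(
    data: pd.DataFrame,
    block: str,
    fdr_q: float = 0.05,
    interaction_show: float = 0.1,
    test_interactions: bool = True,
) -> pd.DataFrame:
    """Fit one block across metrics and return the tidy results table.

    Columns: block, outcome, model, term, estimate, se, ci_lo, ci_hi, p,
    q_flag, interaction_p, slope_male, slope_male_lo, slope_male_hi,
    slope_female, slope_female_lo, slope_female_hi.  FDR flags are computed
    over all focal (predictor, metric) p-values of the block; marginal
    slopes are filled only when the interaction p < ``interaction_show``.
    """
    data = _prepare(data)
    rows = []
    for spec in battery_specs(block):
        focal_names = [t.name for t in spec.predictors]
        base = BlockModel(data, spec).fit()
        inter: dict[str, tuple[float, pd.DataFrame]] = {}
        if test_interactions:
            for name in focal_names:
                if name == "sex_female":
                    continue
                ispec = replace(spec, interaction=name)
                if "sex_female" not in [t.name for t in ispec.predictors + ispec.covariates]:
                    continue
                r = BlockModel(data, ispec).fit()
                inter[name] = (r.interaction_p, r.marginal)
        for name in focal_names:
            t = base.term(name)
            row = {
                "block": block,
                "outcome": spec.outcome,
                "model": spec.label,
                "term": name,
                "estimate": t["estimate"],
                "se": t["se"],
                "ci_lo": t["ci_lo"],
                "ci_hi": t["ci_hi"],
                "p": t["p"],
                "n_obs": base.n_obs,
                "interaction_p": np.nan,
                "slope_male": np.nan,
                "slope_male_lo": np.nan,
                "slope_male_hi": np.nan,
                "slope_female": np.nan,
                "slope_female_lo": np.nan,
                "slope_female_hi": np.nan,
            }
            if name in inter:
                p_int, marg = inter[name]
                row["interaction_p"] = p_int
                if p_int < interaction_show:
                    for _, mr in marg.iterrows():
                        row[f"slope_{mr['sex']}"] = mr["slope"]
                        row[f"slope_{mr['sex']}_lo"] = mr["ci_lo"]
                        row[f"slope_{mr['sex']}_hi"] = mr["ci_hi"]
            rows.append(row)
    out = pd.DataFrame(rows)
    out["q_flag"] = bh_fdr(out["p"].to_numpy(), q=fdr_q)
    return out


def sensitivity_rerun(
    data: pd.DataFrame,
    results: pd.DataFrame,
    mode: str,
    specs: Sequence[ModelSpec] | None = None,
) -> pd.DataFrame:
    """Re-fit the FDR-flagged models with extra covariates.

    ``mode`` is ``"wmhv_tiv"`` (adjust for log-WMHV z and TIV z) or
    ``"apoe"``.  Returns one row per flagged term with the base and adjusted
    estimates and the attenuation (b_base - b_adj) / b_base.
    """
    extra = {
        "wmhv_tiv": (LOG_WMHV, TIV),
        "apoe": (TermSpec("apoe_e4", "apoe_e4", "binary"),),
    }
    if mode not in extra:
        raise ValueError(f"mode must be one of {sorted(extra)}")
    data = _prepare(data)
    flagged = results.loc[results["q_flag"]]
    rows = []
    for (block, outcome, label), grp in flagged.groupby(["block", "outcome", "model"]):
        pool = specs if specs is not None else battery_specs(block, metrics=[outcome])
        spec = next(
            s for s in pool if s.outcome == outcome and s.label == label
        )
        adj = BlockModel(data, spec.with_extra_covariates(extra[mode])).fit()
        for _, r in grp.iterrows():
            b_adj = float(adj.term(r["term"])["estimate"]) if r["term"] in set(adj.terms["term"]) else np.nan
            rows.append(
                {
                    "block": block,
                    "outcome": outcome,
                    "model": label,
                    "term": r["term"],
                    "mode": mode,
                    "estimate_base": r["estimate"],
                    "estimate_adjusted": b_adj,
                    "attenuation": (r["estimate"] - b_adj) / r["estimate"],
                }
            )
    return pd.DataFrame(rows)
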