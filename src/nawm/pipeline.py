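"""End-to-end orchestration and replication.

``build_study_table`` runs one full synthetic study in memory:
generate cohort -> render metric maps on the common grid -> place lesions
-> build per-subject NAWM masks -> fit the healthy voxel-wise reference
(WMHV < 1 mL) -> z-score and summarize -> classify amyloid by the mixture
cut -> derive life-course vascular predictors.  ``run_pipeline`` adds file
outputs (CSV/TSV/NIfTI/JSON manifest) around it; ``replicate_study`` repeats
the study across seeds and reports recovered coefficients against the
generator's truth.

Replication uses *antithetic pairs*: the two members of a pair share every
covariate draw and all voxel noise but flip the sign of the latent residual.
OLS coefficients are linear in that residual, so the pair mean estimates the
same expectation with the dominant Monte Carlo term cancelled — 50
replicates behave like thousands of independent ones (docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .amyloid import classify_abeta, fit_two_gaussian_mixture
from .association import (
    BlockModel,
    ModelSpec,
    TermSpec,
    battery_specs,
    run_battery,
)
from .cohort import draw_cohort
from .config import (
    METRICS,
    ConfigurationError,
    EffectConfig,
    EMConfig,
    ErosionSpec,
    GridSpec,
    PenumbraConfig,
)
from .images import LATENT_SCALE, _DEGRADE_SIGN, make_template, place_lesions, render_cohort_maps
from .masking import make_nawm_mask
from .normative import NormativeReference, select_reference
from .vascular import RiskScoreConfig, add_lifecourse_columns

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PipelineStageError",
    "build_study_table",
    "build_table_only",
    "run_pipeline",
    "replicate_study",
    "extract_target_coefficients",
    "null_calibration",
    "interaction_scenario_replicates",
    "TARGET_TRUTH",
]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _stage(name: str):
    """Decorator-ish context: re-raise any stage failure with its name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _Ctx()


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (generator + imaging + analysis)."""

    cohort: EffectConfig = field(default_factory=EffectConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    erosion: ErosionSpec = field(default_factory=ErosionSpec)
    penumbra: PenumbraConfig | None = None
    reference_threshold_ml: float = 1.0
    n_min: int = 10
    sd_floor: float = 1e-6
    em: EMConfig = field(default_factory=EMConfig)
    risk_config_path: str | None = None
    blocks: tuple[str, ...] = (
        "concurrent_imaging",
        "cognition",
        "demographics",
        "cardiovascular",
    )
    fdr_q: float = 0.05
    interaction_show: float = 0.1
    outdir: str = "nawm_run"
    write_images: bool = False

    def risk_config(self) -> RiskScoreConfig:
        if self.risk_config_path is None:
            return RiskScoreConfig.default()
        if not Path(self.risk_config_path).exists():
            raise ConfigurationError(
                f"risk config path {self.risk_config_path!r} does not exist"
            )
        return RiskScoreConfig.from_yaml(self.risk_config_path)


def _sub_seed(seed: int, stage: int, index: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed, spawn_key=(100 + stage, index))


# ---------------------------------------------------------------------------
# in-memory study

def build_study_table(
    cohort_cfg: EffectConfig,
    grid: GridSpec = GridSpec(),
    erosion: ErosionSpec = ErosionSpec(),
    penumbra: PenumbraConfig | None = None,
    reference_threshold_ml: float = 1.0,
    n_min: int = 10,
    sd_floor: float = 1e-6,
    em: EMConfig = EMConfig(),
    risk_config: RiskScoreConfig | None = None,
    image_seed: int | None = None,
    return_objects: bool = False,
):
    """One full synthetic study; returns the analysis-ready subject table.

    ``image_seed`` controls template, lesion and voxel-noise randomness
    separately from the cohort seed (the antithetic replication design keeps
    it fixed within a pair).  With ``return_objects`` the fitted reference,
    mixture results, template and per-subject NAWM masks are returned too.
    """
    if image_seed is None:
        image_seed = cohort_cfg.seed
    with _stage("draw_cohort"):
        df = draw_cohort(cohort_cfg)
    n = len(df)
    with _stage("make_template"):
        template = make_template(
            grid.shape, grid.voxel_mm, seed=_sub_seed(image_seed, 0).generate_state(1)[0]
        )
    nvox = int(np.prod(grid.shape))
    wm_ml = template.wm_volume_ml
    with _stage("place_lesions"):
        nawm = np.empty((n, nvox), dtype=bool)
        lesions = np.empty((n, nvox), dtype=bool)
        for i in range(n):
            target = min(df["wmhv_ml"].iat[i], 0.5 * wm_ml)  # physical cap
            lesion = place_lesions(
                template.wm_mask,
                target,
                voxel_mm=grid.voxel_mm,
                seed=_sub_seed(image_seed, 1, i).generate_state(1)[0],
            )
            lesions[i] = lesion.reshape(nvox)
            nawm[i] = make_nawm_mask(template.wm_mask, lesion, erosion).reshape(nvox)
    with _stage("render_maps"):
        latents = {m: df[f"latent_{m.lower()}"].to_numpy() for m in METRICS}
        maps = render_cohort_maps(
            template, latents, seed=_sub_seed(image_seed, 2).generate_state(1)[0]
        )
        if penumbra is not None and penumbra.distance_vox > 0:
            from .images import _penumbra_weight

            for i in range(n):
                pen = _penumbra_weight(
                    lesions[i].reshape(grid.shape), penumbra
                ).reshape(nvox)
                for m in METRICS:
                    maps[m][i] += (LATENT_SCALE[m] * _DEGRADE_SIGN[m]) * pen.astype(
                        maps[m].dtype
                    )
    with _stage("select_reference"):
        ref_sel = select_reference(df["wmhv_ml"].to_numpy(), reference_threshold_ml)
    with _stage("fit_reference"):
        reference = NormativeReference.fit(
            {m: maps[m][ref_sel] for m in METRICS},
            nawm[ref_sel],
            df.loc[ref_sel, "subject_id"],
            grid,
            threshold_ml=reference_threshold_ml,
            n_min=min(n_min, int(ref_sel.sum())),
            sd_floor=sd_floor,
        )
    with _stage("zscore_summaries"):
        summary = reference.summarize(maps, nawm, df["subject_id"])
        table = df.merge(summary, on="subject_id")
    with _stage("amyloid_classification"):
        mixture = fit_two_gaussian_mixture(table["suvr"].to_numpy(), em)
        table["abeta_pos"] = classify_abeta(table["suvr"].to_numpy(), mixture.cut_point)
    with _stage("lifecourse_vascular"):
        table = add_lifecourse_columns(table, risk_config)
    if return_objects:
        return table, {
            "template": template,
            "reference": reference,
            "mixture": mixture,
            "nawm_masks": nawm,
            "lesion_masks": lesions,
            "maps": maps,
        }
    return table


def build_table_only(
    cohort_cfg: EffectConfig,
    em: EMConfig = EMConfig(),
    risk_config: RiskScoreConfig | None = None,
) -> pd.DataFrame:
    """Table-level study (no images): the latent factor itself is the
    outcome.  Used for fast calibration runs of the regression machinery."""
    df = draw_cohort(cohort_cfg)
    for m in METRICS:
        df[f"{m.lower()}_z"] = df[f"latent_{m.lower()}"]
    mixture = fit_two_gaussian_mixture(df["suvr"].to_numpy(), em)
    df["abeta_pos"] = classify_abeta(df["suvr"].to_numpy(), mixture.cut_point)
    return add_lifecourse_columns(df, risk_config)


# ---------------------------------------------------------------------------
# file-based run

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write outputs, return the run manifest.

    Outputs under ``config.outdir``: ``cohort.csv`` (seed in a header
    comment), ``reference_model/`` (NIfTI mean/SD/n + JSON sidecar),
    ``results_<block>.tsv``, ``mixture_fit.json``, ``manifest.json``, and
    per-subject NIfTI volumes when ``write_images`` is set.  Identical
    config + seed reproduce byte-identical tables.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, objs = build_study_table(
        config.cohort,
        grid=config.grid,
        erosion=config.erosion,
        penumbra=config.penumbra,
        reference_threshold_ml=config.reference_threshold_ml,
        n_min=config.n_min,
        sd_floor=config.sd_floor,
        em=config.em,
        risk_config=config.risk_config(),
        return_objects=True,
    )
    files: list[Path] = []
    with _stage("write_cohort"):
        cohort_path = outdir / "cohort.csv"
        with open(cohort_path, "w") as fh:
            fh.write(f"# seed={config.cohort.seed} n={config.cohort.n}\n")
            table.to_csv(fh, index=False, float_format="%.10g")
        files.append(cohort_path)
    with _stage("write_reference"):
        refdir = objs["reference"].save(outdir / "reference_model")
        files.extend(sorted(refdir.glob("*")))
    with _stage("write_mixture"):
        mix = objs["mixture"]
        mix_path = outdir / "mixture_fit.json"
        mix_path.write_text(
            json.dumps(
                {
                    "mu": mix.mu,
                    "sigma": mix.sigma,
                    "weights": mix.weights,
                    "cut_point": mix.cut_point,
                    "log_likelihood": mix.log_likelihood,
                    "n_iterations": mix.n_iterations,
                },
                indent=2,
            )
        )
        files.append(mix_path)
    if config.write_images:
        with _stage("write_images"):
            from .niftiio import save_volume

            imgdir = outdir / "images"
            imgdir.mkdir(exist_ok=True)
            shape = config.grid.shape
            save_volume(objs["template"].wm_mask, config.grid, imgdir / "template_WM.nii.gz")
            manifest_rows = []
            for i, sid in enumerate(table["subject_id"]):
                row = {"subject_id": sid}
                for m in METRICS:
                    p = imgdir / f"{sid}_{m}.nii.gz"
                    save_volume(objs["maps"][m][i].reshape(shape), config.grid, p)
                    row[m] = p.name
                for kind, arr in (("WMH", objs["lesion_masks"]), ("NAWM", objs["nawm_masks"])):
                    p = imgdir / f"{sid}_{kind}.nii.gz"
                    save_volume(arr[i].reshape(shape), config.grid, p)
                    row[kind] = p.name
                manifest_rows.append(row)
            pd.DataFrame(manifest_rows).to_csv(imgdir / "manifest.csv", index=False)
    results = {}
    for block in config.blocks:
        with _stage(f"associations_{block}"):
            res = run_battery(
                table,
                block,
                fdr_q=config.fdr_q,
                interaction_show=config.interaction_show,
            )
            results[block] = res
            p = outdir / f"results_{block}.tsv"
            res.to_csv(p, sep="\t", index=False, float_format="%.10g")
            files.append(p)
    manifest = {
        "package_version": _pkg_version,
        "seed": config.cohort.seed,
        "n": config.cohort.n,
        "grid": list(config.grid.shape),
        "voxel_mm": config.grid.voxel_mm,
        "reference_subjects": len(objs["reference"].subject_ids),
        "cut_point": objs["mixture"].cut_point,
        "blocks": list(config.blocks),
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# replication and recovery

#: generator truth for the headline recovered coefficients
TARGET_TRUTH = {
    "wmhv_FA": -0.09,
    "wmhv_NDI": -0.17,
    "wmhv_MD": 0.14,
    "fhs69_FA": -0.06,
    "fhs69_NDI": -0.10,
    "fhs69_MD": 0.09,
    "abeta_male_MD": 0.06,
    "abeta_male_FA": -0.04,
    "abeta_male_NDI": 0.0,  # no amyloid effect encoded for NDI
}


def extract_target_coefficients(table: pd.DataFrame) -> dict[str, float]:
    """Headline coefficients from one study table.

    WMHV and male-amyloid slopes come from the mutually adjusted
    concurrent-imaging model (the amyloid slope from its sex-interaction
    variant); the late-life risk-score coefficients from separate models
    adjusted for age at scan and sex.
    """
    out: dict[str, float] = {}
    for m in ("FA", "NDI", "MD"):
        spec = battery_specs("concurrent_imaging", metrics=[m])[0]
        res = BlockModel(table, spec).fit()
        out[f"wmhv_{m}"] = float(res.term("log_wmhv")["estimate"])
        ires = BlockModel(table, dataclasses.replace(spec, interaction="abeta")).fit()
        male = ires.marginal.set_index("sex").loc["male"]
        out[f"abeta_male_{m}"] = float(male["slope"])
        fspec = ModelSpec(
            outcome=m,
            predictors=(TermSpec("fhs_69", "fhs_69", "z"),),
            block="cardiovascular",
        )
        out[f"fhs69_{m}"] = float(
            BlockModel(table, fspec).fit().term("fhs_69")["estimate"]
        )
    return out


def replicate_study(
    n_reps: int = 50,
    base_seed: int = 1,
    cohort_cfg: EffectConfig | None = None,
    grid: GridSpec = GridSpec(),
    antithetic: bool = True,
    progress: bool = False,
) -> pd.DataFrame:
    """Repeat the full image-level study and summarize coefficient recovery.

    Returns a frame indexed by target with columns ``mean``, ``sd``,
    ``truth`` and ``n_reps``.  With ``antithetic`` (default) replicates come
    in pairs sharing covariates/voxel noise with the latent residual sign
    flipped; seeds derive from ``base_seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = EffectConfig() if cohort_cfg is None else cohort_cfg
    per_rep: list[dict[str, float]] = []
    rep = 0
    while rep < n_reps:
        pair_seed = int(base_seed) + (rep // 2 if antithetic else rep)
        sign = -1 if (antithetic and rep % 2 == 1) else 1
        cfg = base.replace(seed=pair_seed, noise_sign=sign)
        table = build_study_table(cfg, grid=grid, image_seed=pair_seed)
        per_rep.append(extract_target_coefficients(table))
        if progress:
            log.info("replicate %d/%d done", rep + 1, n_reps)
        rep += 1
    frame = pd.DataFrame(per_rep)
    report = pd.DataFrame(
        {
            "mean": frame.mean(),
            "sd": frame.std(ddof=1) if n_reps > 1 else np.nan,
            "truth": pd.Series(TARGET_TRUTH),
            "n_reps": n_reps,
        }
    )
    return report


def null_calibration(
    n_reps: int = 500,
    n: int = 362,
    base_seed: int = 1,
    alpha: float = 0.05,
) -> float:
    """Pre-FDR rejection rate of focal predictors under an all-null
    generator (table-level, mutually adjusted concurrent-imaging model)."""
    rejections = 0
    total = 0
    for r in range(n_reps):
        cfg = EffectConfig.null(n=n, seed=base_seed * 1_000_00 + r)
        table = build_table_only(cfg)
        for m in METRICS:
            spec = battery_specs("concurrent_imaging", metrics=[m])[0]
            res = BlockModel(table, spec).fit()
            for t in ("log_wmhv", "wbv", "abeta"):
                rejections += int(res.term(t)["p"] < alpha)
                total += 1
    return rejections / total


def interaction_scenario_replicates(
    n_reps: int = 100,
    n: int = 362,
    base_seed: int = 1,
    alpha_interaction: float = 0.05,
) -> pd.DataFrame:
    """Replicate the female-only midlife-SBP scenario at table level.

    For each replicate and each of FA and NDI, records whether the
    sex-by-SBP(53) interaction is significant (p < 0.05), the female
    marginal slope is negative, and the male marginal slope's 95% CI covers
    zero.  Returns per-metric pattern frequencies.
    """
    records = []
    for r in range(n_reps):
        cfg = EffectConfig.sex_interaction_scenario(n=n, seed=base_seed * 1_000_00 + r)
        table = build_table_only(cfg)
        for m in ("FA", "NDI"):
            spec = ModelSpec(
                outcome=m,
                predictors=(TermSpec("sbp_53", "sbp_53", "z"),),
                interaction="sbp_53",
                block="cardiovascular",
            )
            res = BlockModel(table, spec).fit()
            marg = res.marginal.set_index("sex")
            records.append(
                {
                    "rep": r,
                    "metric": m,
                    "interaction_sig": res.interaction_p < alpha_interaction,
                    "female_negative": marg.loc["female", "slope"] < 0,
                    "male_ci_covers_zero": (
                        marg.loc["male", "ci_lo"] < 0 < marg.loc["male", "ci_hi"]
                    ),
                }
            )
    df = pd.DataFrame(records)
    df["pattern"] = (
        df["interaction_sig"] & df["female_negative"] & df["male_ci_covers_zero"]
    )
    return df.groupby("metric")[
        ["interaction_sig", "female_negative", "male_ci_covers_zero", "pattern"]
    ].mean()
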