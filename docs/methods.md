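# Methods

This package re-implements, end to end and on fully synthetic data, a
life-course analysis of normal-appearing white matter (NAWM)
microstructural integrity in a single-birth-week cohort imaged with
diffusion MRI at ~age 70.  The pipeline has five scientific stages — NAWM
mask construction, normative voxel-wise z-scoring, amyloid-positivity
classification, life-course vascular variable construction, and an OLS
association battery — plus a synthetic-data generator that defines the
study conditions under which everything is tested.

## Outcome model: normative voxel-wise z-scoring

Absolute diffusion metrics (FA, MD, NDI, ODI) vary strongly across the
brain, so the outcome is each subject's *divergence from healthy tissue*.
A healthy reference is fitted from the subjects with white matter
hyperintensity volume (WMHV) strictly below 1 mL: at every voxel v and
metric m, the mean mu_m(v) and sample SD s_m(v) (n−1 denominator) over the
reference subjects whose own NAWM mask covers v.  A subject's voxel-wise
z-map is (x − mu)/s, and the mean z over the subject's NAWM mask is the
regression outcome.  Voxels with coverage n < n_min (default 10) or
SD < 1e−6 metric units are unusable and excluded from subject means; both
guards prevent unstable or infinite z at thin coverage.  The reference
subjects stay in the analysis sample — z-scored against a model that
contains them they self-normalize (their cohort-mean z is ~0, exactly 0
for the plug-in mean up to mask-size weighting).

The NAWM mask is (WM mask minus lesion mask), then a morphological erosion
of one voxel.  The default structuring element is the 6-connected cross
(face neighbours), the conservative reading of "eroded by one voxel";
26-connectivity is available through `ErosionSpec`.  Lesion voxels outside
WM are tolerated with a logged warning — masks from different segmentation
algorithms need not nest.

All subjects share one template grid (default 32×32×32 at 2.5 mm
isotropic, matching a typical diffusion acquisition while staying
desk-scale), so voxel correspondence across subjects is exact by
construction and no registration stage exists.  This is an implementation
stance, not a claim about how any real cohort was registered.

## Amyloid positivity

SUVR values in a cognitively normal ~70-year-old population are bimodal.
A 1-D two-component Gaussian mixture is fitted by EM (initialisation:
moment estimates on a median split, ten restarts with jittered split
quantiles, tolerance 1e−8 on the log-likelihood, 500 iterations max,
SD floor 1e−6 against degenerate collapse; unequal variances by default
with an equal-variance option).  The positivity cut is the 99th percentile
of the lower component, mu_low + 2.3263·sigma_low, and values strictly
above the cut are positive (the boundary itself is negative).  The EM
implementation is cross-checked in the tests against scikit-learn's
`GaussianMixture` and against known-label moments on separated clouds.

## Life-course vascular predictors

Blood pressure is measured twice per wave at ages 36, 43, 53, 60–64
and 69; the second reading is used unless only one exists.  Linear
device-conversion equations (early-adulthood random-zero instrument to the
later digital one) are applied as configuration; the shipped default is the
identity because the generator already emits converted units.

*Conditional change residuals*: for each target wave from 43 onward, BP is
regressed (OLS with intercept) on all earlier waves' BP — the "all earlier
waves" reading of the conditional-change construction; a
previous-wave-only mode is a switch — separately within each sex, using
subjects complete at all waves.  Residuals are divided by their within-sex
SD (n−1), giving mean 0 / SD 1 per sex and interval exactly, so intervals
are comparable.

*Cardiovascular risk score*: a 10-year general cardiovascular event risk
from the office-based (non-laboratory) profile — a sex-stratified weighted
sum of log age, log BMI, log SBP (separate coefficients when on
antihypertensive treatment), current smoking and diabetes, transformed
through the baseline survival: risk% = 100·(1 − s0^exp(lp − lp_mean)).
The coefficient set ships as versioned YAML (`nawm/data/`), not hard-coded,
so the weighting is auditable and swappable; because generator and analysis
share the config, downstream conclusions do not hinge on the constants'
provenance.  Age inside the score is the nominal wave age: in a
single-birth-week cohort everyone has the same age at a wave.

## Association battery

Per metric, the battery mirrors the study design: the concurrent-imaging
block fits log-WMHV (z of natural log), whole-brain volume (z) and amyloid
status (binary) *in the same model* plus age at scan, sex and total
intracranial volume (z); cognition fits the PACC composite alone and the
four sub-tests jointly; demographics fits sex, age, education (two dummies
against "no qualifications"), parental occupational class, childhood
cognition (z) and APOE-e4 together; each cardiovascular exposure gets its
own model adjusted for age and sex.  Inference is t-based on residual
degrees of freedom.  Sex interactions are tested one focal predictor at a
time; with female coded 1, the male marginal slope is the main effect and
the female slope adds the interaction coefficient, with
Var(b+bi) = Var(b)+Var(bi)+2Cov.  Marginal slopes are reported when the
interaction p < 0.1; an interaction is called significant at p < 0.05
(both thresholds configurable).  Benjamini–Hochberg FDR at 5% is applied
over the (predictor, metric) family of one block — the per-figure reading
of the correction — via an explicit step-up implementation property-tested
against exhaustive search and statsmodels.  Sensitivity re-runs refit
FDR-flagged models with log-WMHV + TIV or APOE-e4 added and report the
relative attenuation (b_base − b_adj)/b_base.

## The synthetic generator as study conditions

Each subject carries a metric-specific latent integrity factor

    L_m = Σ_j β_(j,m) · z(x_j) + ε_m,    Var(L_m) = 1,

with continuous predictors entered as empirical z-scores and binary ones
as centred indicators (so β is a group difference), exactly matching how
the battery standardizes.  The residual ε is correlated 0.7 across the
four metrics — they index one underlying tissue state, which is also why
FA and NDI findings co-occur — and is empirically standardized so the
latent variance is on target in every cohort.  Default effects are the
study-scale standardized coefficients: log-WMHV → FA/NDI/MD of
−0.09/−0.17/+0.14; a male-only amyloid effect → FA/MD of −0.04/+0.06; the
age-69 risk score → FA/NDI/MD of −0.06/−0.10/+0.09; plus nuisance-scale
sex and age effects (every model adjusts for both).  Female-only midlife
BP effects have no published magnitude; they live in a named scenario
(below), not in the defaults, so that models omitting midlife BP are not
confounded by construction.  Cohort marginals follow the published
characteristics table: n = 362, ~49% female, age 70.6 (0.7), log-normal
WMHV matched to median 2.9 mL (IQR 1.6–6.1), sex-specific brain/intracranial
volumes, SUVR from the mixture (1.0, 0.03)/(1.3, 0.1) with 16% in the upper
component, and five-wave BP trajectories with the published wave means/SDs,
within-subject persistence 0.5 and monotone binary risk factors
(smoking only quits, diabetes and treatment only accrue).

Maps are rendered as template mean field + scale_m·L_m (uniform within WM)
+ voxel noise, clipped to the metric's legal range; scales are 0.03 (FA),
3e−5 mm²/s (MD), 0.04 (NDI), 0.03 (ODI) per latent SD.  An optional
penumbra term degrades tissue within a configurable distance of lesion
voxels (FA/NDI down, MD/ODI up).  It is *off* in the study-replication
defaults: the latent WMHV effect already encodes the measured
WMHV–integrity association, and stacking a spatial lesion-proximity effect
on top would double-count it.  The penumbra mechanism is exercised by its
own tests (lesion-adjacent degradation, negative rank correlation between
lesion load and WM-mean FA).

### Calibration budget

The acceptance design requires the full image-level pipeline to give back
the encoded standardized effects, so the z-scored outcome must sit within
a few percent of unit slope in L.  Three multiplicative factors matter:
voxel noise (SD = 0.2·scale) shrinks the slope by 1/sqrt(1+0.2²) ≈ 0.980;
estimating the reference SD from ~50 subjects inflates 1/ŝ by
≈ 1 + 3/(4·n_ref) ≈ 1.015; restriction of the latent range in the
low-WMHV reference subset shrinks by ≈ 0.3% (FA) to 1% (NDI).  The product
is 0.99–1.01 of unity for every default effect — an error budget fixed at
design time, not tuned afterwards.  The noise ratio 0.2 corresponds to
smooth, QC-passed summary maps in which between-subject biological
variation dominates voxel noise; real voxel-wise diffusion data are
noisier, which would shrink recovered coefficients toward zero — passing
recovery here demonstrates correctness of the machinery, not robustness to
arbitrary noise levels.

### What the generator does not emulate

No registration error or spatial misalignment; no spatially structured
(autocorrelated) noise; no scanner or session effects; no
missing-not-at-random dropout (a missing-completely-at-random mask is
available but off by default); no attrition or sampling design; no
diffusion-signal simulation — metric maps are emitted directly.  Passing
tests therefore validate the statistical machinery under the declared
generative model, not the behaviour of the pipeline on real scanner data.

## Replication design

`replicate_study` repeats the full pipeline across seeds and averages each
recovered coefficient.  Replicates come in *antithetic pairs*: both
members share every covariate draw, lesion layout and voxel-noise stream,
and differ only in the sign of the latent residual ε.  OLS coefficients
are linear in ε given the design, so the pair mean removes the dominant
Monte Carlo term exactly; 50 replicates (25 pairs) then pin the mean
recovered coefficient to a few thousandths of an SD.  This matters most
for the male amyloid marginal slope, whose single-replicate sampling SD is
~0.2 (a binary predictor with 14% prevalence in half the sample).

The female-only midlife-SBP scenario
(`EffectConfig.sex_interaction_scenario`) sets β_female = −0.5 (FA, NDI;
+0.5 for MD) and β_male = 0 for wave-53 SBP.  The magnitude comes from an
a-priori power analysis: with ~180 subjects per sex the interaction
contrast has SE ≈ 0.105, so detecting the published qualitative pattern
(significant interaction, negative female slope, null male slope) in ≥90%
of replicates needs a contrast well above 0.35; at 0.5 the interaction
power is ≈ 0.998 and the binding constraint becomes the 95% coverage of
the male slope's CI, which caps per-replicate success near 0.95 — hence
the pattern is evaluated per metric.  Calibration-style replications
(type-I error, interaction scenario) run at table level, using the latent
factor itself as outcome, because they exercise the regression machinery
and do not depend on the imaging channel.

## Numerical and degenerate-input choices

Sample SDs use n−1 throughout.  Constant predictors raise errors rather
than propagating zero-variance z-scores.  Rank-deficient designs raise an
error naming the collinear columns (QR diagnostic).  A perfect-fit
change-residual regression (zero residual SD) leaves the standardized
change missing with a logged warning.  Lesion growth is randomized
Dijkstra flooding from Poisson-many centres, hitting the target voxel
count exactly when WM has room (and within one voxel-volume otherwise);
per-subject lesion volume is capped at half the WM volume as a physical
guard.  Clipping of rendered maps happens after noise addition; MD is
floored at 0.  File outputs use fixed float formatting so identical
config + seed reproduce byte-identical tables.

## Known limitations

The generator's linear-Gaussian latent structure cannot express
non-linear dose–response or threshold effects; the common-grid design
sidesteps registration entirely; the penumbra model is a linear ramp in
Euclidean distance; the amyloid effect enters through true component
membership, so EM misclassification (≈1–2% at the default separation)
attenuates the recovered male slope slightly; and the FDR family is fixed
per block, while other family choices (per metric, across blocks) would
change which borderline terms are flagged.
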