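# Methods

`contrapet` quantifies *remote* neuroinflammation: the TSPO-PET signal in
the hemisphere opposite a unilateral glioma. This note describes the models
the package implements, the synthetic data it validates them against, and
the numerical and design choices a maintainer should know about.

## Intensity normalization

Raw PET concentrations (kBq/mL) are converted to standardized uptake values

    SUV = C_tissue / (ID / BW),

with injected dose ID in kBq and body weight BW in g (dimensionless under
the 1 g/mL tissue convention), then intensity-normalized to the mean of a
spherical reference VOI in the pons:

    SUVr = SUV / mean(SUV | pons VOI).

The pons sphere diameter is not a universal constant; the default is 10 mm
(configurable), and the reference mean, voxel count and VOI geometry are
recorded in each output's JSON provenance sidecar. `normalize_suvr` is
defined on static volumes only — dynamic data are first reduced with
`frame_window_mean` (defaults: 60–80 min for the human protocol, 40–60 min
for the small-animal protocol).

All volumes are assumed pre-registered to one mirror-symmetric atlas grid
(RAS, mm). Under that assumption, moving a right-sided lesion to the
canonical left side is an exact reversal of the first voxel axis
(`flip_lateral`), bit-exact and involutive; grids not declared symmetric
are refused rather than resampled.

## Kinetic modeling

The one-tissue-compartment (1TC) model

    C_T(t) = K1 ∫₀ᵗ C_p(s) e^{−k2 (t−s)} ds,    VT = K1/k2

is simulated by a closed-form update that is exact for piecewise-linear
plasma input on the fine integration grid (default 0.005 min), then
averaged over acquisition frames. The synthetic plasma input is a
tri-exponential bolus C_p(t) = (A1·t − A2 − A3)e^{−λ1 t} + A2 e^{−λ2 t} +
A3 e^{−λ3 t} with C_p(0) = 0 by construction. Image-derived inputs are
per-frame means over a bilateral carotid VOI, with no partial-volume or
metabolite correction (out of scope).

Logan graphical analysis transforms a time-activity curve to
X(t) = ∫₀ᵗC_p / C_T(t), Y(t) = ∫₀ᵗC_T / C_T(t) (trapezoid integrals on
frame midpoints with a zero anchor; the plasma integral on the input's own
grid). The fit start t* is flexible: the earliest frame midpoint such that
the least-squares line through all later points keeps every included
point's **relative residual around the fitted ordinate** within the
configured maximum (default 10%, the tool convention "maximum error" is
not printed anywhere authoritative, so this interpretation is an explicit,
configurable policy). At least 3 points are required; slopes below the VT
threshold (default 0) are reported censored at the threshold; when no t*
qualifies the fit is flagged non-convergent rather than extrapolated.
Voxel-wise maps apply the same per-voxel t* policy (flagged in
provenance); VTr images divide by the mean VT over the pons VOI. On
noise-free 1TC curves with the default frame scheme the Logan slope
recovers K1/k2 to well under 1% across K1 ∈ [0.02, 0.2], k2 ∈ [0.02, 0.1];
with i.i.d. Gaussian frame noise at SNR ≥ 20 the median over replicates
stays within 5% of truth (a small negative bias at low SNR is expected for
this estimator and tolerated).

The mouse emission frame scheme is not a physical constant; the default is
6×10 s, 6×30 s, 6×60 s, 10×300 s over 0–60 min, a standard small-animal
scheme, stored in configuration.

## Tumor segmentation

Tumor extent per modality is defined on background-normalized maps: TBR
(image / mean over a contralateral white-matter VOI) and rCE
(TBR_CE / TBR_native voxel-wise; denominators below 10⁻⁶ of the background
mean are flagged missing, never infinite). Segmentation is iso-contour
region growing: all voxels ≥ threshold reachable from user seeds through
face-adjacent (default; 26-adjacency available) super-threshold voxels,
intersected with a user-supplied confining mask (the mechanism for
"cutting" adjacent sinus/calvaria). Thresholds: 1.6 for amino-acid-PET TBR
and rCE, 1.3 for T2 TBR; the TSPO-PET tumor threshold is visually defined
per subject and therefore a recorded input parameter, not a constant.
The implementation (connected-component labeling) is deterministic and is
tested for exact equality against an independent brute-force flood fill;
raising the threshold can never enlarge the mask.

## Regional statistics

A mirrored parcellation (default 123 regions per hemisphere, 246 total)
maps each subject to per-region mean SUVr, tagged
contralateral/ipsilateral relative to the canonical lesion side. Healthy
controls have no lesion side; their control value per region is the mean
of the two mirrored hemispheres (a documented convention — the source
protocol does not state one). Regions aggregate into 15 anatomo-functional
groups by voxel-count-weighted means. Group comparisons use two-sided
equal-variance t tests per region with Benjamini–Hochberg FDR across
regions ("FDR" without a named procedure defaults to BH; recorded in
provenance), pooled-SD Cohen's d, and z-scores against the control cohort
(SD with ddof 1, n ≥ 3 controls required). Effect-size profiles across
region groupings are compared by one-way fixed-effects ANOVA.

## Connectivity

Interhemispheric coupling is measured four ways: per-region Pearson
correlation of a tumor seed value across subjects (optionally partialed on
covariates); one pooled Pearson R over all (subject, region) pairs of
ipsilateral vs mirrored contralateral values; the k×k interregional
Pearson matrix across subjects ("synchronicity", summarized by its mean
off-diagonal entry); and per-voxel OLS of image value on the seed (slope
and t maps, optional Gaussian pre-smoothing, off by default). The "simple
linear regression" connectivity maps are Pearson/OLS machinery — R and the
slope differ only by scale — and no random-field correction is applied at
this scale; cohort matrices require complete cases with n reported.

## Outcome models

Partial correlation is residual-on-residual Pearson with p from a t
distribution on n−k−2 df. Multiple regression reports raw and
standardized coefficients, R², adjusted R² and the model F. Cox
proportional-hazards fits use Efron tie handling (the original software is
unstated; Efron is the better tie approximation and the lifelines
default); covariates flagged for z-transformation yield hazard ratios per
SD. Median splits put ties at the median into the low group (the high
group is strictly "> median"); log-rank and Kaplan–Meier medians come from
lifelines, with unreached medians reported as such. "Corrected for"
group comparisons are covariate-adjusted linear models (ANCOVA), which
reduce exactly to the pooled Student t when no covariates are given.
Subjects lost to follow-up are excluded from survival fits, never imputed.
TSPO-SNP binding class enters models dummy-coded by default (ordinal
coding available), flagged in output.

## Per-cell radiotracer uptake

Pellet activities are decay-corrected to injection (A₀ = A·2^{t/T½},
F-18 T½ = 109.77 min, a configurable constant), divided by the pellet cell
count, and normalized as %ID×BW = (Bq/cell ÷ ID_Bq)·100·BW_g. The
normalization is implemented literally as percent-of-dose times body
weight (unit %·g per cell); because the unit convention is a single
constant, any alternative convention is a one-line change. Purity
correction of the enriched-fraction cell count is an optional flag,
default off (whether the source data were purity-corrected is not
stated). Fold changes are ratios of group means with a one-way ANOVA
omnibus and BH-corrected pairwise t tests.

## Synthetic cohort generator

The generator reproduces the statistical structure the analysis assumes,
not anatomy or MR physics:

* **Atlas** — mirrored Voronoi parcellation of an ellipsoidal brain mask;
  exact left/right symmetry so flipping the label volume equals mirror
  relabeling; 15 groups anchored on the first 15 region seeds.
* **Subjects** — per-region targets = baseline pattern (SD 5% across
  regions) × global subject factor (lognormal, SD 10%) × per-region
  subject variability (lognormal, SD 5%) × contralateral effect for the
  glioblastoma group. The effect profile is graded over the 15 groups
  (strongest mesio-temporally, ≈ +14%) and rescaled per atlas so its
  voxel-weighted hemisphere mean equals the configured global effect
  (default +9%). The effect multiplier carries a positive coupling to two
  tumor latents (uptake severity and volume), so hotter/larger tumors have
  more elevated contralateral signal. Voxel noise is 5% multiplicative; a
  per-subject global scale factor (scanner/dose) is added and cancelled by
  the SUVr normalization. A unilateral tumor ellipsoid (uptake multiplier
  ≈ 3× baseline) plus matched CE-T1/native-T1/T2 abnormality fields give
  threshold segmentation its ground truth; geometry latents are redrawn
  until the lesion is unilateral, emulating the exclusion of
  bi-hemispheric disease. Half of the patients get right-sided lesions to
  exercise the flipping path.
* **Survival** — exponential proportional hazards, hazard
  λ₀·HR^z with z the within-group z-score of the true contralateral level,
  default HR 2.18 per SD, baseline median 12 months; non-informative
  uniform censoring C ~ U(0, c_max) with c_max solved numerically for the
  configured expected censored fraction (default 20%).
* **Pellets** — lognormal per-cell uptake with myeloid group means in the
  configured fold relations (defaults 2.8 tumor/sham and 4.2
  tumor/healthy, 15% CV; n = 13/14/8 animals), one shared
  myeloid-depleted mean across groups, per-cell activity proportional to
  injected dose per body weight (so %ID×BW cancels dosimetry), sorting
  loss 10% with enriched+depleted activities conserving the pre-sort total.

All randomness derives from one mandatory master seed through
counter-based `SeedSequence(seed, spawn_key=...)` expansion, so any
subject is reproducible in isolation and identical configurations are
bit-identical across runs.

What the generator does **not** emulate: anatomical detail, partial-volume
effects, registration error, attenuation/scatter, non-exponential
survival, and informative censoring. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated statistical
model, not robustness to real-data physics.

## Problem sizes

The default ("full") grid is 64³ at 3 mm; the fast profile used by the
recovery studies and the end-to-end tests is 32³ with the same statistical
structure, chosen so that a full cohort (41 glioblastoma / 7 IDH-mutant
astrocytoma / 20 controls) generates and analyzes in a few seconds and
100-cohort recovery studies finish in minutes. The dynamic kinetic phantom
is 16–24³ with a 28-frame 0–60 min scheme; voxel-wise Logan fits run on a
central slab plus the reference VOI.

## Pipeline and provenance

`run_pipeline` executes stages in dependency order (simulate → SUVr →
parcellate / segment / kinetics → regional stats → connectivity → outcome
→ per-cell uptake), writing TSV/JSON/NIfTI outputs plus a `manifest.json`
with per-stage parameters and SHA-256 checksums of inputs and outputs.
Re-runs skip stages whose parameters and checksums are unchanged
("cached"); a recomputed stage forces all downstream stages to recompute.
Because every stochastic stage consumes only configured seeds, two runs
from the same configuration are bit-identical (NIfTI outputs are written
uncompressed so byte equality is meaningful).

## Known limitations

* The Logan "maximum error" linearity rule is one of several conventions;
  alternative definitions would shift t* on noisy data.
* Voxel-wise Logan fitting is a plain Python loop — adequate at phantom
  scale, not optimized for whole-brain 4D fitting.
* The ANCOVA "correction" and the BH choice for "FDR" are documented
  interpretations of underspecified analysis descriptions.
* Synthetic MRI abnormality maps are flat fields with noise; they validate
  threshold/connectivity logic, not contrast physics.
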