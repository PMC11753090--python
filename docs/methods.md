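# Methods

This note documents the models, conventions and numerical choices behind
`deltarad`, and what its synthetic cohorts do and do not emulate.

## Feature extraction

Extraction is 3D and operates on a volume + binary tumor mask. The volume
is first rescaled by its own global mean so the mean becomes 100 — the mean
is taken over *all* voxels, not the tumor, because the normalization is a
per-scan gain correction for the arbitrary T2-weighted signal scale. ROI
intensities are then discretized with a fixed bin width W (default 10, i.e.
10% of the volume mean) anchored at the ROI minimum, with half-open bins:
`level(x) = floor((x − min)/W) + 1`. Because the bin width acts after
min-subtraction on mean-normalized intensities, the full 82-feature vector
is invariant under any global rescaling of the raw intensities (verified in
the test suite). No spatial resampling is performed; voxel spacing is kept
as metadata only.

Texture conventions follow the widely used radiomics-framework defaults:

* **GLCM / GLRLM** — the 13 unique offsets at Chebyshev distance 1;
  symmetric co-occurrence matrices; features computed per direction and
  averaged, unweighted, over directions that contribute at least one pair
  (run).
* **GLDM** — 26-neighbourhood, distance 1, dependence tolerance α = 0. The
  stored matrix indexes raw neighbour counts 0–26; formulas use dependence
  size = count + 1 (the center counts itself), matching the framework
  convention so that published coefficients transfer.
* **GLSZM** — zones are 26-connected components of equal gray level. Mass
  conservation Σ s·P(g, s) = N_p holds by construction and is asserted in
  tests.
* **NGTDM** — neighbourhood averages over in-mask 26-neighbours; voxels
  with no valid neighbour are excluded from the level counts.
* **First order** (7 retained) — Entropy, Uniformity (on the discretized
  histogram), Skewness, Kurtosis, Variance, Mean Absolute Deviation,
  Robust MAD (on the normalized intensities). Location/scale statistics of
  the raw signal (mean, median, range, percentiles) are excluded as
  meaningless on non-quantitative T2 images; the retained set is
  configurable because it is a catalog decision, not a mathematical one.

Degenerate cases: sum-over-unequal-pair features (e.g. GLCM Inverse
Variance on a single-level ROI) return 0; GLCM Correlation and the maximal
correlation coefficient return 1 when variance vanishes; NGTDM Coarseness
is capped at 1e6 where its denominator is 0; single-voxel ROIs return 0
for dispersion features. These conventions keep every one of the 82
features finite for any mask with ≥ 1 voxel.

Every textural feature is checked against an independent brute-force
enumeration oracle (explicit voxel-pair/run/flood-fill/neighbourhood loops
plus naive formula evaluation) at relative tolerance 1e-9 on dozens of
random ROIs.

## Harmonization

Scanner/protocol effects are removed by per-feature ordinary least squares
on an intercept + nine numeric acquisition covariates + one-hot
manufacturer (first level alphabetically as reference), fitted on the
concatenated pre+mid table, followed by z-normalization of the residuals
using moments stored from the fitting table. Anisotropy is defined as
slice thickness ÷ in-plane pixel spacing; FOV enters as one scalar.
Rank-deficient designs fall back to the minimum-norm solution with a
logged warning; constant covariates are dropped with a warning; features
with zero residual variance are flagged and excluded from modeling.

Fitting on the full concatenated data (both cohorts) follows the study
design being reproduced; it leaks validation-row information into the
transformation, which is documented and avoidable via `fit_rows` /
`harmonize_fit_on: training`.

## Robustness gate

Feature reproducibility across two raters' masks uses ICC(A,1) — two-way
random effects, absolute agreement, single measures — with the
McGraw–Wong F-based 95% CI. Absolute agreement (not consistency) is
deliberate: a systematic inter-rater shift in a feature is a real
reproducibility failure. The gate retains a feature iff ICC > 0.75
(strict) and the CI lower bound ≥ 0.60 (inclusive) at both timepoints.
ICCs are computed on raw extracted features, since robustness is a
property of extraction, before any modeling; this is switchable.

## Δfeatures and LASSO-Cox signatures

Δfeature = mid − pre of harmonized features, inner-joined on patient.
Signatures are fitted by L1-penalized Cox regression (coordinate descent
via scikit-survival's coxnet, the same algorithm family as glmnet) on
standardized features, coefficients reported on the input scale. The λ
grid is the solver's 100 log-spaced values from λ_max down to 0.001·λ_max;
λ is chosen to minimize leave-one-out cross-validated partial-likelihood
deviance computed by the leave-out-difference construction
−2·[pll(all) − pll(held-in)], which is well defined for single-observation
folds. Ties in the partial likelihood use the Breslow convention,
consistent with the solver; event times here are continuous so ties are
measure-zero. Solver tolerance is 1e-5; the zero-penalty limit is fitted
with a dedicated Newton solver and agrees with lifelines to < 1e-3.

## Survival evaluation

The time-dependent AUC is cumulative-cases / dynamic-controls at a horizon
t (default 60 months): cases progressed by t, controls event-free beyond
t, censoring handled by inverse-probability weights 1/Ĝ(T−) from the
Kaplan–Meier estimator of the censoring distribution; score ties count ½.
The paired AUC-difference test uses an influence-function (two-sample
U-statistic projection) variance with the censoring weights treated as
fixed — the censoring-estimation component largely cancels in a paired
difference on the same subjects, and the test's type-I error is verified
by simulation. The Youden cutoff maximizes IPCW sensitivity + specificity
− 1 over midpoints of adjacent observed scores, ties broken toward the
lower cutoff; it is learned on the training cohort only and frozen for
validation. Kaplan–Meier curves and log-rank tests go through lifelines;
Mann–Whitney/Wilcoxon/Spearman through scipy (Wilcoxon: zero differences
dropped, exact tie-aware null for ≤ 25 nonzero pairs); the Hodges–Lehmann
location shift is the median of all pairwise differences with the
distribution-free order-statistic CI; 2×k tables with k > 2 use exact
conditional enumeration under the multivariate hypergeometric null.

## Synthetic cohorts

The generator emulates the structure of a paired-MRI LACC cohort at desk
scale, with every knob on `SyntheticCohortSpec`:

* **Geometry** — 52×52×24 volumes; ellipsoidal tumors with radii ~12–16 ×
  10–14 × 5–6.5 voxels pre-treatment, shrunk at mid by a volume factor
  drawn from (0.35, 0.85). Real cervical tumors span far more voxels;
  these sizes are the smallest at which boundary effects behave
  realistically while keeping a full cohort extraction in seconds.
* **Texture** — Gaussian random fields (smoothed white noise) inside the
  tumor; the smoothing length acts as a "zone size" dial. A per-patient
  latent risk u ~ N(0,1) (clipped ±2.5) coarsens the mid-treatment texture
  (+0.45·u on the relative length scale; +0.15·u at baseline), so the
  planted signal lands in the GLSZM family with Δ values *lower* in
  progressors. A per-patient texture trait shared by both timepoints adds
  biological between-patient variation — it raises feature ICCs to
  realistic levels and cancels exactly in Δfeatures.
* **Raters** — both raters' masks are smooth, band-limited deformations of
  the true boundary (independent fields, independent ~10% volume jitter,
  deep core always kept), with the shared amplitude bisected per case
  until their mutual Dice hits the target (0.85 pre, 0.57 mid). Symmetry
  is essential: making rater 1 the exact geometric truth would hand rater
  2 a systematic off-tumor sampling bias that absolute-agreement ICC
  punishes out of all proportion to anything seen between two real
  radiologists.
* **Scanner effects** — image-level: noise scales with field strength and
  NEX, through-plane blur with slice thickness; table-level: an exact
  linear covariate-effect matrix (`simulate_feature_table`) for the
  harmonization unit tests.
* **Survival** — Weibull proportional hazards with shape 0.5 and baseline
  median 600 months: a falling hazard concentrates progressions early
  (median time-to-progression ~15 months) while non-progressors accrue
  long event-free follow-up, so the 60-month horizon retains both cases
  and controls. An exponential model cannot reproduce this once censoring
  is calibrated to ~68%. Uniform censoring U(0, c_max) has c_max solved by
  bisection against the requested censored fraction on the realized event
  times. The planted effect is β = 1.6 per SD of u, which puts the *true*
  risk's validation AUC near 0.87 and the *fitted* Δ-signature near
  0.75–0.80 — signature estimates are attenuated relative to the truth
  they estimate, so the planted truth must discriminate more strongly than
  the published fitted AUCs it is meant to mirror.
* **Split** — 2:1 training:validation via supervised stratification on
  event status, follow-up tertile and field strength (110 → 73/37);
  singleton strata go to training.

What passing tests on these cohorts do **not** show: the generator has no
MR physics (no bias fields, coil profiles, motion), tumors are ellipsoids
with stationary texture, and the planted risk is one-dimensional — so
end-to-end results demonstrate that the pipeline recovers a planted signal
under realistic noise, censoring and rater variability, not that any
specific clinical effect size would be attained on real patients. At the
study's own sample size (n = 110) single-cohort results are noticeably
seed-dependent, exactly as the wide confidence bands of such studies
suggest.

## Problem sizes in the test suite

Texture oracles run on ROIs up to 8×8×8 (50 random ROIs in the acceptance
suite); the LASSO recovery study uses n = 150, p = 20 over 20 replicates;
null calibrations use 500–1000 replicates of tabular data; the end-to-end
recoverability check runs ten 200-patient image cohorts through the full
pipeline. These sizes make the whole suite run in minutes while leaving
each statistical check adequately powered.
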