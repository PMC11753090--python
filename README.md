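# deltarad

Delta-radiomics prognostication for locally advanced cervical cancer (LACC)
treated with concurrent chemoradiotherapy (CCRT).

Patients with LACC are imaged with T2-weighted pelvic MRI before treatment
(pre-CCRT) and again about four weeks in (mid-CCRT). `deltarad` implements
the full analysis pipeline that turns those paired scans plus manual tumor
segmentations into validated prognostic risk scores for progression-free
survival (PFS):

1. **3D texture feature extraction** — each scan is normalized to its own
   mean (`f ← f · 100 / f̄`), discretized with a fixed bin width of 10, and
   reduced to 82 radiomic features: 7 first-order distribution-shape
   statistics plus 75 textural features from five gray-level matrix
   families (GLCM 24, GLDM 14, GLRLM 16, GLSZM 16, NGTDM 5). Shape and
   raw-signal features are deliberately excluded.
2. **Scanner harmonization** — each feature is regressed on ten acquisition
   covariates (TR, TE, flip angle, slice thickness, NEX, anisotropy, voxel
   volume, FOV, field strength, manufacturer) on the concatenated pre+mid
   table; the residuals are z-normalized to mean 0, SD 1.
3. **Robustness gating** — features are kept only when the two-rater
   intraclass correlation (ICC(A,1), two-way random effects, absolute
   agreement) exceeds 0.75 with a lower 95% confidence bound ≥ 0.60 at
   *both* timepoints. Segmentation agreement itself is summarized by the
   Dice coefficient.
4. **Δfeatures and LASSO-Cox signatures** — Δfeature = mid − pre; an
   L1-penalized Cox model on the training cohort selects features and
   coefficients, with λ chosen by leave-one-out cross-validated
   partial-likelihood deviance. The risk score is the linear combination
   `score = Σ βk · xk`.
5. **Survival evaluation** — time-dependent ROC AUC at the 5-year (60
   month) horizon with Kaplan–Meier inverse-probability-of-censoring
   weights, paired AUC comparison, Youden-index cutoff (learned on training
   only), Kaplan–Meier curves with log-rank tests, and the nonparametric
   battery (Mann–Whitney with Hodges–Lehmann location shifts, paired
   Wilcoxon, Spearman, exact 2×k tests).

The two published signatures ship with the package:

```
Delta_rad     (λ = 0.033) = −0.020·Δf1 + 0.006·Δf2 − 0.379·Δf4 + 0.044·Δf5 − 0.239·Δf7 − 0.350·Δf10
Pre-CCRT_rad  (λ = 0.019) = −0.210·f3 + 0.583·f4 − 0.094·f5 − 0.270·f6 + 0.132·f7 + 0.142·f8 + 0.128·f9
```

where f1 = GLCM Autocorrelation, f2 = GLCM Inverse Variance, f3 = GLDM
Dependence Non-Uniformity Normalized, f4 = GLDM Dependence Variance,
f5 = GLDM Gray Level Variance, f6 = GLRLM Long Run Emphasis, f7 = GLSZM
Size Zone Non-Uniformity Normalized, f8 = GLSZM Small Area Emphasis,
f9 = GLSZM Small Area High Gray Level Emphasis, f10 = GLSZM Zone
Percentage.

Because the patient data are private, the package includes a first-class
**synthetic cohort generator**: textured ellipsoidal tumors at two
timepoints with treatment-induced texture/size change, two-rater masks at
controllable Dice (≈0.85 pre, ≈0.57 mid), scanner covariate effects, and
survival drawn from a Weibull proportional-hazards model on a planted risk
variable — so every stage is testable end to end with known ground truth.

## Worked example

Scoring two patients' Δfeatures with the published delta signature:

```python
import pandas as pd
from deltarad import load_published_signatures, score

delta_sig, pre_sig = load_published_signatures()
X = pd.DataFrame({
    "GLCM Autocorrelation":                      [ 0.41, -0.86],
    "GLCM Inverse Variance":                     [ 0.12,  0.57],
    "GLDM Dependence Variance":                  [-0.93,  0.48],
    "GLDM Gray Level Variance":                  [ 0.22, -0.31],
    "GLSZM Size Zone Non-Uniformity Normalized": [-0.55,  0.24],
    "GLSZM Zone Percentage":                     [-0.10,  0.78],
}, index=["patient_A", "patient_B"])
print(score(delta_sig, X))
```

```
patient_A    0.52112
patient_B   -0.50530
```

Patient A's texture *coarsened* during treatment (Δ Dependence Variance and
Δ size-zone features fell), which the signature maps to a high risk score;
patient B moved the other way. Higher scores mean poorer predicted PFS.

A full end-to-end run on a synthetic 110-patient cohort (73/37
training/validation split, ~32% progression events):

```bash
deltarad simulate --data-dir cohort --simulate-n-patients 110 --seed 1
deltarad run-all --data-dir cohort --out-dir run --seed 1
cat run/summary.txt
```

```
deltarad run (seed 1)
retained features: 35
tdROC AUC @ 60 mo, Delta_fitted/training: 0.859
tdROC AUC @ 60 mo, Delta_fitted/validation: 0.748
tdROC AUC @ 60 mo, Pre_fitted/training: 0.725
tdROC AUC @ 60 mo, Pre_fitted/validation: 0.844
```

Here 35 of 82 features survived the two-rater robustness gate; the fitted
Δ-signature (λ = 0.051, 8 nonzero coefficients) discriminates 5-year PFS
with validation AUC 0.75, and splitting patients at the training Youden
cutoff (0.86) separates the validation Kaplan–Meier curves (log-rank
p = 0.017). The planted Δ GLSZM Size Zone Non-Uniformity Normalized is
lower in progressors (location shift −0.36, p = 0.043), the direction the
generator encodes. `run/evaluation.json` holds the full report.

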