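"""Synthetic paired-MRI cohorts with known ground truth.

Each synthetic patient carries an ellipsoidal "tumor" with Gaussian-random-
field internal texture embedded in a noisy background, imaged at two
timepoints. A latent per-patient risk u ~ N(0,1) drives three linked
phenomena:

* texture coarsening at the mid-treatment scan — higher-risk patients
  develop larger homogeneous intensity zones, so the planted signal lands in
  the GLSZM family (size-zone non-uniformity, small-area emphasis, zone
  percentage), with Δfeature values lower in progressors;
* mildly larger baseline tumors (and a weak baseline texture link, so a
  pre-treatment signature also carries signal);
* the survival hazard: event times follow a Weibull proportional-hazards
  model (decreasing hazard: progressions cluster early, non-progressors
  enjoy long event-free follow-up) with linear predictor beta·u, censored
  by independent uniform censoring calibrated to a requested censoring
  fraction.

Two raters' masks are produced per scan by symmetrically deforming the true
tumor boundary with independent smooth fields, the shared amplitude
bisected per case until the raters' mutual Dice hits a target (defaults
mirror the agreement levels of pre- and mid-treatment pelvic MRI: about
0.85 and 0.57).

Everything is deterministic under a fixed spec seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .radiomics import AcquisitionMeta, ImageVolume, TumorMask
from .robustness import dice

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCase",
    "SyntheticCohort",
    "gen_tumor_case",
    "gen_survival",
    "stratified_split",
    "gen_cohort",
    "write_cohort",
    "simulate_feature_table",
    "simulate_two_rater_features",
]

PLANTED_FEATURES = (
    "GLSZM Size Zone Non-Uniformity Normalized",
    "GLSZM Small Area Emphasis",
    "GLSZM Zone Percentage",
)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative parameters of a synthetic cohort.

    Defaults mirror the study scale: 110 patients, ~32% progression events
    (68% censoring), a 2:1 training:validation split stratified on event,
    follow-up tertile and field strength, and two-rater masks for ~25% of
    patients at Dice targets 0.85 (pre) / 0.57 (mid).
    """

    n_patients: int = 110
    seed: int = 0
    volume_shape: tuple[int, int, int] = (52, 52, 24)
    background_intensity: float = 60.0
    tumor_intensity: float = 140.0
    texture_contrast: float = 35.0
    texture_length_scale: float = 1.2
    pre_risk_texture_shift: float = 0.15
    mid_risk_texture_shift: float = 0.45
    texture_idiosyncrasy: float = 0.25  # per-patient trait, shared across timepoints
    contrast_idiosyncrasy: float = 0.15
    size_risk_shift: float = 0.08
    noise_sd: float = 6.0
    shrinkage_range: tuple[float, float] = (0.35, 0.85)  # volume factor in (0, 1]
    rater_noise: float = 1.0  # 0 disables rater-2 mask perturbation
    dice_pre: float = 0.85
    dice_mid: float = 0.57
    two_rater_fraction: float = 0.25
    planted_beta: float = 1.6
    baseline_median_months: float = 600.0
    weibull_shape: float = 0.5  # < 1: early progressions, long event-free tails
    censoring_rate: float = 0.68
    split_ratio: float = 1.0 / 3.0
    planted_features: tuple[str, ...] = PLANTED_FEATURES

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        lo, hi = self.shrinkage_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("shrinkage factors must lie in (0, 1]")


@dataclass
class SyntheticCase:
    patient_id: str
    pre: ImageVolume
    mid: ImageVolume
    pre_mask: TumorMask
    mid_mask: TumorMask
    pre_mask_r2: TumorMask | None
    mid_mask_r2: TumorMask | None
    risk: float
    diameter_cm_pre: float
    diameter_cm_mid: float


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    cases: list[SyntheticCase]
    clinical: pd.DataFrame
    truth: dict


def _grf(shape, length_scale, rng) -> np.ndarray:
    """Unit-variance Gaussian random field via smoothed white noise."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=length_scale)
    s = f.std()
    return f / s if s > 0 else f


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def _rater_pair(mask: np.ndarray, target_dice: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Two raters' masks around a true boundary, calibrated to a mutual Dice.

    Both raters deviate symmetrically from the true mask — each delineation
    is the true boundary deformed by an independent smooth field, confined to
    a boundary band (three 26-connected erosions to three dilations; the deep
    core is always kept, distant voxels are never included) and constrained
    to the true segmented volume. The shared deformation amplitude is
    bisected until Dice(rater1, rater2) hits the target. Symmetry matters:
    neither rater is systematically closer to the geometric truth, so there
    is no artificial inter-rater bias for absolute-agreement ICC to punish.
    """
    from scipy.ndimage import binary_dilation, binary_erosion

    struct = np.ones((3, 3, 3), dtype=bool)
    core = binary_erosion(mask, struct, iterations=3)
    outer = binary_dilation(mask, struct, iterations=3)
    band = outer & ~core
    base = gaussian_filter(mask.astype(float), sigma=1.5)
    noises = []
    for _ in range(2):
        z = gaussian_filter(rng.standard_normal(mask.shape), sigma=3.0)
        s = z.std()
        noises.append(z / s if s > 0 else z)

    # each rater's segmented volume differs from truth by an independent
    # ~10% jitter; boundary placement then differs by the deformation field
    n_true = int(mask.sum() - core.sum())
    jitters = [float(np.clip(1.0 + 0.10 * rng.standard_normal(), 0.7, 1.3))
               for _ in range(2)]

    def realize(amp, which):
        n_band = int(np.clip(round(n_true * jitters[which]), 0, int(band.sum())))
        if n_band <= 0:
            return core.copy()
        field = base + amp * noises[which]
        vals = field[band]
        thr = np.partition(vals, len(vals) - n_band)[len(vals) - n_band]
        return core | (band & (field >= thr))

    def d(amp):
        m1 = realize(amp, 0)
        m2 = realize(amp, 1)
        if not (m1.any() and m2.any()):
            return 0.0
        return dice(TumorMask(m1), TumorMask(m2))

    lo, hi = 0.0, 0.25
    while d(hi) > target_dice and hi < 64.0:
        hi *= 2.0
    if d(hi) > target_dice:
        warnings.warn(
            f"rater boundary noise cannot reach Dice {target_dice}; "
            f"achieved {d(hi):.2f}"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if d(mid) > target_dice:
            lo = mid
        else:
            hi = mid
    amp = 0.5 * (lo + hi)
    m1 = realize(amp, 0)
    m2 = realize(amp, 1)
    if not m1.any() or not m2.any():
        m1, m2 = mask.copy(), mask.copy()
    return m1, m2


def _sample_meta(rng, timepoint: str) -> AcquisitionMeta:
    if timepoint == "pre":
        manufacturer = ("GE", "Philips", "Siemens")[rng.integers(0, 3)]
        field_strength = 1.5 if rng.random() < 60 / 110 else 3.0
    else:
        manufacturer = ("GE", "Siemens")[rng.integers(0, 2)]
        field_strength = 1.5 if rng.random() < 79 / 110 else 3.0
    thick = float(rng.choice([3.0, 4.0]))
    px = float(rng.uniform(0.5, 0.9))
    return AcquisitionMeta(
        tr_ms=float(rng.uniform(3000, 6000)),
        te_ms=float(rng.uniform(80, 120)),
        flip_angle_deg=float(rng.uniform(88, 92)),
        slice_thickness_mm=thick,
        nex=float(rng.choice([1.0, 2.0])),
        anisotropy=thick / px,
        voxel_volume_mm3=px * px * thick,
        fov_mm=float(rng.uniform(200, 280)),
        field_strength_t=field_strength,
        manufacturer=manufacturer,
    )


def _render(spec, shape, mask, length_scale, contrast, meta, rng) -> np.ndarray:
    img = np.full(shape, spec.background_intensity, dtype=float)
    tex = _grf(shape, length_scale, rng)
    img[mask] = spec.tumor_intensity + contrast * tex[mask]
    # covariate-linked image degradation: partial-volume blur along z from
    # slice thickness, noise level from field strength and averaging
    zsig = 0.35 * meta.slice_thickness_mm / 3.0
    img = gaussian_filter(img, sigma=(0.4, 0.4, zsig))
    noise_sd = spec.noise_sd * np.sqrt(1.5 / meta.field_strength_t) / np.sqrt(meta.nex)
    img = img + noise_sd * rng.standard_normal(shape)
    return img


def gen_tumor_case(
    spec: SyntheticCohortSpec, patient_index: int, two_rater: bool = True
) -> SyntheticCase:
    """Generate one patient's paired volumes, masks and metadata.

    Deterministic in (spec.seed, patient_index); the latent risk is stored on
    the returned case.
    """
    rng = np.random.default_rng([spec.seed, patient_index])
    shape = spec.volume_shape
    u = float(np.clip(rng.standard_normal(), -2.5, 2.5))

    size_scale = 1.0 + spec.size_risk_shift * u
    rx = rng.uniform(12.0, 16.0) * size_scale
    ry = rng.uniform(10.0, 14.0) * size_scale
    rz = rng.uniform(5.0, 6.5) * size_scale
    center = (
        shape[0] / 2 + rng.uniform(-2, 2),
        shape[1] / 2 + rng.uniform(-2, 2),
        shape[2] / 2 + rng.uniform(-1, 1),
    )
    for r, n in zip((rx, ry, rz), shape):
        if 2 * r >= n:
            raise ValueError(f"tumor radius {r:.1f} does not fit volume extent {n}")

    shrink_vol = rng.uniform(*spec.shrinkage_range)
    f_lin = shrink_vol ** (1.0 / 3.0)
    radii_pre = (rx, ry, rz)
    radii_mid = tuple(max(1.5, r * f_lin) for r in radii_pre)

    # patient-level texture traits common to both timepoints: they raise
    # between-patient variance (hence feature ICC) but cancel in Δfeatures
    e_tex = float(np.clip(rng.standard_normal(), -2.0, 2.0))
    e_con = float(np.clip(rng.standard_normal(), -2.0, 2.0))
    ls0 = spec.texture_length_scale
    trait = spec.texture_idiosyncrasy * e_tex
    ls_pre = max(0.4, ls0 * (1.0 + spec.pre_risk_texture_shift * u + trait))
    ls_mid = max(0.4, ls0 * (1.0 + spec.mid_risk_texture_shift * u + trait))
    contrast = spec.texture_contrast * max(0.3, 1.0 + spec.contrast_idiosyncrasy * e_con)

    meta_pre = _sample_meta(rng, "pre")
    meta_mid = _sample_meta(rng, "mid")
    mask_pre = _ellipsoid(shape, center, radii_pre)
    mask_mid = _ellipsoid(shape, center, radii_mid)

    img_pre = _render(spec, shape, mask_pre, ls_pre, contrast, meta_pre, rng)
    img_mid = _render(spec, shape, mask_mid, ls_mid, contrast, meta_mid, rng)

    pid = f"P{patient_index:04d}"
    px_pre = np.sqrt(meta_pre.voxel_volume_mm3 / meta_pre.slice_thickness_mm)
    spacing_pre = (px_pre, px_pre, meta_pre.slice_thickness_mm)
    px_mid = np.sqrt(meta_mid.voxel_volume_mm3 / meta_mid.slice_thickness_mm)
    spacing_mid = (px_mid, px_mid, meta_mid.slice_thickness_mm)

    # rater masks are always drawn (keeps the RNG stream identical whether or
    # not the second rater's mask is kept for this patient)
    if spec.rater_noise == 0:
        r1_pre, r2_pre = mask_pre.copy(), mask_pre.copy()
        r1_mid, r2_mid = mask_mid.copy(), mask_mid.copy()
    else:
        r1_pre, r2_pre = _rater_pair(mask_pre, spec.dice_pre, rng)
        r1_mid, r2_mid = _rater_pair(mask_mid, spec.dice_mid, rng)
    r2_pre_m = TumorMask(r2_pre) if two_rater else None
    r2_mid_m = TumorMask(r2_mid) if two_rater else None

    diam_pre = 2 * max(rx * px_pre, ry * px_pre, rz * meta_pre.slice_thickness_mm) / 10.0
    diam_mid = diam_pre * f_lin
    return SyntheticCase(
        patient_id=pid,
        pre=ImageVolume(img_pre, spacing_pre, meta_pre, scan_id=f"{pid}_pre"),
        mid=ImageVolume(img_mid, spacing_mid, meta_mid, scan_id=f"{pid}_mid"),
        pre_mask=TumorMask(r1_pre),
        mid_mask=TumorMask(r1_mid),
        pre_mask_r2=r2_pre_m,
        mid_mask_r2=r2_mid_m,
        risk=u,
        diameter_cm_pre=float(diam_pre),
        diameter_cm_mid=float(diam_mid),
    )


def gen_survival(
    spec: SyntheticCohortSpec, scores_truth: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Event/censoring times from an exponential proportional-hazards model.

    The linear predictor is ``planted_beta * scores_truth``; independent
    uniform censoring C ~ U(0, c_max) is calibrated by bisection so the
    expected censored fraction matches ``spec.censoring_rate``.
    """
    u = np.asarray(scores_truth, dtype=float)
    n = len(u)
    lp = spec.planted_beta * u
    k = spec.weibull_shape
    h0 = np.log(2.0) / spec.baseline_median_months ** k
    # Weibull proportional hazards: S(t) = exp(-h0 t^k e^lp); shape < 1 gives
    # a falling hazard — early progressions, long event-free survival after
    T = (rng.exponential(1.0, size=n) / (h0 * np.exp(lp))) ** (1.0 / k)

    target = spec.censoring_rate
    if target <= 0:
        time, event = T, np.ones(n, dtype=int)
    else:
        if target >= 1:
            warnings.warn(f"censoring rate {target} unattainable; using 0.99")
            target = 0.99

        def frac_cens(cmax):
            return float(np.minimum(T / cmax, 1.0).mean())

        lo, hi = 1e-3, 1e7
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if frac_cens(mid) > target:
                lo = mid
            else:
                hi = mid
        cmax = np.sqrt(lo * hi)
        achieved = frac_cens(cmax)
        if abs(achieved - spec.censoring_rate) > 0.05:
            warnings.warn(
                f"requested censoring {spec.censoring_rate:.2f}, "
                f"achieved {achieved:.2f}"
            )
        C = np.maximum(rng.uniform(0.0, cmax, size=n), 1e-6)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    return pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "time_months": time,
        "event": event,
    })


def stratified_split(
    records: pd.DataFrame,
    ratio: float = 1.0 / 3.0,
    strata: list[str] | None = None,
    seed: int = 0,
) -> pd.Series:
    """Seeded 2:1 training/validation assignment with supervised
    stratification on event status, follow-up-time tertile, and any extra
    strata columns (e.g. field strength). Singleton strata go to training."""
    from sklearn.model_selection import train_test_split

    df = records.reset_index(drop=True)
    n = len(df)
    tert = pd.qcut(df["time_months"], 3, labels=False, duplicates="drop")
    label = df["event"].astype(int).astype(str) + "|" + tert.astype(str)
    for c in strata or []:
        label = label + "|" + df[c].astype(str)

    counts = label.value_counts()
    singleton = label.isin(counts[counts < 2].index)
    if singleton.any():
        warnings.warn(
            f"{int(singleton.sum())} subject(s) in singleton strata assigned to training"
        )
    pool = df.index[~singleton]
    n_val = int(np.ceil(n * ratio))
    n_val = min(n_val, max(len(pool) - 1, 0))
    cohort = pd.Series("training", index=df.index, name="cohort")
    if n_val >= 1:
        val_idx = None
        for strat in (label[pool], df.loc[pool, "event"], None):
            try:
                _, val_idx = train_test_split(
                    pool, test_size=n_val, stratify=strat, random_state=seed
                )
                break
            except ValueError:
                continue
        if val_idx is None:
            warnings.warn("cohort too small to split; all subjects in training")
        else:
            if strat is not label[pool]:
                warnings.warn("full stratification infeasible; coarser split used")
            cohort.loc[val_idx] = "validation"
    else:
        warnings.warn("cohort too small to split; all subjects in training")
    cohort.index = records.index
    return cohort


_FIGO_PROBS = {1: 0.07, 2: 0.35, 3: 0.52, 4: 0.06}


def gen_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate the full cohort: cases, clinical table, split, ground truth."""
    n = spec.n_patients
    sel_rng = np.random.default_rng([spec.seed, 999_983])
    n_two = max(3, int(round(spec.two_rater_fraction * n)))
    two_rater_ids = set(sel_rng.choice(n, size=min(n_two, n), replace=False).tolist())

    cases = [
        gen_tumor_case(spec, i, two_rater=(i in two_rater_ids)) for i in range(n)
    ]
    u = np.array([c.risk for c in cases])

    surv_rng = np.random.default_rng([spec.seed, 424_242])
    surv = gen_survival(spec, u, surv_rng)

    # ordinal FIGO-like stage weakly linked to risk
    figo_rng = np.random.default_rng([spec.seed, 77_777])
    latent = 0.35 * u + figo_rng.standard_normal(n)
    qs = np.cumsum([_FIGO_PROBS[k] for k in (1, 2, 3)])
    cuts = np.quantile(latent, qs)
    figo = np.digitize(latent, cuts) + 1

    clinical = surv.copy()
    clinical["figo_stage"] = figo
    clinical["tumor_diameter_cm_pre"] = [c.diameter_cm_pre for c in cases]
    clinical["tumor_diameter_cm_mid"] = [c.diameter_cm_mid for c in cases]
    clinical["field_strength_t"] = [c.pre.meta.field_strength_t for c in cases]
    clinical["cohort"] = stratified_split(
        clinical, ratio=spec.split_ratio, strata=["field_strength_t"], seed=spec.seed
    ).to_numpy()
    clinical = clinical.drop(columns=["field_strength_t"])

    truth = {
        "risk": u.tolist(),
        "log_hazard": (spec.planted_beta * u).tolist(),
        "planted_features": list(spec.planted_features),
        "planted_beta": spec.planted_beta,
        "two_rater_ids": sorted(f"P{i:04d}" for i in two_rater_ids),
        "spec": dataclasses.asdict(spec),
    }
    return SyntheticCohort(spec=spec, cases=cases, clinical=clinical, truth=truth)


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write a cohort in the on-disk layout the pipeline reads: NIfTI
    volumes/masks, metadata.csv, clinical.csv and ground_truth.json."""
    import os

    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)

    meta_rows = []
    for case in cohort.cases:
        for tp, vol, m1, m2 in (
            ("pre", case.pre, case.pre_mask, case.pre_mask_r2),
            ("mid", case.mid, case.mid_mask, case.mid_mask_r2),
        ):
            affine = np.diag(list(vol.spacing) + [1.0])
            base = os.path.join(img_dir, f"{case.patient_id}_{tp}")
            nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), affine),
                     base + ".nii.gz")
            nib.save(nib.Nifti1Image(m1.voxels.astype(np.uint8), affine),
                     base + "_mask_r1.nii.gz")
            if m2 is not None:
                nib.save(nib.Nifti1Image(m2.voxels.astype(np.uint8), affine),
                         base + "_mask_r2.nii.gz")
            meta_rows.append({"patient_id": case.patient_id, "timepoint": tp,
                              **vol.meta.as_dict()})
    pd.DataFrame(meta_rows).to_csv(os.path.join(out_dir, "metadata.csv"), index=False)
    cohort.clinical.to_csv(os.path.join(out_dir, "clinical.csv"), index=False)
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Feature-level simulators (fast paths for the tabular stages)
# ---------------------------------------------------------------------------


def simulate_feature_table(
    n_rows: int = 200,
    n_features: int = 10,
    seed: int = 0,
    covariate_effects: dict[str, dict[str, float]] | None = None,
    vendor_offsets: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 1.0,
    signal: np.ndarray | None = None,
    signal_loadings: dict[str, float] | None = None,
) -> pd.DataFrame:
    """A patients x features table with planted linear covariate
    contamination — the exact setting the harmonization step removes.

    Features are named ``f0``..``f{p-1}``. ``covariate_effects`` maps feature
    -> {numeric covariate -> slope}; ``vendor_offsets`` maps feature ->
    {manufacturer -> additive offset}; ``signal_loadings`` plants a
    biological signal (per-row ``signal`` vector) into chosen features.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_rows):
        meta = _sample_meta(rng, "pre" if i % 2 == 0 else "mid")
        rows.append({"patient_id": f"P{i // 2:04d}",
                     "timepoint": "pre" if i % 2 == 0 else "mid",
                     **meta.as_dict()})
    df = pd.DataFrame(rows)
    feats = [f"f{j}" for j in range(n_features)]
    X = noise_sd * rng.standard_normal((n_rows, n_features))
    for j, f in enumerate(feats):
        for cov, slope in (covariate_effects or {}).get(f, {}).items():
            X[:, j] += slope * df[cov].to_numpy(dtype=float)
        for vendor, off in (vendor_offsets or {}).get(f, {}).items():
            X[:, j] += off * (df["manufacturer"] == vendor).to_numpy(dtype=float)
        if signal is not None and signal_loadings and f in signal_loadings:
            X[:, j] += signal_loadings[f] * np.asarray(signal, dtype=float)
    df[feats] = X
    return df


def simulate_two_rater_features(
    n_subjects: int = 40,
    n_reproducible: int = 10,
    n_noisy: int = 10,
    reproducible_noise_sd: float = 0.15,
    noisy_noise_sd: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Two raters' feature tables with planted reproducibility structure.

    Every feature has unit between-subject variance; reproducible features
    get small independent rater noise, noise-dominated ones get large noise.
    Returns (rater1, rater2, names_of_reproducible_features).
    """
    rng = np.random.default_rng(seed)
    names = [f"f{j}" for j in range(n_reproducible + n_noisy)]
    subj = rng.standard_normal((n_subjects, len(names)))
    sds = np.array([reproducible_noise_sd] * n_reproducible + [noisy_noise_sd] * n_noisy)
    r1 = subj + sds * rng.standard_normal(subj.shape)
    r2 = subj + sds * rng.standard_normal(subj.shape)
    ids = [f"P{i:04d}" for i in range(n_subjects)]
    t1 = pd.DataFrame(r1, columns=names)
    t1.insert(0, "patient_id", ids)
    t2 = pd.DataFrame(r2, columns=names)
    t2.insert(0, "patient_id", ids)
    return t1, t2, names[:n_reproducible]
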