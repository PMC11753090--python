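"""3D radiomic texture feature extraction from a tumor volume and mask.

Implements the 82-feature catalog used throughout the package: 7 first-order
distribution-shape features plus 75 textural features from five gray-level
matrix families (GLCM, GLDM, GLRLM, GLSZM, NGTDM), computed in 3D on a
mean-normalized, fixed-bin-width discretized region of interest.

Conventions (matching the common radiomics-framework defaults):

* intensity normalization rescales the whole volume so its mean is 100;
* discretization uses half-open bins of fixed width anchored at the ROI
  minimum, level(x) = floor((x - min)/W) + 1;
* GLCM and GLRLM are computed per direction over the 13 unique 3D offsets at
  Chebyshev distance 1, features averaged over directions that contribute;
* GLDM uses the 26-neighbourhood with dependence tolerance alpha = 0;
* GLSZM zones and NGTDM neighbourhoods use 26-connectivity;
* degenerate denominators follow a documented policy: sum-over-unequal-pair
  features return 0, NGTDM Coarseness is capped at a large finite value.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "AcquisitionMeta",
    "ImageVolume",
    "TumorMask",
    "DiscretizedROI",
    "ExtractionConfig",
    "FeatureVector",
    "FEATURE_CATALOG",
    "FEATURE_CLASS_COUNTS",
    "FEATURE_ALIASES",
    "canonical_feature_name",
    "normalize_intensity",
    "discretize_fixed_bin_width",
    "glcm_features",
    "gldm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "first_order_features",
    "extract_feature_vector",
]

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

MANUFACTURERS = ("GE", "Philips", "Siemens")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Per-scan acquisition parameters used as harmonization covariates."""

    tr_ms: float
    te_ms: float
    flip_angle_deg: float
    slice_thickness_mm: float
    nex: float
    anisotropy: float
    voxel_volume_mm3: float
    fov_mm: float
    field_strength_t: float
    manufacturer: str

    def __post_init__(self) -> None:
        for name in (
            "tr_ms", "te_ms", "flip_angle_deg", "slice_thickness_mm",
            "nex", "anisotropy", "voxel_volume_mm3", "fov_mm",
            "field_strength_t",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"AcquisitionMeta.{name} must be finite and > 0, got {v!r}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


COVARIATE_COLUMNS = [
    "tr_ms", "te_ms", "flip_angle_deg", "slice_thickness_mm", "nex",
    "anisotropy", "voxel_volume_mm3", "fov_mm", "field_strength_t",
    "manufacturer",
]


@dataclass
class ImageVolume:
    """A 3D scalar image with voxel spacing and optional acquisition metadata."""

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: AcquisitionMeta | None = None
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.intensities.shape}")
        if min(self.intensities.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"non-finite intensities in volume {self.scan_id!r}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class TumorMask:
    """Binary segmentation congruent with an :class:`ImageVolume`."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.voxels.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class DiscretizedROI:
    """Integer gray levels (1..n_levels) inside the mask, 0 outside."""

    levels: np.ndarray  # int array, 0 outside mask
    n_levels: int
    n_voxels: int
    bin_width: float

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0


DEFAULT_FIRST_ORDER = (
    "Entropy",
    "Uniformity",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Mean Absolute Deviation",
    "Robust Mean Absolute Deviation",
)


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable extraction settings.

    bin_width: intensity units of the fixed-width discretization bins (after
        mean-normalization to 100, so a width of 10 is 10% of the volume mean).
    first_order: which first-order distribution features to retain.
    coarseness_cap: finite value returned for NGTDM Coarseness when its
        denominator vanishes (uniform ROI).
    """

    bin_width: float = 10.0
    first_order: tuple[str, ...] = DEFAULT_FIRST_ORDER
    coarseness_cap: float = 1.0e6

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


GLCM_FEATURES = (
    "Autocorrelation", "Joint Average", "Cluster Prominence", "Cluster Shade",
    "Cluster Tendency", "Contrast", "Correlation", "Difference Average",
    "Difference Entropy", "Difference Variance", "Joint Energy",
    "Joint Entropy", "Informational Measure of Correlation 1",
    "Informational Measure of Correlation 2", "Inverse Difference Moment",
    "Inverse Difference Moment Normalized", "Inverse Difference",
    "Inverse Difference Normalized", "Inverse Variance",
    "Maximum Probability", "Maximal Correlation Coefficient", "Sum Average",
    "Sum Entropy", "Sum of Squares",
)

GLDM_FEATURES = (
    "Small Dependence Emphasis", "Large Dependence Emphasis",
    "Gray Level Non-Uniformity", "Dependence Non-Uniformity",
    "Dependence Non-Uniformity Normalized", "Gray Level Variance",
    "Dependence Variance", "Dependence Entropy", "Low Gray Level Emphasis",
    "High Gray Level Emphasis", "Small Dependence Low Gray Level Emphasis",
    "Small Dependence High Gray Level Emphasis",
    "Large Dependence Low Gray Level Emphasis",
    "Large Dependence High Gray Level Emphasis",
)

GLRLM_FEATURES = (
    "Short Run Emphasis", "Long Run Emphasis", "Gray Level Non-Uniformity",
    "Gray Level Non-Uniformity Normalized", "Run Length Non-Uniformity",
    "Run Length Non-Uniformity Normalized", "Run Percentage",
    "Gray Level Variance", "Run Variance", "Run Entropy",
    "Low Gray Level Run Emphasis", "High Gray Level Run Emphasis",
    "Short Run Low Gray Level Emphasis", "Short Run High Gray Level Emphasis",
    "Long Run Low Gray Level Emphasis", "Long Run High Gray Level Emphasis",
)

GLSZM_FEATURES = (
    "Small Area Emphasis", "Large Area Emphasis", "Gray Level Non-Uniformity",
    "Gray Level Non-Uniformity Normalized", "Size Zone Non-Uniformity",
    "Size Zone Non-Uniformity Normalized", "Zone Percentage",
    "Gray Level Variance", "Zone Variance", "Zone Entropy",
    "Low Gray Level Zone Emphasis", "High Gray Level Zone Emphasis",
    "Small Area Low Gray Level Emphasis", "Small Area High Gray Level Emphasis",
    "Large Area Low Gray Level Emphasis", "Large Area High Gray Level Emphasis",
)

NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

FEATURE_CLASS_COUNTS = {
    "First Order": 7,
    "GLCM": 24,
    "GLDM": 14,
    "GLRLM": 16,
    "GLSZM": 16,
    "NGTDM": 5,
}


def _build_catalog(config: ExtractionConfig | None = None) -> list[str]:
    cfg = config or ExtractionConfig()
    names = [f"First Order {n}" for n in cfg.first_order]
    names += [f"GLCM {n}" for n in GLCM_FEATURES]
    names += [f"GLDM {n}" for n in GLDM_FEATURES]
    names += [f"GLRLM {n}" for n in GLRLM_FEATURES]
    names += [f"GLSZM {n}" for n in GLSZM_FEATURES]
    names += [f"NGTDM {n}" for n in NGTDM_FEATURES]
    return names


FEATURE_CATALOG: list[str] = _build_catalog()

# Alternate printed spellings accepted when resolving signature coefficients.
FEATURE_ALIASES = {
    "GLSZM Zone%": "GLSZM Zone Percentage",
    "GLCM Sum Squares": "GLCM Sum of Squares",
    "First Order MAD": "First Order Mean Absolute Deviation",
}


def canonical_feature_name(name: str) -> str:
    return FEATURE_ALIASES.get(name, name)


class FeatureVector(Mapping):
    """Ordered feature-name -> value map with a catalog identifier."""

    def __init__(self, values: dict[str, float], catalog_version: str = "default-82"):
        self._values = dict(values)
        self.catalog_version = catalog_version

    def __getitem__(self, key):
        return self._values[canonical_feature_name(key)]

    def __iter__(self):
        return iter(self._values)

    def __len__(self):
        return len(self._values)

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)


# ---------------------------------------------------------------------------
# Normalization and discretization
# ---------------------------------------------------------------------------


def normalize_intensity(vol: ImageVolume) -> ImageVolume:
    """Rescale a volume by its own mean so the output mean equals 100.

    The mean is taken over the whole data set (all voxels), not only the
    tumor, so the transformation is a single global gain factor.
    """
    mean = float(vol.intensities.mean())
    if not np.isfinite(mean) or mean == 0.0:
        raise ValueError(
            f"cannot normalize scan {vol.scan_id!r}: volume mean is {mean!r}"
        )
    return ImageVolume(
        intensities=vol.intensities * (100.0 / mean),
        spacing=vol.spacing,
        meta=vol.meta,
        scan_id=vol.scan_id,
    )


def discretize_fixed_bin_width(
    vol: ImageVolume, mask: TumorMask, bin_width: float = 10.0
) -> DiscretizedROI:
    """Map ROI intensities to integer gray levels with fixed-width bins.

    level(x) = floor((x - min_ROI)/W) + 1, so the minimum-intensity voxel maps
    to level 1 and bins are half-open [min + (k-1)W, min + kW).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if mask.shape != vol.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume shape {vol.shape}"
        )
    m = mask.voxels
    n_vox = int(m.sum())
    if n_vox == 0:
        raise ValueError(f"empty mask for scan {vol.scan_id!r}")
    roi = vol.intensities[m]
    lo = roi.min()
    levels = np.zeros(vol.shape, dtype=np.int64)
    levels[m] = np.floor((vol.intensities[m] - lo) / bin_width).astype(np.int64) + 1
    n_levels = int(levels.max())
    return DiscretizedROI(levels=levels, n_levels=n_levels, n_voxels=n_vox,
                          bin_width=bin_width)


# ---------------------------------------------------------------------------
# Offset machinery
# ---------------------------------------------------------------------------

# The 13 unique 3D direction offsets at Chebyshev distance 1 (half of the
# 26-neighbourhood; the other half are their negatives).
OFFSETS_13 = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

OFFSETS_26 = OFFSETS_13 + tuple(tuple(-o for o in off) for off in OFFSETS_13)


def _shift_slices(shape, off):
    """Slices (src, dst) such that arr[src] and arr[dst] pair x with x + off."""
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm_matrices(roi: DiscretizedROI) -> list[np.ndarray]:
    """Symmetric GLCM count matrices, one per direction with >= 1 pair."""
    lv = roi.levels
    ng = roi.n_levels
    out = []
    for off in OFFSETS_13:
        src, dst = _shift_slices(lv.shape, off)
        a = lv[src].ravel()
        b = lv[dst].ravel()
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        idx = (a[ok] - 1) * ng + (b[ok] - 1)
        c = np.bincount(idx, minlength=ng * ng).reshape(ng, ng).astype(float)
        out.append(c + c.T)
    return out


def _glcm_single(P: np.ndarray, ng: int) -> dict[str, float]:
    iv = np.arange(1, ng + 1, dtype=float)
    I = iv[:, None]
    J = iv[None, :]
    px = P.sum(axis=1)  # symmetric: px == py
    mu = float((iv * px).sum())
    sig2 = float(((iv - mu) ** 2 * px).sum())
    sig = np.sqrt(sig2)

    ksum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.bincount((np.add.outer(np.arange(ng), np.arange(ng))).ravel(),
                        weights=P.ravel(), minlength=2 * ng - 1)
    kdiff = np.arange(0, ng, dtype=float)
    p_diff = np.bincount(np.abs(np.subtract.outer(np.arange(ng), np.arange(ng))).ravel(),
                         weights=P.ravel(), minlength=ng)

    da = float((kdiff * p_diff).sum())
    hx = _entropy2(px)
    hxy = _entropy2(P.ravel())
    pos = P > 0
    outer = np.outer(px, px)
    hxy1 = float(-(P[pos] * np.log2(outer[pos])).sum()) if pos.any() else 0.0
    opos = outer > 0
    hxy2 = float(-(outer[opos] * np.log2(outer[opos])).sum()) if opos.any() else 0.0

    if hx > 0:
        imc1 = (hxy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sig2 > 0:
        corr = float(((I * J * P).sum() - mu * mu) / sig2)
    else:
        corr = 1.0

    # Maximal correlation coefficient: sqrt of second-largest eigenvalue of Q
    present = px > 0
    if present.sum() <= 1:
        mcc = 1.0
    else:
        Ps = P[np.ix_(present, present)]
        pxs = px[present]
        A = Ps / pxs[:, None]
        B = Ps / pxs[None, :]
        Q = A @ B.T
        eig = np.linalg.eigvals(Q)
        eig = np.sort(np.real(eig))[::-1]
        mcc = float(np.sqrt(max(0.0, eig[1]))) if eig.size > 1 else 1.0

    dmask = I != J
    diff2 = (I - J) ** 2

    return {
        "Autocorrelation": float((I * J * P).sum()),
        "Joint Average": mu,
        "Cluster Prominence": float(((I + J - 2 * mu) ** 4 * P).sum()),
        "Cluster Shade": float(((I + J - 2 * mu) ** 3 * P).sum()),
        "Cluster Tendency": float(((I + J - 2 * mu) ** 2 * P).sum()),
        "Contrast": float((diff2 * P).sum()),
        "Correlation": corr,
        "Difference Average": da,
        "Difference Entropy": _entropy2(p_diff),
        "Difference Variance": float(((kdiff - da) ** 2 * p_diff).sum()),
        "Joint Energy": float((P ** 2).sum()),
        "Joint Entropy": hxy,
        "Informational Measure of Correlation 1": imc1,
        "Informational Measure of Correlation 2": imc2,
        "Inverse Difference Moment": float((P / (1.0 + diff2)).sum()),
        "Inverse Difference Moment Normalized": float((P / (1.0 + diff2 / ng ** 2)).sum()),
        "Inverse Difference": float((P / (1.0 + np.abs(I - J))).sum()),
        "Inverse Difference Normalized": float((P / (1.0 + np.abs(I - J) / ng)).sum()),
        "Inverse Variance": float((P[dmask] / diff2[dmask]).sum()) if dmask.any() else 0.0,
        "Maximum Probability": float(P.max()),
        "Maximal Correlation Coefficient": mcc,
        "Sum Average": float((ksum * p_sum).sum()),
        "Sum Entropy": _entropy2(p_sum),
        "Sum of Squares": sig2,
    }


def glcm_features(roi: DiscretizedROI) -> dict[str, float]:
    """24 GLCM features, computed per direction and averaged."""
    mats = glcm_matrices(roi)
    if not mats:
        # no voxel pair in any direction (e.g. single-voxel ROI)
        vals = {n: 0.0 for n in GLCM_FEATURES}
        vals["Correlation"] = 1.0
        vals["Maximal Correlation Coefficient"] = 1.0
        return vals
    per_dir = [_glcm_single(m / m.sum(), roi.n_levels) for m in mats]
    return {n: float(np.mean([d[n] for d in per_dir])) for n in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------


def gldm_matrix(roi: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Counts P(i, d): voxels of level i with d dependent 26-neighbours.

    A neighbour is dependent when |level difference| <= alpha. Columns run
    from d = 0 (isolated voxel) to d = 26.
    """
    lv = roi.levels
    dep = np.zeros(lv.shape, dtype=np.int64)
    for off in OFFSETS_26:
        src, dst = _shift_slices(lv.shape, off)
        ok = (lv[src] > 0) & (lv[dst] > 0) & (np.abs(lv[src] - lv[dst]) <= alpha)
        dep[src] += ok
    m = roi.mask
    ng = roi.n_levels
    idx = (lv[m] - 1) * 27 + dep[m]
    return np.bincount(idx, minlength=ng * 27).reshape(ng, 27).astype(float)


def gldm_features(roi: DiscretizedROI) -> dict[str, float]:
    """14 GLDM features. Dependence size in the formulas is d + 1 (the center
    voxel counts itself), matching the framework convention."""
    P = gldm_matrix(roi)
    ng = roi.n_levels
    nz = P.sum()
    iv = np.arange(1, ng + 1, dtype=float)[:, None]
    jv = np.arange(1, 28, dtype=float)[None, :]  # dependence size = d + 1
    p = P / nz
    pg = P.sum(axis=1)  # per gray level
    pd = P.sum(axis=0)  # per dependence
    mu_i = float((iv[:, 0] * pg / nz).sum())
    mu_j = float((jv[0, :] * pd / nz).sum())
    return {
        "Small Dependence Emphasis": float((P / jv ** 2).sum() / nz),
        "Large Dependence Emphasis": float((P * jv ** 2).sum() / nz),
        "Gray Level Non-Uniformity": float((pg ** 2).sum() / nz),
        "Dependence Non-Uniformity": float((pd ** 2).sum() / nz),
        "Dependence Non-Uniformity Normalized": float((pd ** 2).sum() / nz ** 2),
        "Gray Level Variance": float((p * (iv - mu_i) ** 2).sum()),
        "Dependence Variance": float((p * (jv - mu_j) ** 2).sum()),
        "Dependence Entropy": _entropy2(p.ravel()),
        "Low Gray Level Emphasis": float((P / iv ** 2).sum() / nz),
        "High Gray Level Emphasis": float((P * iv ** 2).sum() / nz),
        "Small Dependence Low Gray Level Emphasis": float((P / (iv ** 2 * jv ** 2)).sum() / nz),
        "Small Dependence High Gray Level Emphasis": float((P * iv ** 2 / jv ** 2).sum() / nz),
        "Large Dependence Low Gray Level Emphasis": float((P * jv ** 2 / iv ** 2).sum() / nz),
        "Large Dependence High Gray Level Emphasis": float((P * iv ** 2 * jv ** 2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def glrlm_matrices(roi: DiscretizedROI) -> list[np.ndarray]:
    """Run-length count matrices P(i, r), one per direction."""
    lv = roi.levels
    shape = lv.shape
    ng = roi.n_levels
    max_run = max(shape)
    inmask = lv > 0
    out = []
    for off in OFFSETS_13:
        src, dst = _shift_slices(shape, off)
        same = np.zeros(shape, dtype=bool)
        same[src] = inmask[src] & inmask[dst] & (lv[src] == lv[dst])
        # run length looking forward: rl(x) = 1 + rl(x + off) when same
        rl = inmask.astype(np.int64)
        for _ in range(max_run):
            nxt = np.zeros(shape, dtype=np.int64)
            nxt[src] = rl[dst]
            new = np.where(same, 1 + nxt, inmask.astype(np.int64))
            if np.array_equal(new, rl):
                break
            rl = new
        prev_same = np.zeros(shape, dtype=bool)
        prev_same[dst] = same[src]
        starts = inmask & ~prev_same
        levels = lv[starts] - 1
        lengths = rl[starts]
        idx = levels * max_run + (lengths - 1)
        P = np.bincount(idx, minlength=ng * max_run).reshape(ng, max_run).astype(float)
        out.append(P)
    return out


def _rl_single(P: np.ndarray, n_vox: int) -> dict[str, float]:
    ng, mr = P.shape
    nr = P.sum()
    iv = np.arange(1, ng + 1, dtype=float)[:, None]
    rv = np.arange(1, mr + 1, dtype=float)[None, :]
    p = P / nr
    pg = P.sum(axis=1)
    pr = P.sum(axis=0)
    mu_i = float((iv[:, 0] * pg / nr).sum())
    mu_r = float((rv[0, :] * pr / nr).sum())
    return {
        "Short Run Emphasis": float((P / rv ** 2).sum() / nr),
        "Long Run Emphasis": float((P * rv ** 2).sum() / nr),
        "Gray Level Non-Uniformity": float((pg ** 2).sum() / nr),
        "Gray Level Non-Uniformity Normalized": float((pg ** 2).sum() / nr ** 2),
        "Run Length Non-Uniformity": float((pr ** 2).sum() / nr),
        "Run Length Non-Uniformity Normalized": float((pr ** 2).sum() / nr ** 2),
        "Run Percentage": float(nr / n_vox),
        "Gray Level Variance": float((p * (iv - mu_i) ** 2).sum()),
        "Run Variance": float((p * (rv - mu_r) ** 2).sum()),
        "Run Entropy": _entropy2(p.ravel()),
        "Low Gray Level Run Emphasis": float((P / iv ** 2).sum() / nr),
        "High Gray Level Run Emphasis": float((P * iv ** 2).sum() / nr),
        "Short Run Low Gray Level Emphasis": float((P / (iv ** 2 * rv ** 2)).sum() / nr),
        "Short Run High Gray Level Emphasis": float((P * iv ** 2 / rv ** 2).sum() / nr),
        "Long Run Low Gray Level Emphasis": float((P * rv ** 2 / iv ** 2).sum() / nr),
        "Long Run High Gray Level Emphasis": float((P * iv ** 2 * rv ** 2).sum() / nr),
    }


def glrlm_features(roi: DiscretizedROI) -> dict[str, float]:
    """16 run-length features averaged over the 13 directions."""
    per_dir = [_rl_single(P, roi.n_voxels) for P in glrlm_matrices(roi)]
    return {n: float(np.mean([d[n] for d in per_dir])) for n in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(roi: DiscretizedROI) -> np.ndarray:
    """Zone count matrix P(i, s): 26-connected zones of level i and size s."""
    lv = roi.levels
    ng = roi.n_levels
    max_zone = roi.n_voxels
    P = np.zeros((ng, max_zone), dtype=float)
    for g in range(1, ng + 1):
        sel = lv == g
        if not sel.any():
            continue
        lab, nlab = ndimage.label(sel, structure=_STRUCT_26)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s, cnt in zip(*np.unique(sizes, return_counts=True)):
            P[g - 1, s - 1] += cnt
    return P


def glszm_features(roi: DiscretizedROI) -> dict[str, float]:
    """16 size-zone features from a single 26-connectivity zone matrix."""
    P = glszm_matrix(roi)
    ng, ms = P.shape
    nz = P.sum()
    iv = np.arange(1, ng + 1, dtype=float)[:, None]
    sv = np.arange(1, ms + 1, dtype=float)[None, :]
    p = P / nz
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    mu_i = float((iv[:, 0] * pg / nz).sum())
    mu_s = float((sv[0, :] * ps / nz).sum())
    return {
        "Small Area Emphasis": float((P / sv ** 2).sum() / nz),
        "Large Area Emphasis": float((P * sv ** 2).sum() / nz),
        "Gray Level Non-Uniformity": float((pg ** 2).sum() / nz),
        "Gray Level Non-Uniformity Normalized": float((pg ** 2).sum() / nz ** 2),
        "Size Zone Non-Uniformity": float((ps ** 2).sum() / nz),
        "Size Zone Non-Uniformity Normalized": float((ps ** 2).sum() / nz ** 2),
        "Zone Percentage": float(nz / roi.n_voxels),
        "Gray Level Variance": float((p * (iv - mu_i) ** 2).sum()),
        "Zone Variance": float((p * (sv - mu_s) ** 2).sum()),
        "Zone Entropy": _entropy2(p.ravel()),
        "Low Gray Level Zone Emphasis": float((P / iv ** 2).sum() / nz),
        "High Gray Level Zone Emphasis": float((P * iv ** 2).sum() / nz),
        "Small Area Low Gray Level Emphasis": float((P / (iv ** 2 * sv ** 2)).sum() / nz),
        "Small Area High Gray Level Emphasis": float((P * iv ** 2 / sv ** 2).sum() / nz),
        "Large Area Low Gray Level Emphasis": float((P * sv ** 2 / iv ** 2).sum() / nz),
        "Large Area High Gray Level Emphasis": float((P * iv ** 2 * sv ** 2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def ngtdm_table(roi: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """Per-level (n_i, s_i): voxel counts and summed absolute differences
    from the mean level of in-mask 26-neighbours. Voxels without any in-mask
    neighbour are excluded from both."""
    lv = roi.levels
    shape = lv.shape
    ng = roi.n_levels
    nbr_sum = np.zeros(shape, dtype=float)
    nbr_cnt = np.zeros(shape, dtype=np.int64)
    inmask = lv > 0
    for off in OFFSETS_26:
        src, dst = _shift_slices(shape, off)
        nbr_sum[src] += np.where(inmask[dst], lv[dst], 0)
        nbr_cnt[src] += inmask[dst]
    valid = inmask & (nbr_cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        abar = np.where(valid, nbr_sum / np.maximum(nbr_cnt, 1), 0.0)
    diffs = np.abs(lv - abar)[valid]
    levels = lv[valid] - 1
    n_i = np.bincount(levels, minlength=ng).astype(float)
    s_i = np.bincount(levels, weights=diffs, minlength=ng)
    return n_i, s_i


def ngtdm_features(roi: DiscretizedROI, coarseness_cap: float = 1.0e6) -> dict[str, float]:
    """The five neighbourhood gray-tone difference features."""
    n_i, s_i = ngtdm_table(roi)
    ng = roi.n_levels
    nvp = n_i.sum()
    p_i = n_i / nvp if nvp > 0 else n_i
    iv = np.arange(1, ng + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())

    coars_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coars_den if coars_den > 0 else coarseness_cap
    coarseness = min(coarseness, coarseness_cap)

    if ngp > 1:
        pi = p_i[present]
        ii = iv[present]
        d2 = (ii[:, None] - ii[None, :]) ** 2
        contrast = float((pi[:, None] * pi[None, :] * d2).sum()) / (ngp * (ngp - 1))
        contrast *= float(s_i.sum()) / nvp
        busy_den = float(np.abs(ii[:, None] * pi[:, None] - ii[None, :] * pi[None, :]).sum())
        busyness = coars_den / busy_den if busy_den > 0 else 0.0
        si = s_i[present]
        num = np.abs(ii[:, None] - ii[None, :]) * (
            (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
            / (pi[:, None] + pi[None, :])
        )
        complexity = float(num.sum()) / nvp
        s_tot = float(s_i.sum())
        strength = (
            float(((pi[:, None] + pi[None, :]) * d2).sum()) / s_tot if s_tot > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# First order
# ---------------------------------------------------------------------------


def first_order_features(
    vol: ImageVolume,
    mask: TumorMask,
    roi: DiscretizedROI,
    which: tuple[str, ...] = DEFAULT_FIRST_ORDER,
) -> dict[str, float]:
    """Distribution-shape statistics of the (normalized) ROI intensities.

    Entropy and Uniformity are computed on the discretized level histogram;
    the moment-based features use the continuous intensities. Dispersion
    features of a constant ROI return 0 (Uniformity returns 1).
    """
    x = vol.intensities[mask.voxels]
    if x.size == 0:
        raise ValueError(f"empty mask for scan {vol.scan_id!r}")
    p = np.bincount(roi.levels[roi.mask] - 1, minlength=roi.n_levels) / roi.n_voxels

    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())

    p10, p90 = np.percentile(x, [10, 90])
    sub = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(sub - sub.mean()).mean()) if sub.size else 0.0

    vals = {
        "Entropy": _entropy2(p),
        "Uniformity": float((p ** 2).sum()),
        "Skewness": m3 / m2 ** 1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2 ** 2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Mean Absolute Deviation": float(np.abs(x - mean).mean()),
        "Robust Mean Absolute Deviation": rmad,
    }
    missing = [w for w in which if w not in vals]
    if missing:
        raise KeyError(f"unknown first-order features requested: {missing}")
    return {w: vals[w] for w in which}


# ---------------------------------------------------------------------------
# Full 82-feature extraction
# ---------------------------------------------------------------------------


def extract_feature_vector(
    vol: ImageVolume,
    mask: TumorMask,
    config: ExtractionConfig | None = None,
) -> FeatureVector:
    """Extract the full 82-feature vector from one volume + mask in 3D.

    Applies mean-normalization, fixed-bin-width discretization, then all six
    feature families. Deterministic for fixed input.
    """
    cfg = config or ExtractionConfig()
    if mask.shape != vol.shape:
        raise ValueError(
            f"scan {vol.scan_id!r}: mask shape {mask.shape} != volume shape {vol.shape}"
        )
    if mask.n_voxels == 0:
        raise ValueError(f"scan {vol.scan_id!r}: mask has no foreground voxels")
    try:
        norm = normalize_intensity(vol)
        # crop to the mask bounding box (one-voxel margin); texture matrices
        # only involve in-mask voxels, so this changes nothing but speed
        idx = np.nonzero(mask.voxels)
        sl = tuple(
            slice(max(int(i.min()) - 1, 0), min(int(i.max()) + 2, n))
            for i, n in zip(idx, mask.shape)
        )
        norm = ImageVolume(norm.intensities[sl], norm.spacing, norm.meta, norm.scan_id)
        mask = TumorMask(mask.voxels[sl])
        roi = discretize_fixed_bin_width(norm, mask, cfg.bin_width)
        values: dict[str, float] = {}
        for name, v in first_order_features(norm, mask, roi, cfg.first_order).items():
            values[f"First Order {name}"] = v
        for name, v in glcm_features(roi).items():
            values[f"GLCM {name}"] = v
        for name, v in gldm_features(roi).items():
            values[f"GLDM {name}"] = v
        for name, v in glrlm_features(roi).items():
            values[f"GLRLM {name}"] = v
        for name, v in glszm_features(roi).items():
            values[f"GLSZM {name}"] = v
        for name, v in ngtdm_features(roi, cfg.coarseness_cap).items():
            values[f"NGTDM {name}"] = v
    except ValueError as err:
        raise ValueError(f"feature extraction failed for scan {vol.scan_id!r}: {err}") from err
    return FeatureVector(values)
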