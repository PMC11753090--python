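"""Segmentation agreement and feature-reproducibility gating.

Two radiologists segmenting the same tumors rarely produce identical masks;
the Dice similarity coefficient quantifies mask overlap and the intraclass
correlation coefficient (ICC) quantifies how reproducible each radiomic
feature is across the two raters' masks. Features pass the robustness gate
only when ICC > 0.75 with a lower 95% confidence bound >= 0.60 at *both*
imaging timepoints.

The ICC model is two-way random effects, absolute agreement, single measures
(McGraw & Wong case 2A,1) with the F-based 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .radiomics import FEATURE_CATALOG, TumorMask

__all__ = [
    "ICCResult",
    "RobustFeatureSet",
    "dice",
    "icc_two_way",
    "icc_table",
    "select_robust_features",
]


def dice(a: TumorMask, b: TumorMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two masks."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        raise ValueError("both masks are empty; Dice undefined")
    inter = int((a.voxels & b.voxels).sum())
    return 2.0 * inter / (na + nb)


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    n_subjects: int
    n_raters: int


def icc_two_way(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    Parameters
    ----------
    ratings : (n_subjects, n_raters) matrix; n_subjects >= 3.

    Returns the point estimate with the F-based (1 - alpha) confidence
    interval. Raises if the total variance is zero (ICC undefined).
    """
    Y = np.asarray(ratings, dtype=float)
    if Y.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    n, k = Y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects for an ICC")
    if k < 2:
        raise ValueError("need at least 2 raters")
    if np.ptp(Y) == 0:
        raise ValueError("zero total variance: ICC undefined")

    grand = Y.mean()
    rowm = Y.mean(axis=1)
    colm = Y.mean(axis=0)
    msr = k * ((rowm - grand) ** 2).sum() / (n - 1)
    msc = n * ((colm - grand) ** 2).sum() / (k - 1)
    mse = ((Y - rowm[:, None] - colm[None, :] + grand) ** 2).sum() / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("zero denominator: ICC undefined")
    r = (msr - mse) / denom

    if mse == 0 and msc == 0:
        # raters agree exactly on every subject
        return ICCResult(1.0, 1.0, 1.0, n, k)

    # McGraw & Wong F-based interval for case 2A single measures
    with np.errstate(divide="ignore", invalid="ignore"):
        a = k * r / (n * (1.0 - r)) if r < 1 else np.inf
        b = 1.0 + k * r * (n - 1) / (n * (1.0 - r)) if r < 1 else np.inf
    if np.isfinite(a) and np.isfinite(b) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    else:
        v = n - 1
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)

    lower = float(np.clip(lower, -1.0, 1.0))
    upper = float(np.clip(upper, -1.0, 1.0))
    est = float(np.clip(r, -1.0, 1.0))
    lower = min(lower, est)
    upper = max(upper, est)
    return ICCResult(est, lower, upper, n, k)


def icc_table(
    rater1: pd.DataFrame, rater2: pd.DataFrame, features: list[str]
) -> dict[str, ICCResult]:
    """Per-feature ICC from two raters' feature tables (aligned on patient_id)."""
    a = rater1.set_index("patient_id") if "patient_id" in rater1 else rater1
    b = rater2.set_index("patient_id") if "patient_id" in rater2 else rater2
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common subjects for ICC")
    out = {}
    for f in features:
        ratings = np.column_stack([
            a.loc[common, f].to_numpy(dtype=float),
            b.loc[common, f].to_numpy(dtype=float),
        ])
        try:
            out[f] = icc_two_way(ratings)
        except ValueError:
            # undefined ICC (constant feature): treat as non-reproducible
            out[f] = ICCResult(np.nan, np.nan, np.nan, len(common), 2)
    return out


@dataclass
class RobustFeatureSet:
    retained: list[str]
    pre_icc: dict[str, ICCResult] = field(default_factory=dict)
    mid_icc: dict[str, ICCResult] = field(default_factory=dict)

    def report(self) -> dict:
        def _d(r: ICCResult):
            return {
                "icc": None if np.isnan(r.estimate) else r.estimate,
                "ci_lower": None if np.isnan(r.ci_lower) else r.ci_lower,
                "ci_upper": None if np.isnan(r.ci_upper) else r.ci_upper,
            }

        return {
            "retained": self.retained,
            "pre": {f: _d(r) for f, r in self.pre_icc.items()},
            "mid": {f: _d(r) for f, r in self.mid_icc.items()},
        }


def select_robust_features(
    pre_icc: dict[str, ICCResult],
    mid_icc: dict[str, ICCResult],
    threshold: float = 0.75,
    ci_floor: float = 0.60,
) -> RobustFeatureSet:
    """Apply the robustness gate at both timepoints.

    A feature is retained iff estimate > ``threshold`` (strict) and
    ci_lower >= ``ci_floor`` at pre *and* at mid. Output order follows the
    feature catalog for catalog features, input order otherwise.
    """
    missing = set(pre_icc) ^ set(mid_icc)
    if missing:
        raise KeyError(f"feature keys differ between timepoints: {sorted(missing)}")

    def passes(r: ICCResult) -> bool:
        return (
            np.isfinite(r.estimate)
            and np.isfinite(r.ci_lower)
            and r.estimate > threshold
            and r.ci_lower >= ci_floor
        )

    names = list(pre_icc)
    ordered = [f for f in FEATURE_CATALOG if f in pre_icc]
    ordered += [f for f in names if f not in set(ordered)]
    retained = [f for f in ordered if passes(pre_icc[f]) and passes(mid_icc[f])]
    return RobustFeatureSet(retained=retained, pre_icc=pre_icc, mid_icc=mid_icc)
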