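"""Scanner/protocol-effect harmonization of radiomic feature tables.

Two-step procedure applied to the concatenated pre- and mid-treatment rows:

1. each feature is regressed (ordinary least squares) on the acquisition
   covariates — TR, TE, flip angle, slice thickness, NEX, anisotropy, voxel
   volume, FOV, field strength, and a one-hot encoded manufacturer — and the
   linear prediction is subtracted, leaving residuals;
2. the residuals are z-normalized to mean 0 and standard deviation 1 using
   moments stored from the fitting table.

The regression is fitted on the full concatenated data set by default (both
cohorts, both timepoints). Because the z-moments and regression coefficients
then see validation rows, a ``fit_rows`` argument is provided to restrict
fitting to (for example) the training cohort when leakage must be avoided.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .radiomics import COVARIATE_COLUMNS, FEATURE_CATALOG

__all__ = [
    "HarmonizationModel",
    "NUMERIC_COVARIATES",
    "feature_columns",
    "fit_harmonization",
    "apply_harmonization",
]

logger = logging.getLogger(__name__)

NUMERIC_COVARIATES = [c for c in COVARIATE_COLUMNS if c != "manufacturer"]


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a table, in catalog order where possible."""
    in_catalog = [c for c in FEATURE_CATALOG if c in table.columns]
    if in_catalog:
        return in_catalog
    reserved = {"patient_id", "timepoint", "rater", "cohort"} | set(COVARIATE_COLUMNS)
    return [c for c in table.columns if c not in reserved]


@dataclass
class HarmonizationModel:
    """Per-feature OLS coefficients plus post-residual z-moments."""

    design_columns: list[str]
    manufacturer_levels: list[str]
    dropped_covariates: list[str]
    coefficients: pd.DataFrame  # design_columns x features
    residual_mean: pd.Series
    residual_sd: pd.Series
    degenerate_features: list[str] = field(default_factory=list)

    @property
    def features(self) -> list[str]:
        return list(self.coefficients.columns)

    def to_json(self, path) -> None:
        payload = {
            "design_columns": self.design_columns,
            "manufacturer_levels": self.manufacturer_levels,
            "dropped_covariates": self.dropped_covariates,
            "coefficients": {f: self.coefficients[f].tolist() for f in self.features},
            "residual_mean": self.residual_mean.to_dict(),
            "residual_sd": self.residual_sd.to_dict(),
            "degenerate_features": self.degenerate_features,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "HarmonizationModel":
        with open(path) as fh:
            d = json.load(fh)
        feats = list(d["coefficients"])
        coef = pd.DataFrame(
            {f: d["coefficients"][f] for f in feats}, index=d["design_columns"]
        )
        return cls(
            design_columns=d["design_columns"],
            manufacturer_levels=d["manufacturer_levels"],
            dropped_covariates=d["dropped_covariates"],
            coefficients=coef,
            residual_mean=pd.Series(d["residual_mean"]),
            residual_sd=pd.Series(d["residual_sd"]),
            degenerate_features=d["degenerate_features"],
        )


def _design_matrix(
    table: pd.DataFrame,
    manufacturer_levels: list[str],
    numeric_cols: list[str],
) -> np.ndarray:
    n = len(table)
    cols = [np.ones(n)]
    for c in numeric_cols:
        v = table[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"covariate column {c!r} contains non-finite values")
        cols.append(v)
    # one-hot with the first (alphabetical) level as reference
    seen = set(table["manufacturer"].astype(str))
    unknown = seen - set(manufacturer_levels)
    if unknown:
        raise ValueError(
            f"unseen manufacturer level(s) {sorted(unknown)}; "
            f"model knows {manufacturer_levels}"
        )
    for lev in manufacturer_levels[1:]:
        cols.append((table["manufacturer"].astype(str) == lev).to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_harmonization(
    table: pd.DataFrame,
    features: list[str] | None = None,
    fit_rows: np.ndarray | None = None,
) -> HarmonizationModel:
    """Fit per-feature OLS residualization + z-moments on a feature table.

    Parameters
    ----------
    table : rows are (patient, timepoint) scans with covariate and feature
        columns; pre- and mid-treatment rows are expected concatenated.
    features : feature columns to harmonize (default: all catalog features
        present in the table).
    fit_rows : optional boolean row selector restricting the fit (e.g. to the
        training cohort); transformation is still applicable to all rows.
    """
    feats = features if features is not None else feature_columns(table)
    if not feats:
        raise ValueError("no feature columns found to harmonize")
    fit_tab = table if fit_rows is None else table.loc[np.asarray(fit_rows)]

    numeric = []
    dropped = []
    for c in NUMERIC_COVARIATES:
        v = fit_tab[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            dropped.append(c)
            warnings.warn(f"covariate {c!r} is constant on the fitting table; dropped")
        else:
            numeric.append(c)
    manufacturer_levels = sorted(set(fit_tab["manufacturer"].astype(str)))

    X = _design_matrix(fit_tab, manufacturer_levels, numeric)
    n, k = X.shape
    if n < k + 2:
        raise ValueError(
            f"need at least {k + 2} rows to fit a {k}-column design, got {n}"
        )
    Y = fit_tab[feats].to_numpy(dtype=float)
    # minimum-norm least squares handles rank-deficient designs
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < k:
        logger.warning("harmonization design is rank-deficient (rank %d < %d); "
                       "minimum-norm solution used", rank, k)
    resid = Y - X @ beta
    rmean = resid.mean(axis=0)
    rsd = resid.std(axis=0, ddof=0)
    degenerate = [f for f, s in zip(feats, rsd) if s == 0]
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} feature(s) have zero residual variance and are "
            f"flagged for exclusion from modeling: {degenerate[:5]}..."
        )
    rsd_safe = np.where(rsd > 0, rsd, 1.0)

    design_columns = ["intercept"] + numeric + [
        f"manufacturer[{lev}]" for lev in manufacturer_levels[1:]
    ]
    return HarmonizationModel(
        design_columns=design_columns,
        manufacturer_levels=manufacturer_levels,
        dropped_covariates=dropped,
        coefficients=pd.DataFrame(beta, index=design_columns, columns=feats),
        residual_mean=pd.Series(rmean, index=feats),
        residual_sd=pd.Series(rsd_safe, index=feats),
        degenerate_features=degenerate,
    )


def apply_harmonization(model: HarmonizationModel, table: pd.DataFrame) -> pd.DataFrame:
    """Residualize and z-normalize features using a fitted model.

    Output schema equals the input schema (same columns, same order); only
    the harmonized feature columns change. Applied to its own fitting table,
    each feature column has mean 0 and SD 1 (degenerate zero-variance
    features excepted — they come out identically 0).
    """
    numeric = [c for c in NUMERIC_COVARIATES if c not in model.dropped_covariates]
    X = _design_matrix(table, model.manufacturer_levels, numeric)
    feats = model.features
    Y = table[feats].to_numpy(dtype=float)
    resid = Y - X @ model.coefficients.to_numpy()
    z = (resid - model.residual_mean.to_numpy()) / model.residual_sd.to_numpy()
    out = table.copy()
    out[feats] = z
    return out
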