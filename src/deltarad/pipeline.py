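"""End-to-end workflow orchestration.

Stages run in the study's order — extract → harmonize → robustness-gate →
Δfeatures → signature fit/score → survival evaluation — each writing its
artifact (CSV/JSON) into the run directory. Stage outputs are pure functions
of (inputs, config, seed); reports carry no timestamps so identical runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import harmonization as hz
from . import robustness as rb
from . import signatures as sg
from . import simulate as sim
from . import survival as sv
from .radiomics import (
    COVARIATE_COLUMNS,
    AcquisitionMeta,
    ExtractionConfig,
    ImageVolume,
    TumorMask,
    extract_feature_vector,
)

__all__ = ["RunConfig", "ValidationReport", "validate_inputs", "run_pipeline"]

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = [
    "patient_id", "time_months", "event", "cohort", "figo_stage",
    "tumor_diameter_cm_pre", "tumor_diameter_cm_mid",
]


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    data_dir: str = ""
    out_dir: str = "deltarad_run"
    bin_width: float = 10.0
    harmonize_fit_on: str = "all"  # "all" (study convention) or "training"
    icc_threshold: float = 0.75
    icc_ci_floor: float = 0.60
    signature_mode: str = "fit"  # "fit" or "published"
    horizon_months: float = 60.0
    seed: int = 0
    simulate_n_patients: int = 0  # > 0: generate a synthetic cohort first

    def __post_init__(self) -> None:
        if self.signature_mode not in ("fit", "published"):
            raise ValueError(f"signature_mode must be fit|published, got {self.signature_mode!r}")
        if self.harmonize_fit_on not in ("all", "training"):
            raise ValueError("harmonize_fit_on must be all|training")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be > 0")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def persist(self) -> None:
        os.makedirs(self.out_dir, exist_ok=True)
        with open(os.path.join(self.out_dir, "run_config.json"), "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def _sha(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _load_nifti(path: str):
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def _scan_paths(data_dir: str, patient_id: str, tp: str) -> dict[str, str]:
    base = os.path.join(data_dir, "images", f"{patient_id}_{tp}")
    return {
        "volume": base + ".nii.gz",
        "mask": base + "_mask_r1.nii.gz",
        "mask_r2": base + "_mask_r2.nii.gz",
    }


def validate_inputs(data_dir: str) -> ValidationReport:
    """Check volume/mask congruence, metadata completeness and clinical
    schema; fatal issues are accumulated, not fail-fast."""
    rep = ValidationReport()
    meta_path = os.path.join(data_dir, "metadata.csv")
    clin_path = os.path.join(data_dir, "clinical.csv")
    for p in (meta_path, clin_path):
        if not os.path.exists(p):
            rep.fatal.append(f"missing required file: {p}")
    if rep.fatal:
        return rep

    meta = pd.read_csv(meta_path)
    clinical = pd.read_csv(clin_path)

    for c in ["patient_id", "timepoint"] + COVARIATE_COLUMNS:
        if c not in meta.columns:
            rep.fatal.append(f"metadata.csv missing column {c!r}")
        elif c not in ("patient_id", "timepoint", "manufacturer") and meta[c].isna().any():
            bad = meta.loc[meta[c].isna(), "patient_id"].tolist()
            rep.fatal.append(f"metadata.csv column {c!r} missing for scans {bad[:5]}")
    if meta.duplicated(["patient_id", "timepoint"]).any():
        dups = meta.loc[meta.duplicated(["patient_id", "timepoint"]), "patient_id"]
        rep.fatal.append(f"duplicate (patient_id, timepoint) rows: {dups.tolist()[:5]}")

    for c in ("patient_id", "time_months", "event", "cohort"):
        if c not in clinical.columns:
            rep.fatal.append(f"clinical.csv missing column {c!r}")
    if "event" in clinical.columns and not clinical["event"].isin([0, 1]).all():
        rep.fatal.append("clinical.csv event column must be 0/1")
    if "time_months" in clinical.columns and (clinical["time_months"] <= 0).any():
        rep.fatal.append("clinical.csv contains non-positive follow-up times")
    if "patient_id" in clinical.columns and clinical["patient_id"].duplicated().any():
        rep.fatal.append("duplicate patient_id in clinical.csv")

    if "patient_id" in meta.columns and "timepoint" in meta.columns:
        for _, row in meta.iterrows():
            paths = _scan_paths(data_dir, row["patient_id"], row["timepoint"])
            if not os.path.exists(paths["volume"]):
                rep.fatal.append(f"missing volume: {paths['volume']}")
                continue
            if not os.path.exists(paths["mask"]):
                rep.fatal.append(f"missing mask: {paths['mask']}")
                continue
            vol, _ = _load_nifti(paths["volume"])
            msk, _ = _load_nifti(paths["mask"])
            if vol.shape != msk.shape:
                rep.fatal.append(
                    f"{row['patient_id']} {row['timepoint']}: mask shape "
                    f"{msk.shape} != volume shape {vol.shape}"
                )
            elif not (msk > 0).any():
                rep.warnings.append(
                    f"{row['patient_id']} {row['timepoint']}: empty mask"
                )
    return rep


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig) -> str:
    spec = sim.SyntheticCohortSpec(n_patients=cfg.simulate_n_patients, seed=cfg.seed)
    cohort = sim.gen_cohort(spec)
    data_dir = os.path.join(cfg.out_dir, "synthetic_data")
    sim.write_cohort(cohort, data_dir)
    logger.info("simulated cohort of %d patients into %s", spec.n_patients, data_dir)
    return data_dir


def stage_extract(cfg: RunConfig, data_dir: str, rater: int = 1) -> pd.DataFrame:
    """Extract the 82-feature vector for every (patient, timepoint) scan."""
    meta = pd.read_csv(os.path.join(data_dir, "metadata.csv"))
    ex_cfg = ExtractionConfig(bin_width=cfg.bin_width)
    rows = []
    for _, m in meta.iterrows():
        pid, tp = m["patient_id"], m["timepoint"]
        paths = _scan_paths(data_dir, pid, tp)
        mask_path = paths["mask"] if rater == 1 else paths["mask_r2"]
        if rater == 2 and not os.path.exists(mask_path):
            continue
        try:
            data, spacing = _load_nifti(paths["volume"])
            mdata, _ = _load_nifti(mask_path)
            am = AcquisitionMeta(**{c: m[c] for c in COVARIATE_COLUMNS})
            vol = ImageVolume(data, spacing, am, scan_id=f"{pid}_{tp}")
            fv = extract_feature_vector(vol, TumorMask(mdata > 0.5), ex_cfg)
        except Exception as err:
            raise RuntimeError(
                f"stage extract failed for record {pid}/{tp}: {err}"
            ) from err
        rows.append({"patient_id": pid, "timepoint": tp,
                     **{c: m[c] for c in COVARIATE_COLUMNS}, **fv.as_dict()})
        logger.debug("extracted %s %s (volume %s)", pid, tp, _sha(paths["volume"]))
    return pd.DataFrame(rows)


def stage_harmonize(cfg: RunConfig, features: pd.DataFrame,
                    clinical: pd.DataFrame) -> tuple[pd.DataFrame, hz.HarmonizationModel]:
    fit_rows = None
    if cfg.harmonize_fit_on == "training":
        train_ids = set(clinical.loc[clinical["cohort"] == "training", "patient_id"])
        fit_rows = features["patient_id"].isin(train_ids).to_numpy()
    model = hz.fit_harmonization(features, fit_rows=fit_rows)
    return hz.apply_harmonization(model, features), model


def stage_robustness(cfg: RunConfig, raw_r1: pd.DataFrame,
                     raw_r2: pd.DataFrame) -> rb.RobustFeatureSet:
    feats = hz.feature_columns(raw_r1)
    iccs = {}
    for tp in ("pre", "mid"):
        a = raw_r1[raw_r1["timepoint"] == tp]
        b = raw_r2[raw_r2["timepoint"] == tp]
        common = set(a["patient_id"]) & set(b["patient_id"])
        iccs[tp] = rb.icc_table(
            a[a["patient_id"].isin(common)], b[b["patient_id"].isin(common)], feats
        )
    return rb.select_robust_features(
        iccs["pre"], iccs["mid"], threshold=cfg.icc_threshold, ci_floor=cfg.icc_ci_floor
    )


def _split_timepoints(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    pre = features[features["timepoint"] == "pre"].copy()
    mid = features[features["timepoint"] == "mid"].copy()
    return pre, mid


def stage_fit(cfg: RunConfig, delta: pd.DataFrame, pre: pd.DataFrame,
              clinical: pd.DataFrame,
              retained: list[str]) -> tuple[sg.RadiomicSignature, sg.RadiomicSignature]:
    if cfg.signature_mode == "published":
        return sg.load_published_signatures()
    train = clinical[clinical["cohort"] == "training"]
    sig_delta = sg.fit_lasso_cox(delta, train, name="Delta_fitted")
    pre_x = pre.set_index("patient_id")[retained]
    sig_pre = sg.fit_lasso_cox(pre_x, train, name="Pre_fitted")
    return sig_delta, sig_pre


def _safe_auc(scores: pd.Series, clin: pd.DataFrame, horizon: float, marker: str):
    aligned = clin.set_index("patient_id").loc[scores.index]
    try:
        r = sv.td_auc(scores.to_numpy(), aligned["time_months"].to_numpy(),
                      aligned["event"].to_numpy(), horizon, marker=marker)
        return {"auc": r.auc, "se": r.se, "n_cases": r.n_cases,
                "n_controls": r.n_controls}
    except ValueError as err:
        return {"auc": None, "error": str(err)}


def stage_evaluate(cfg: RunConfig, scores: dict[str, pd.Series],
                   delta: pd.DataFrame, clinical: pd.DataFrame) -> dict:
    """tdROC AUCs per cohort, Youden cutoff + KM/log-rank risk groups, and
    progressor vs non-progressor Δfeature location shifts."""
    clin = clinical.set_index("patient_id")
    report: dict = {"horizon_months": cfg.horizon_months, "auc": {}, "km": {},
                    "cutoffs": {}, "delta_shifts": {}}
    for name, s in scores.items():
        for cohort in ("training", "validation"):
            ids = clin.index[clin["cohort"] == cohort].intersection(s.index)
            report["auc"][f"{name}/{cohort}"] = _safe_auc(
                s.loc[ids], clinical, cfg.horizon_months, name
            )
        # cutoff learned on training only, frozen for validation
        tr_ids = clin.index[clin["cohort"] == "training"].intersection(s.index)
        try:
            cut = sv.youden_cutoff(
                s.loc[tr_ids].to_numpy(),
                clin.loc[tr_ids, "time_months"].to_numpy(),
                clin.loc[tr_ids, "event"].to_numpy(),
                cfg.horizon_months,
            )
            report["cutoffs"][name] = cut
            for cohort in ("training", "validation"):
                ids = clin.index[clin["cohort"] == cohort].intersection(s.index)
                groups = np.where(s.loc[ids] > cut, "high", "low")
                if len(set(groups)) < 2:
                    report["km"][f"{name}/{cohort}"] = {"error": "single risk group"}
                    continue
                cmp_, _curves = sv.km_logrank(
                    groups,
                    clin.loc[ids, "time_months"].to_numpy(),
                    clin.loc[ids, "event"].to_numpy(),
                )
                report["km"][f"{name}/{cohort}"] = {
                    "logrank_statistic": cmp_.statistic, "p_value": cmp_.p_value,
                }
        except ValueError as err:
            report["cutoffs"][name] = None
            report["km"][name] = {"error": str(err)}

    prog_ids = clin.index[clin["event"] == 1].intersection(delta.index)
    nonprog_ids = clin.index[clin["event"] == 0].intersection(delta.index)
    if len(prog_ids) and len(nonprog_ids):
        for f in delta.columns:
            c = sv.mw_location_shift(
                delta.loc[prog_ids, f].to_numpy(), delta.loc[nonprog_ids, f].to_numpy()
            )
            report["delta_shifts"][f] = {
                "location_shift": c.effect, "ci": [c.ci_lower, c.ci_upper],
                "p_value": c.p_value,
            }
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the evaluation report (also on disk)."""
    cfg.persist()
    out = cfg.out_dir

    data_dir = cfg.data_dir
    if cfg.simulate_n_patients > 0:
        data_dir = stage_simulate(cfg)

    rep = validate_inputs(data_dir)
    for w in rep.warnings:
        logger.warning("input validation: %s", w)
    if not rep.ok:
        raise RuntimeError("input validation failed:\n" + "\n".join(rep.fatal))

    clinical = pd.read_csv(os.path.join(data_dir, "clinical.csv"))

    features = stage_extract(cfg, data_dir, rater=1)
    features.to_csv(os.path.join(out, "features_rater1.csv"), index=False)
    features_r2 = stage_extract(cfg, data_dir, rater=2)
    features_r2.to_csv(os.path.join(out, "features_rater2.csv"), index=False)

    harmonized, model = stage_harmonize(cfg, features, clinical)
    model.to_json(os.path.join(out, "harmonization_model.json"))
    harmonized.to_csv(os.path.join(out, "features_harmonized.csv"), index=False)

    if len(features_r2):
        robust = stage_robustness(cfg, features, features_r2)
    else:
        warnings.warn("no second-rater masks found; robustness gate skipped")
        robust = rb.RobustFeatureSet(retained=hz.feature_columns(features))
    with open(os.path.join(out, "robustness_report.json"), "w") as fh:
        json.dump(robust.report(), fh, indent=1, sort_keys=True)
    retained = robust.retained
    if not retained:
        raise RuntimeError("stage robustness: no feature passed the gate")

    pre_h, mid_h = _split_timepoints(harmonized)
    # Δ over the full catalog: the robustness gate restricts *fitting*, while
    # published signatures may reference features outside this cohort's gate
    delta = sg.compute_delta(pre_h, mid_h, hz.feature_columns(harmonized))
    delta.to_csv(os.path.join(out, "delta_features.csv"))

    sig_delta, sig_pre = stage_fit(cfg, delta[retained], pre_h, clinical, retained)
    sig_delta.to_json(os.path.join(out, "signature_delta.json"))
    sig_pre.to_json(os.path.join(out, "signature_pre.json"))

    scores = {
        sig_delta.name: sg.score(sig_delta, delta),
        sig_pre.name: sg.score(sig_pre, pre_h.set_index("patient_id")),
    }
    pd.DataFrame(scores).to_csv(os.path.join(out, "scores.csv"))

    # location shifts reported for the signature features (mirrors the
    # forest-plot analysis of Δfeatures in progressors vs non-progressors)
    sig_feats = sorted(set(sig_delta.coefficients) | set(sig_pre.coefficients))
    shift_cols = [f for f in sig_feats if f in delta.columns]
    report = stage_evaluate(cfg, scores, delta[shift_cols], clinical)
    report["retained_features"] = retained
    report["signatures"] = {
        sig_delta.name: {"lambda": sig_delta.lambda_,
                         "coefficients": sig_delta.coefficients},
        sig_pre.name: {"lambda": sig_pre.lambda_,
                       "coefficients": sig_pre.coefficients},
    }
    with open(os.path.join(out, "evaluation.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)

    lines = [f"deltarad run (seed {cfg.seed})",
             f"retained features: {len(retained)}"]
    for key, val in sorted(report["auc"].items()):
        if val.get("auc") is not None:
            lines.append(f"tdROC AUC @ {cfg.horizon_months:g} mo, {key}: {val['auc']:.3f}")
    with open(os.path.join(out, "summary.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return report
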