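"""Δfeature computation, LASSO-Cox signature fitting, and linear risk scoring.

A radiomic signature is a sparse linear combination of (harmonized)
features whose coefficients come from an L1-penalized Cox proportional-
hazards fit on the training cohort. The penalty strength λ is chosen by
leave-one-out cross-validated partial-likelihood deviance over a descending
log-spaced grid (100 values from λ_max down to 0.001·λ_max). Coefficients
are estimated on internally standardized features and reported on the input
scale.

The two published signatures (delta and pre-treatment) ship as package data
and can be loaded with :func:`load_published_signatures`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .radiomics import canonical_feature_name

__all__ = [
    "SurvivalRecord",
    "RadiomicSignature",
    "compute_delta",
    "breslow_partial_loglik",
    "fit_lasso_cox",
    "score",
    "load_published_signatures",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: time in months, progression indicator, cohort."""

    patient_id: str
    time: float
    event: int
    cohort: str = "training"

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"follow-up time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass
class RadiomicSignature:
    """Named sparse linear risk score: only nonzero coefficients are stored."""

    name: str
    coefficients: dict[str, float]
    lambda_: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = {
            canonical_feature_name(k): float(v)
            for k, v in self.coefficients.items()
            if v != 0.0
        }
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"name": self.name, "lambda": self.lambda_,
                 "coefficients": self.coefficients},
                fh, indent=1, sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "RadiomicSignature":
        with open(path) as fh:
            d = json.load(fh)
        return cls(name=d["name"], coefficients=d["coefficients"], lambda_=d["lambda"])


def compute_delta(pre: pd.DataFrame, mid: pd.DataFrame,
                  features: list[str] | None = None) -> pd.DataFrame:
    """Elementwise mid − pre feature table, inner-joined on patient_id.

    Patients present at only one timepoint are excluded with a warning.
    """
    a = pre.set_index("patient_id") if "patient_id" in pre else pre
    b = mid.set_index("patient_id") if "patient_id" in mid else mid
    feats = features if features is not None else [
        c for c in a.columns if c in b.columns and np.issubdtype(a[c].dtype, np.number)
    ]
    missing_a = [c for c in feats if c not in a.columns]
    missing_b = [c for c in feats if c not in b.columns]
    if missing_a or missing_b:
        raise KeyError(f"feature columns missing: pre={missing_a}, mid={missing_b}")
    common = a.index.intersection(b.index)
    dropped = sorted(set(a.index).symmetric_difference(b.index))
    if dropped:
        warnings.warn(
            f"{len(dropped)} patient(s) present at only one timepoint excluded "
            f"from Δ computation: {dropped[:10]}"
        )
    delta = b.loc[common, feats].astype(float) - a.loc[common, feats].astype(float)
    delta.index.name = "patient_id"
    return delta


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties) and LASSO path fitting
# ---------------------------------------------------------------------------


def breslow_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Breslow partial log-likelihood.

    ``lp`` may be (n,) or (n, m) for m coefficient vectors at once; returns a
    scalar or an (m,) vector.
    """
    lp = np.asarray(lp, dtype=float)
    squeeze = lp.ndim == 1
    if squeeze:
        lp = lp[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)

    order = np.argsort(-time, kind="stable")
    t_s = time[order]
    e_s = event[order]
    lp_s = lp[order]
    # stabilize exponentials
    shift = lp_s.max(axis=0, keepdims=True)
    exps = np.exp(lp_s - shift)
    cum = np.cumsum(exps, axis=0)
    # risk set of an event at time t includes every subject with time >= t,
    # ties included: use the last cumulative index among tied times
    last_tie = np.searchsorted(-t_s, -t_s, side="right") - 1
    log_risk = np.log(cum[last_tie]) + shift
    pll = (lp_s[e_s] - log_risk[e_s]).sum(axis=0)
    return pll[0] if squeeze else pll


def _coxnet_path(Xs: np.ndarray, time: np.ndarray, event: np.ndarray,
                 alphas: np.ndarray | None):
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(event=event.astype(bool), time=time)
    kwargs = dict(l1_ratio=1.0, fit_baseline_model=False, tol=1e-5, max_iter=100000)
    if alphas is None:
        model = CoxnetSurvivalAnalysis(n_alphas=100, alpha_min_ratio=0.001, **kwargs)
    else:
        model = CoxnetSurvivalAnalysis(alphas=list(alphas), **kwargs)
    model.fit(Xs, y)
    got_alphas = np.asarray(model.alphas_)
    coefs = np.asarray(model.coef_)  # (p, n_alphas)
    if alphas is not None and len(got_alphas) != len(alphas):
        # the solver may truncate the requested grid (non-convergence at the
        # small end); align by value, padding with the last fitted column
        req = np.asarray(alphas, dtype=float)
        out = np.empty((coefs.shape[0], len(req)))
        j = 0
        for k, a in enumerate(req):
            while j + 1 < len(got_alphas) and abs(got_alphas[j + 1] - a) <= abs(got_alphas[j] - a):
                j += 1
            out[:, k] = coefs[:, j]
        return req, out
    return got_alphas, coefs


def _unpenalized_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    from sksurv.linear_model import CoxPHSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(event=event.astype(bool), time=time)
    m = CoxPHSurvivalAnalysis(ties="breslow", n_iter=200, tol=1e-10)
    m.fit(X, y)
    return np.asarray(m.coef_)


def fit_lasso_cox(
    X: pd.DataFrame,
    surv: pd.DataFrame,
    lambda_grid: np.ndarray | None = None,
    cv: str | None = "loo",
    fixed_lambda: float | None = None,
    name: str = "signature",
) -> RadiomicSignature:
    """Fit an L1-penalized Cox model and assemble a radiomic signature.

    Parameters
    ----------
    X : patients x features matrix (training-cohort rows only), indexed or
        keyed by patient_id.
    surv : DataFrame with ``patient_id``, ``time_months`` and ``event``.
    lambda_grid : optional descending λ grid; default is the solver's
        100-value log-spaced path from λ_max to 0.001·λ_max.
    cv : ``"loo"`` for leave-one-out deviance selection, or None to take the
        smallest grid value.
    fixed_lambda : skip selection and fit at this λ (0 = unpenalized Cox).

    The cross-validated deviance uses the leave-out-difference construction,
    -2·[pll(full data) − pll(held-in data)] summed over left-out subjects,
    which is well defined for single-observation folds.
    """
    sv = surv.set_index("patient_id") if "patient_id" in surv else surv
    Xi = X.set_index("patient_id") if "patient_id" in X else X
    ids = Xi.index.intersection(sv.index)
    Xi = Xi.loc[ids]
    sv = sv.loc[ids]
    time = sv["time_months"].to_numpy(dtype=float)
    event = sv["event"].to_numpy(dtype=int)
    n, p = Xi.shape
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events in the training data; Cox model undefined")
    if n_events < 10:
        warnings.warn(f"only {n_events} events; LASSO-Cox selection may be unstable")

    feats = list(Xi.columns)
    Xmat = Xi.to_numpy(dtype=float)
    sd = Xmat.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature(s) before fitting")
        Xmat = Xmat[:, keep]
        feats = [f for f, k in zip(feats, keep) if k]
        sd = sd[keep]
    mean = Xmat.mean(axis=0)
    Xs = (Xmat - mean) / sd

    if fixed_lambda is not None and fixed_lambda == 0.0:
        beta_std = _unpenalized_cox(Xs, time, event)
        coef = beta_std / sd
        return RadiomicSignature(
            name=name, lambda_=0.0,
            coefficients=dict(zip(feats, coef)),
        )

    if fixed_lambda is not None:
        alphas, coefs = _coxnet_path(
            Xs, time, event,
            np.unique(np.concatenate([[fixed_lambda], np.geomspace(
                max(fixed_lambda * 100, 1e-3), fixed_lambda, 10)]))[::-1],
        )
        j = int(np.argmin(np.abs(alphas - fixed_lambda)))
        coef = coefs[:, j] / sd
        return RadiomicSignature(name=name, lambda_=float(fixed_lambda),
                                 coefficients=dict(zip(feats, coef)))

    alphas, coefs = _coxnet_path(Xs, time, event, lambda_grid)

    if cv == "loo":
        dev = np.zeros(len(alphas))
        for i in range(n):
            keep_i = np.ones(n, dtype=bool)
            keep_i[i] = False
            if event[keep_i].sum() == 0:
                continue
            try:
                _, coefs_i = _coxnet_path(Xs[keep_i], time[keep_i], event[keep_i], alphas)
            except Exception:  # pragma: no cover - solver failure on a fold
                continue
            lp_full = Xs @ coefs_i
            lp_train = Xs[keep_i] @ coefs_i
            pll_full = breslow_partial_loglik(lp_full, time, event)
            pll_train = breslow_partial_loglik(lp_train, time[keep_i], event[keep_i])
            dev += -2.0 * (pll_full - pll_train)
        best = int(np.argmin(dev))
    elif cv is None:
        best = len(alphas) - 1
    else:
        raise ValueError(f"unknown cv mode {cv!r}")

    coef = coefs[:, best] / sd
    return RadiomicSignature(
        name=name, lambda_=float(alphas[best]),
        coefficients=dict(zip(feats, coef)),
    )


def score(sig: RadiomicSignature, X: pd.DataFrame) -> pd.Series:
    """Linear risk score Σ coef_k · x_k per patient. No imputation: every
    signature feature must be present in ``X`` (aliases accepted)."""
    Xi = X.set_index("patient_id") if "patient_id" in X else X
    colmap = {canonical_feature_name(c): c for c in Xi.columns}
    missing = [f for f in sig.coefficients if f not in colmap]
    if missing:
        raise KeyError(f"signature {sig.name!r}: features missing from table: {missing}")
    s = pd.Series(0.0, index=Xi.index, name=sig.name)
    for f, c in sig.coefficients.items():
        s = s + c * Xi[colmap[f]].astype(float)
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError(f"non-finite score for signature {sig.name!r}")
    return s


def load_published_signatures() -> tuple[RadiomicSignature, RadiomicSignature]:
    """The two published signatures: (delta, pre-treatment).

    Delta_rad has six Δfeature terms at λ = 0.033; Pre-CCRT_rad has seven
    pre-treatment terms at λ = 0.019; they share three features (GLDM
    Dependence Variance, GLDM Gray Level Variance, GLSZM Size Zone
    Non-Uniformity Normalized).
    """
    pkg = resources.files("deltarad.data")
    with resources.as_file(pkg / "delta_rad.json") as p:
        delta = RadiomicSignature.from_json(p)
    with resources.as_file(pkg / "pre_ccrt_rad.json") as p:
        pre = RadiomicSignature.from_json(p)
    return delta, pre
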