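"""Time-dependent ROC evaluation and nonparametric comparison tests.

The discrimination of a prognostic score for event status by a horizon t is
measured with the cumulative-cases / dynamic-controls time-dependent AUC:
cases are subjects with an observed event by t, controls are subjects still
event-free beyond t, and censoring before t is handled by inverse-
probability-of-censoring weights (IPCW) from the Kaplan–Meier estimator of
the censoring distribution. Ties in scores contribute 1/2.

Also provided: a paired AUC-difference test (influence-function variance),
the Youden-index cutoff at a horizon, Kaplan–Meier / log-rank group
comparison (via lifelines), Mann–Whitney tests with Hodges–Lehmann location
shifts, paired Wilcoxon signed-rank, Spearman rank association, and exact
conditional tests for 2xk contingency tables.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "TdROCResult",
    "GroupComparison",
    "km_curve",
    "td_auc",
    "compare_auc",
    "youden_cutoff",
    "km_logrank",
    "mw_location_shift",
    "paired_wilcoxon",
    "spearman_assoc",
    "fisher_exact_2xk",
    "mw_cohort_compare",
]

DEFAULT_HORIZON = 60.0  # months; 5-year progression-free survival


@dataclass(frozen=True)
class TdROCResult:
    horizon: float
    auc: float
    se: float
    marker: str = ""
    n_cases: int = 0
    n_controls: int = 0


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    effect: float = np.nan
    ci_lower: float = np.nan
    ci_upper: float = np.nan
    note: str = ""


# ---------------------------------------------------------------------------
# Kaplan–Meier (product-limit) estimator
# ---------------------------------------------------------------------------


def km_curve(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate. Returns (event_times, S(t)) with S a
    right-continuous step function; use :func:`_km_eval` to evaluate."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    uniq = np.unique(t_s[e_s]) if e_s.any() else np.array([])
    n = len(t_s)
    surv = []
    s = 1.0
    for t in uniq:
        at_risk = np.sum(t_s >= t)
        d = np.sum((t_s == t) & e_s)
        s *= 1.0 - d / at_risk
        surv.append(s)
    return uniq, np.asarray(surv)


def _km_eval(times: np.ndarray, surv: np.ndarray, t, left: bool = False):
    """Evaluate a KM step function at t (right-continuous); ``left`` gives
    the left limit S(t-)."""
    t = np.asarray(t, dtype=float)
    if len(times) == 0:
        return np.ones_like(t)
    side = "left" if left else "right"
    idx = np.searchsorted(times, t, side=side) - 1
    return np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)


def _censoring_weights(time, event, horizon):
    """IPCW case weights 1/G(T_i-) and control weight 1/G(t) from the KM
    estimator of the censoring distribution G."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    ct, cs = km_curve(time, 1 - event)
    g_case = _km_eval(ct, cs, time, left=True)
    g_ctrl = float(_km_eval(ct, cs, np.asarray([horizon]))[0])
    return g_case, g_ctrl


def _case_control(time, event, horizon):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    return cases, controls


def _auc_and_influence(scores, time, event, horizon):
    scores = np.asarray(scores, dtype=float)
    cases, controls = _case_control(time, event, horizon)
    n_case, n_ctrl = int(cases.sum()), int(controls.sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError(
            f"no {'cases' if n_case == 0 else 'controls'} at horizon {horizon}"
        )
    g_case, _ = _censoring_weights(time, event, horizon)
    w = np.zeros(len(scores))
    gc = g_case[cases]
    if np.any(gc <= 0):
        raise ValueError("zero censoring-survival weight; horizon beyond support")
    w[cases] = 1.0 / gc

    sc = scores[cases]
    st = scores[controls]
    wc = w[cases]
    h = (sc[:, None] > st[None, :]).astype(float) + 0.5 * (sc[:, None] == st[None, :])
    sw = wc.sum()
    theta = float((wc[:, None] * h).sum() / (sw * n_ctrl))

    # influence function with weights treated as fixed
    psi = np.zeros(len(scores))
    h_case = h.mean(axis=1)
    psi[cases] = wc * (h_case - theta) / sw
    g_ctrl_term = (wc[:, None] * h).sum(axis=0) / sw
    psi[controls] = (g_ctrl_term - theta) / n_ctrl
    se = float(np.sqrt((psi ** 2).sum()))
    return theta, se, psi, n_case, n_ctrl


def td_auc(scores, time, event, horizon: float = DEFAULT_HORIZON,
           marker: str = "") -> TdROCResult:
    """Cumulative/dynamic time-dependent AUC with KM-based IPCW at a horizon."""
    auc, se, _, n_case, n_ctrl = _auc_and_influence(scores, time, event, horizon)
    return TdROCResult(horizon=horizon, auc=auc, se=se, marker=marker,
                       n_cases=n_case, n_controls=n_ctrl)


def compare_auc(scores_a, scores_b, time, event,
                horizon: float = DEFAULT_HORIZON) -> GroupComparison:
    """Paired test of equal time-dependent AUCs for two markers on the same
    subjects, using the influence-function variance of the AUC difference."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired markers must cover the same subjects")
    auc_a, _, psi_a, _, _ = _auc_and_influence(scores_a, time, event, horizon)
    auc_b, _, psi_b, _, _ = _auc_and_influence(scores_b, time, event, horizon)
    d = auc_a - auc_b
    var = float(((psi_a - psi_b) ** 2).sum())
    if var == 0:
        return GroupComparison(statistic=0.0, p_value=1.0, effect=d,
                               note="identical influence curves")
    z = d / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    half = stats.norm.ppf(0.975) * np.sqrt(var)
    return GroupComparison(statistic=float(z), p_value=float(p), effect=float(d),
                           ci_lower=float(d - half), ci_upper=float(d + half))


def youden_cutoff(scores, time, event, horizon: float = DEFAULT_HORIZON) -> float:
    """Cutoff maximizing sensitivity(t) + specificity(t) − 1 at the horizon.

    Sensitivity uses IPCW case weights; candidates are midpoints between
    consecutive distinct observed scores; ties in the Youden index break
    toward the lower cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        raise ValueError("constant marker: Youden cutoff undefined")
    cases, controls = _case_control(time, event, horizon)
    if not cases.any() or not controls.any():
        raise ValueError(f"no cases or controls at horizon {horizon}")
    g_case, _ = _censoring_weights(time, event, horizon)
    wc = 1.0 / g_case[cases]
    sc = scores[cases]
    st = scores[controls]
    uniq = np.unique(scores)
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    best_j, best_c = -np.inf, cands[0]
    for c in cands:
        se = wc[sc > c].sum() / wc.sum()
        sp = np.mean(st <= c)
        j = se + sp - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


# ---------------------------------------------------------------------------
# Kaplan–Meier group comparison
# ---------------------------------------------------------------------------


def km_logrank(groups, time, event) -> tuple[GroupComparison, dict]:
    """Two-sample log-rank test plus per-group product-limit curves."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(labels)}")
    m0 = groups == labels[0]
    m1 = groups == labels[1]
    if not m0.any() or not m1.any():
        raise ValueError("one group is empty")
    curves = {}
    for lab, m in ((labels[0], m0), (labels[1], m1)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(lab))
        sf = kmf.survival_function_
        curves[str(lab)] = {
            "times": sf.index.to_numpy().tolist(),
            "survival": sf.iloc[:, 0].to_numpy().tolist(),
        }
    if np.array_equal(np.sort(time[m0]), np.sort(time[m1])) and np.array_equal(
        np.sort(event[m0]), np.sort(event[m1])
    ):
        # identical samples: statistic 0 by construction
        return GroupComparison(statistic=0.0, p_value=1.0, note="identical groups"), curves
    res = logrank_test(time[m0], time[m1], event_observed_A=event[m0],
                       event_observed_B=event[m1])
    return (
        GroupComparison(statistic=float(res.test_statistic), p_value=float(res.p_value)),
        curves,
    )


# ---------------------------------------------------------------------------
# Nonparametric comparisons
# ---------------------------------------------------------------------------


def mw_location_shift(x, y, alpha: float = 0.05) -> GroupComparison:
    """Mann–Whitney U test with the Hodges–Lehmann location-shift estimate.

    The effect is median{x_i − y_j} with the distribution-free confidence
    interval from the ordered pairwise differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    hl = float(np.median(diffs))
    m, n = len(x), len(y)
    if m >= 2 and n >= 2:
        u = stats.mannwhitneyu(x, y, alternative="two-sided")
        stat, p = float(u.statistic), float(u.pvalue)
    else:
        stat, p = np.nan, np.nan
    z = stats.norm.ppf(1 - alpha / 2)
    k = int(np.floor(m * n / 2.0 - z * np.sqrt(m * n * (m + n + 1) / 12.0)))
    k = max(k, 1)
    lo = float(diffs[k - 1])
    hi = float(diffs[m * n - k])
    return GroupComparison(statistic=stat, p_value=p, effect=hl,
                           ci_lower=lo, ci_upper=hi)


def paired_wilcoxon(pre, mid) -> GroupComparison:
    """Wilcoxon signed-rank test of mid − pre on paired vectors.

    Zero differences are dropped; the exact (tie-aware) null is used for
    <= 25 nonzero pairs, a tie-corrected normal approximation otherwise.
    All-zero differences return p = 1 flagged degenerate.
    """
    pre = np.asarray(pre, dtype=float)
    mid = np.asarray(mid, dtype=float)
    if pre.shape != mid.shape:
        raise ValueError("paired vectors must have equal length")
    d = mid - pre
    nz = d[d != 0]
    if nz.size == 0:
        return GroupComparison(statistic=0.0, p_value=1.0,
                               note="all paired differences are zero")
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(mid, pre, zero_method="wilcox", method=method)
    return GroupComparison(statistic=float(res.statistic), p_value=float(res.pvalue),
                           effect=float(np.median(nz)))


def spearman_assoc(x, y) -> GroupComparison:
    """Spearman rank correlation with average-rank ties; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return GroupComparison(statistic=np.nan, p_value=np.nan,
                               note="constant vector: correlation undefined")
    r, p = stats.spearmanr(x, y)
    return GroupComparison(statistic=float(r), p_value=float(p), effect=float(r))


def _exact_2xk(table: np.ndarray) -> float:
    """Exact conditional p for a 2xk table: sum of probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's (multivariate hypergeometric null)."""
    table = np.asarray(table, dtype=int)
    row1 = int(table[0].sum())
    cols = table.sum(axis=0)
    total = int(cols.sum())

    def log_prob(xs):
        lp = -(gammaln(total + 1) - gammaln(row1 + 1) - gammaln(total - row1 + 1))
        for x, cj in zip(xs, cols):
            lp += gammaln(cj + 1) - gammaln(x + 1) - gammaln(cj - x + 1)
        return lp

    obs = log_prob(table[0])
    p = 0.0
    ranges = [range(0, int(c) + 1) for c in cols[:-1]]
    for xs in itertools.product(*ranges):
        rest = row1 - sum(xs)
        if 0 <= rest <= cols[-1]:
            lp = log_prob(list(xs) + [rest])
            if lp <= obs + 1e-9:
                p += np.exp(lp)
    return float(min(p, 1.0))


def fisher_exact_2xk(table) -> GroupComparison:
    """Exact conditional test for a 2xk contingency table (Fisher for 2x2)."""
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2xk table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("empty margin in contingency table")
    if table.shape[1] == 2:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return GroupComparison(statistic=float(odds), p_value=float(p))
    p = _exact_2xk(table)
    return GroupComparison(statistic=np.nan, p_value=p)


def mw_cohort_compare(x, y) -> GroupComparison:
    """Mann–Whitney comparison of a continuous characteristic between cohorts."""
    return mw_location_shift(x, y)
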