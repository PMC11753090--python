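"""Time-dependent ROC, cutoffs, KM/log-rank, and nonparametric tests."""

import numpy as np
import pytest
from scipy import stats

from deltarad import (
    compare_auc,
    fisher_exact_2xk,
    km_logrank,
    mw_location_shift,
    paired_wilcoxon,
    spearman_assoc,
    td_auc,
    youden_cutoff,
)
from deltarad.survival import km_curve


def _ipcw_auc_oracle(scores, time, event, horizon):
    """Independent IPCW double-sum: censoring KM computed step by step."""
    n = len(scores)
    # Kaplan-Meier of the censoring distribution
    order = np.argsort(time)
    t_s = np.asarray(time, float)[order]
    c_s = 1 - np.asarray(event, int)[order]

    def G(t, left=False):
        s = 1.0
        for ti in np.unique(t_s):
            if (ti < t) or (not left and ti == t):
                at_risk = np.sum(t_s >= ti)
                d = np.sum((t_s == ti) & (c_s == 1))
                s *= 1 - d / at_risk
        return s

    num = den_w = 0.0
    cases = [i for i in range(n) if time[i] <= horizon and event[i] == 1]
    ctrls = [i for i in range(n) if time[i] > horizon]
    for i in cases:
        w = 1.0 / G(time[i], left=True)
        den_w += w
        for j in ctrls:
            if scores[i] > scores[j]:
                num += w
            elif scores[i] == scores[j]:
                num += 0.5 * w
    return num / (den_w * len(ctrls))


class TestTdAUC:
    def test_perfect_ordering_uncensored(self):
        time = np.array([10, 20, 30, 80, 90, 100], float)
        event = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([6, 5, 4, 1, 2, 3], float)
        r = td_auc(scores, time, event, horizon=60)
        assert r.auc == pytest.approx(1.0)

    def test_constant_score_is_half(self):
        time = np.array([10, 20, 70, 90], float)
        event = np.array([1, 1, 0, 0])
        r = td_auc(np.ones(4), time, event, horizon=60)
        assert r.auc == pytest.approx(0.5)

    def test_matches_ipcw_double_sum_oracle(self, rng):
        """12-subject instance with censoring: exact agreement with a
        step-by-step hand computation of the weighted double sum."""
        time = np.array([5, 12, 18, 25, 33, 41, 47, 55, 64, 72, 80, 95], float)
        event = np.array([1, 0, 1, 1, 0, 1, 0, 1, 0, 0, 1, 0])
        scores = rng.standard_normal(12)
        r = td_auc(scores, time, event, horizon=60)
        assert r.auc == pytest.approx(
            _ipcw_auc_oracle(scores, time, event, 60), abs=1e-12)

    def test_reduces_to_binary_auc_without_censoring(self, rng):
        from sklearn.metrics import roc_auc_score

        n = 80
        time = rng.uniform(1, 120, n)
        event = np.ones(n, int)
        scores = rng.standard_normal(n)
        label = (time <= 60).astype(int)
        r = td_auc(scores, time, event, horizon=60)
        assert r.auc == pytest.approx(roc_auc_score(label, scores))

    def test_agrees_with_sksurv_cross_check(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        n = 120
        scores = rng.standard_normal(n)
        time = rng.exponential(60, n) * np.exp(-0.5 * scores)
        cens = rng.uniform(0, 150, n)
        obs = np.minimum(time, cens)
        event = (time <= cens).astype(int)
        r = td_auc(scores, obs, event, horizon=40)
        y = Surv.from_arrays(event=event.astype(bool), time=obs)
        ref, _ = cumulative_dynamic_auc(y, y, scores, [40])
        assert r.auc == pytest.approx(float(ref[0]), abs=1e-6)

    def test_invariant_under_monotone_transform(self, rng):
        n = 60
        time = rng.uniform(1, 120, n)
        event = rng.integers(0, 2, n)
        if not ((time <= 60) & (event == 1)).any():
            event[np.argmin(time)] = 1
        scores = rng.standard_normal(n)
        a = td_auc(scores, time, event, 60).auc
        b = td_auc(np.exp(3 * scores), time, event, 60).auc
        assert a == pytest.approx(b)

    def test_no_controls_raises(self):
        with pytest.raises(ValueError, match="controls"):
            td_auc([1.0, 2.0], [10, 20], [1, 1], horizon=60)


class TestCompareAUC:
    def test_marker_against_itself(self, rng):
        n = 60
        time = rng.uniform(1, 120, n)
        event = np.ones(n, int)
        s = rng.standard_normal(n)
        c = compare_auc(s, s, time, event, 60)
        assert c.effect == 0.0
        assert c.p_value == 1.0

    def test_power_against_pure_noise_marker(self):
        """Informative vs noise marker at n = 300 uncensored: rejects at the
        5% level in >= 80% of seeded replicates."""
        rejections = 0
        reps = 25
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            n = 300
            good = rng.standard_normal(n)
            time = np.exp(-good) * rng.exponential(60, n)
            event = np.ones(n, int)
            noise = rng.standard_normal(n)
            horizon = float(np.median(time))
            c = compare_auc(good, noise, time, event, horizon)
            rejections += c.p_value < 0.05
        assert rejections >= 0.8 * reps

    def test_type_i_error_for_correlated_equal_markers(self):
        """Two highly correlated markers with equal true AUC: empirical
        type-I error within 3 points of the 5% level over 500 replicates."""
        rejections = 0
        reps = 500
        for rep in range(reps):
            rng = np.random.default_rng(10_000 + rep)
            n = 150
            base = rng.standard_normal(n)
            a = base + 0.3 * rng.standard_normal(n)
            b = base + 0.3 * rng.standard_normal(n)
            time = np.exp(-base) * rng.exponential(40, n)
            event = np.ones(n, int)
            c = compare_auc(a, b, time, event, float(np.median(time)))
            rejections += c.p_value < 0.05
        assert abs(rejections / reps - 0.05) <= 0.03


class TestYouden:
    def test_perfect_separation_cutoff_in_gap(self):
        time = np.array([10, 20, 30, 80, 90, 100], float)
        event = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([5.0, 6.0, 7.0, 1.0, 2.0, 3.0])
        cut = youden_cutoff(scores, time, event, 60)
        assert 3.0 < cut < 5.0

    def test_matches_exhaustive_midpoint_search(self, rng):
        time = np.array([8, 15, 22, 30, 45, 55, 70, 80, 90, 110], float)
        event = np.array([1, 1, 0, 1, 0, 1, 0, 0, 1, 0])
        scores = rng.standard_normal(10)
        cut = youden_cutoff(scores, time, event, 60)

        # exhaustive oracle over all midpoints using the same IPCW weights
        best = (-np.inf, None)
        uniq = np.unique(scores)
        for c in (uniq[:-1] + uniq[1:]) / 2:
            auc_like = 0.0
            cases = (time <= 60) & (event == 1)
            ctrl = time > 60
            w = np.array([1.0 / _g_left(time, event, t) for t in time])
            se = w[cases & (scores > c)].sum() / w[cases].sum()
            sp = np.mean(scores[ctrl] <= c)
            j = se + sp - 1
            if j > best[0] + 1e-12:
                best = (j, c)
        assert cut == pytest.approx(best[1])

    def test_shift_equivariance(self, rng):
        time = rng.uniform(1, 120, 40)
        event = rng.integers(0, 2, 40)
        event[np.argmin(time)] = 1
        if not (time > 60).any():
            time[0] = 100
        scores = rng.standard_normal(40)
        c0 = youden_cutoff(scores, time, event, 60)
        c1 = youden_cutoff(scores + 4.2, time, event, 60)
        assert c1 == pytest.approx(c0 + 4.2)

    def test_constant_marker_raises(self):
        with pytest.raises(ValueError, match="constant"):
            youden_cutoff(np.ones(6), np.arange(1.0, 7), np.ones(6, int), 3)


def _g_left(time, event, t):
    ts, ss = km_curve(np.asarray(time, float), 1 - np.asarray(event, int))
    s = 1.0
    for ti, si in zip(ts, ss):
        if ti < t:
            s = si
    return s


class TestKMLogrank:
    def test_identical_groups_p_one(self):
        time = np.array([5, 10, 15, 5, 10, 15], float)
        event = np.array([1, 1, 0, 1, 1, 0])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        cmp_, curves = km_logrank(groups, time, event)
        assert cmp_.statistic == 0.0
        assert cmp_.p_value == 1.0
        assert set(curves) == {"a", "b"}

    def test_matches_hand_computed_logrank_table(self):
        """10-subject instance: observed-expected and variance accumulated
        event time by event time by hand."""
        time = np.array([3, 5, 7, 9, 11, 4, 6, 8, 10, 12], float)
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0])
        groups = np.array(["a"] * 5 + ["b"] * 5)

        o_minus_e = 0.0
        var = 0.0
        for t in sorted(time[event == 1]):
            at_risk = time >= t
            n1 = int((at_risk & (groups == "a")).sum())
            n = int(at_risk.sum())
            d = int(((time == t) & (event == 1)).sum())
            d1 = int(((time == t) & (event == 1) & (groups == "a")).sum())
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e ** 2 / var

        cmp_, _ = km_logrank(groups, time, event)
        assert cmp_.statistic == pytest.approx(expected_chi2, rel=1e-9)
        assert cmp_.p_value == pytest.approx(stats.chi2.sf(expected_chi2, 1), rel=1e-9)

    def test_km_curve_equals_empirical_survival_without_censoring(self, rng):
        t = rng.uniform(1, 50, 30)
        times, surv = km_curve(t, np.ones(30, int))
        for ti, si in zip(times, surv):
            assert si == pytest.approx((t > ti).mean())

    def test_power_under_hazard_ratio_three(self):
        """Hazard ratio 3 at n = 200: log-rank p < 0.001 in >= 95% of
        replicates."""
        hits = 0
        reps = 40
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            t0 = rng.exponential(60, 100)
            t1 = rng.exponential(20, 100)
            time = np.concatenate([t0, t1])
            event = np.ones(200, int)
            groups = np.array(["lo"] * 100 + ["hi"] * 100)
            cmp_, _ = km_logrank(groups, time, event)
            hits += cmp_.p_value < 0.001
        assert hits >= 0.95 * reps

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            km_logrank(np.array(["a", "a"]), np.array([1.0, 2.0]), np.array([1, 1]))


class TestMannWhitneyHL:
    def test_identical_samples_zero_shift(self):
        x = np.array([3.0, 1.0, 2.0])
        c = mw_location_shift(x, x)
        assert c.effect == 0.0

    def test_hodges_lehmann_enumeration(self):
        c = mw_location_shift(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))
        # all 9 pairwise differences: median is -1
        assert c.effect == pytest.approx(-1.0)
        assert c.ci_lower <= -1.0 <= c.ci_upper

    def test_shift_consistency_simulation(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100) + 1.0
        c = mw_location_shift(x, y)
        assert c.effect == pytest.approx(-1.0, abs=0.3)

    def test_label_swap_flips_effect(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30) + 0.5
        a = mw_location_shift(x, y)
        b = mw_location_shift(y, x)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.effect == pytest.approx(-b.effect)


class TestWilcoxon:
    def test_all_zero_differences_flagged(self):
        pre = np.arange(1.0, 6.0)
        c = paired_wilcoxon(pre, pre.copy())
        assert c.p_value == 1.0
        assert "zero" in c.note

    def test_uniform_shift_exact_p(self):
        pre = np.arange(10, dtype=float)
        c = paired_wilcoxon(pre, pre + 1.0)
        assert c.p_value == pytest.approx(2.0 / 1024.0)

    def test_null_calibration(self):
        """Exchangeable null, n = 50: empirical type-I error near 5% over
        1000 replicates."""
        rej = 0
        reps = 1000
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            pre = rng.standard_normal(50)
            mid = pre + rng.standard_normal(50)
            rej += paired_wilcoxon(pre, mid).p_value < 0.05
        assert abs(rej / reps - 0.05) < 0.02


class TestSpearman:
    def test_strictly_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_assoc(x, np.exp(x)).statistic == pytest.approx(1.0)
        assert spearman_assoc(x, -x).statistic == pytest.approx(-1.0)

    def test_ties_equal_pearson_on_average_ranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        y = np.array([2.0, 3.0, 3.0, 5.0, 4.0, 4.0])
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_assoc(x, y).statistic == pytest.approx(expected)

    def test_constant_vector_flagged(self):
        c = spearman_assoc(np.ones(5), np.arange(5.0))
        assert np.isnan(c.statistic)
        assert "constant" in c.note


class TestFisherExact:
    def test_balanced_2x2_p_one(self):
        c = fisher_exact_2xk([[10, 10], [10, 10]])
        assert c.p_value == pytest.approx(1.0)

    def test_2x2_matches_hypergeometric_enumeration(self):
        table = np.array([[8, 2], [1, 9]])
        c = fisher_exact_2xk(table)
        # enumerate the conditional distribution of the top-left cell
        n1, n2 = table.sum(axis=1)
        k = table.sum(axis=0)[0]
        pmf = {a: stats.hypergeom.pmf(a, n1 + n2, n1, k)
               for a in range(max(0, k - n2), min(n1, k) + 1)}
        p_obs = pmf[8]
        expected = sum(v for v in pmf.values() if v <= p_obs + 1e-12)
        assert c.p_value == pytest.approx(expected, rel=1e-6)

    def test_balanced_2x3_p_one(self):
        c = fisher_exact_2xk([[5, 5, 5], [5, 5, 5]])
        assert c.p_value == pytest.approx(1.0)

    def test_2x3_p_in_unit_interval_and_small_under_association(self):
        c = fisher_exact_2xk([[9, 1, 0], [0, 1, 9]])
        assert 0.0 <= c.p_value <= 1.0
        assert c.p_value < 0.01

    def test_empty_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2xk([[0, 0], [3, 4]])
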