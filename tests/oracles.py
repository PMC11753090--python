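"""Independent brute-force oracles for the texture features.

Everything here enumerates voxels, pairs, runs, zones and neighbourhoods
with explicit Python loops and evaluates the feature formulas naively from
the resulting count matrices. No code is shared with the package's
vectorized implementation.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]
OFFSETS_26 = OFFSETS_13 + [tuple(-o for o in off) for off in OFFSETS_13]


def _inside(pos, shape):
    return all(0 <= p < s for p, s in zip(pos, shape))


def _log2(x):
    return math.log2(x) if x > 0 else 0.0


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def _glcm_feats(P):
    ng = P.shape[0]
    px = [sum(P[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sig2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))

    p_sum = {}
    p_diff = {}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + P[i][j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + P[i][j]
    da = sum(k * v for k, v in p_diff.items())

    hx = -sum(p * _log2(p) for p in px if p > 0)
    hxy = -sum(P[i][j] * _log2(P[i][j]) for i in range(ng) for j in range(ng) if P[i][j] > 0)
    hxy1 = -sum(P[i][j] * _log2(px[i] * px[j]) for i in range(ng) for j in range(ng)
                if P[i][j] > 0 and px[i] * px[j] > 0)
    hxy2 = -sum(px[i] * px[j] * _log2(px[i] * px[j]) for i in range(ng) for j in range(ng)
                if px[i] * px[j] > 0)

    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    if sig2 > 0:
        corr = (sum((i + 1) * (j + 1) * P[i][j] for i in range(ng) for j in range(ng))
                - mu * mu) / sig2
    else:
        corr = 1.0

    present = [i for i in range(ng) if px[i] > 0]
    if len(present) <= 1:
        mcc = 1.0
    else:
        m = len(present)
        Q = np.zeros((m, m))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                Q[a, b] = sum(
                    P[i][k] * P[j][k] / (px[i] * px[k])
                    for k in present
                )
        eig = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        mcc = math.sqrt(max(0.0, eig[1]))

    out = {
        "Autocorrelation": sum((i + 1) * (j + 1) * P[i][j] for i in range(ng) for j in range(ng)),
        "Joint Average": mu,
        "Cluster Prominence": sum((i + j + 2 - 2 * mu) ** 4 * P[i][j] for i in range(ng) for j in range(ng)),
        "Cluster Shade": sum((i + j + 2 - 2 * mu) ** 3 * P[i][j] for i in range(ng) for j in range(ng)),
        "Cluster Tendency": sum((i + j + 2 - 2 * mu) ** 2 * P[i][j] for i in range(ng) for j in range(ng)),
        "Contrast": sum((i - j) ** 2 * P[i][j] for i in range(ng) for j in range(ng)),
        "Correlation": corr,
        "Difference Average": da,
        "Difference Entropy": -sum(v * _log2(v) for v in p_diff.values() if v > 0),
        "Difference Variance": sum((k - da) ** 2 * v for k, v in p_diff.items()),
        "Joint Energy": sum(P[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "Joint Entropy": hxy,
        "Informational Measure of Correlation 1": imc1,
        "Informational Measure of Correlation 2": imc2,
        "Inverse Difference Moment": sum(P[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)),
        "Inverse Difference Moment Normalized": sum(P[i][j] / (1 + (i - j) ** 2 / ng ** 2) for i in range(ng) for j in range(ng)),
        "Inverse Difference": sum(P[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)),
        "Inverse Difference Normalized": sum(P[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)),
        "Inverse Variance": sum(P[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j),
        "Maximum Probability": max(P[i][j] for i in range(ng) for j in range(ng)),
        "Maximal Correlation Coefficient": mcc,
        "Sum Average": sum(k * v for k, v in p_sum.items()),
        "Sum Entropy": -sum(v * _log2(v) for v in p_sum.values() if v > 0),
        "Sum of Squares": sig2,
    }
    return out


def oracle_glcm(levels):
    shape = levels.shape
    ng = int(levels.max())
    per_dir = []
    for off in OFFSETS_13:
        P = np.zeros((ng, ng))
        for x in np.ndindex(shape):
            a = levels[x]
            if a == 0:
                continue
            y = tuple(xi + oi for xi, oi in zip(x, off))
            if _inside(y, shape) and levels[y] > 0:
                b = levels[y]
                P[a - 1][b - 1] += 1
                P[b - 1][a - 1] += 1
        tot = P.sum()
        if tot == 0:
            continue
        per_dir.append(_glcm_feats(P / tot))
    if not per_dir:
        out = {k: 0.0 for k in _glcm_feats(np.ones((1, 1)))}
        out["Correlation"] = 1.0
        out["Maximal Correlation Coefficient"] = 1.0
        return out
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------


def oracle_gldm(levels, alpha=0):
    shape = levels.shape
    ng = int(levels.max())
    counts = {}
    for x in np.ndindex(shape):
        a = levels[x]
        if a == 0:
            continue
        dep = 0
        for off in OFFSETS_26:
            y = tuple(xi + oi for xi, oi in zip(x, off))
            if _inside(y, shape) and levels[y] > 0 and abs(int(levels[y]) - int(a)) <= alpha:
                dep += 1
        counts[(int(a), dep)] = counts.get((int(a), dep), 0) + 1

    nz = sum(counts.values())
    # dependence size = neighbour count + 1 in the formulas
    sde = sum(c / (d + 1) ** 2 for (i, d), c in counts.items()) / nz
    lde = sum(c * (d + 1) ** 2 for (i, d), c in counts.items()) / nz
    pg = {}
    pd_ = {}
    for (i, d), c in counts.items():
        pg[i] = pg.get(i, 0) + c
        pd_[d] = pd_.get(d, 0) + c
    gln = sum(v ** 2 for v in pg.values()) / nz
    dn = sum(v ** 2 for v in pd_.values()) / nz
    mu_i = sum(i * c for (i, d), c in counts.items()) / nz
    mu_j = sum((d + 1) * c for (i, d), c in counts.items()) / nz
    glv = sum(c * (i - mu_i) ** 2 for (i, d), c in counts.items()) / nz
    dv = sum(c * (d + 1 - mu_j) ** 2 for (i, d), c in counts.items()) / nz
    de = -sum((c / nz) * _log2(c / nz) for c in counts.values())
    return {
        "Small Dependence Emphasis": sde,
        "Large Dependence Emphasis": lde,
        "Gray Level Non-Uniformity": gln,
        "Dependence Non-Uniformity": dn,
        "Dependence Non-Uniformity Normalized": dn / nz,
        "Gray Level Variance": glv,
        "Dependence Variance": dv,
        "Dependence Entropy": de,
        "Low Gray Level Emphasis": sum(c / i ** 2 for (i, d), c in counts.items()) / nz,
        "High Gray Level Emphasis": sum(c * i ** 2 for (i, d), c in counts.items()) / nz,
        "Small Dependence Low Gray Level Emphasis": sum(c / (i ** 2 * (d + 1) ** 2) for (i, d), c in counts.items()) / nz,
        "Small Dependence High Gray Level Emphasis": sum(c * i ** 2 / (d + 1) ** 2 for (i, d), c in counts.items()) / nz,
        "Large Dependence Low Gray Level Emphasis": sum(c * (d + 1) ** 2 / i ** 2 for (i, d), c in counts.items()) / nz,
        "Large Dependence High Gray Level Emphasis": sum(c * i ** 2 * (d + 1) ** 2 for (i, d), c in counts.items()) / nz,
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def _rl_feats(counts, n_vox):
    nr = sum(counts.values())
    pg = {}
    pr = {}
    for (i, r), c in counts.items():
        pg[i] = pg.get(i, 0) + c
        pr[r] = pr.get(r, 0) + c
    mu_i = sum(i * c for (i, r), c in counts.items()) / nr
    mu_r = sum(r * c for (i, r), c in counts.items()) / nr
    return {
        "Short Run Emphasis": sum(c / r ** 2 for (i, r), c in counts.items()) / nr,
        "Long Run Emphasis": sum(c * r ** 2 for (i, r), c in counts.items()) / nr,
        "Gray Level Non-Uniformity": sum(v ** 2 for v in pg.values()) / nr,
        "Gray Level Non-Uniformity Normalized": sum(v ** 2 for v in pg.values()) / nr ** 2,
        "Run Length Non-Uniformity": sum(v ** 2 for v in pr.values()) / nr,
        "Run Length Non-Uniformity Normalized": sum(v ** 2 for v in pr.values()) / nr ** 2,
        "Run Percentage": nr / n_vox,
        "Gray Level Variance": sum(c * (i - mu_i) ** 2 for (i, r), c in counts.items()) / nr,
        "Run Variance": sum(c * (r - mu_r) ** 2 for (i, r), c in counts.items()) / nr,
        "Run Entropy": -sum((c / nr) * _log2(c / nr) for c in counts.values()),
        "Low Gray Level Run Emphasis": sum(c / i ** 2 for (i, r), c in counts.items()) / nr,
        "High Gray Level Run Emphasis": sum(c * i ** 2 for (i, r), c in counts.items()) / nr,
        "Short Run Low Gray Level Emphasis": sum(c / (i ** 2 * r ** 2) for (i, r), c in counts.items()) / nr,
        "Short Run High Gray Level Emphasis": sum(c * i ** 2 / r ** 2 for (i, r), c in counts.items()) / nr,
        "Long Run Low Gray Level Emphasis": sum(c * r ** 2 / i ** 2 for (i, r), c in counts.items()) / nr,
        "Long Run High Gray Level Emphasis": sum(c * i ** 2 * r ** 2 for (i, r), c in counts.items()) / nr,
    }


def oracle_glrlm(levels):
    shape = levels.shape
    n_vox = int((levels > 0).sum())
    per_dir = []
    for off in OFFSETS_13:
        counts = {}
        for x in np.ndindex(shape):
            a = levels[x]
            if a == 0:
                continue
            prev = tuple(xi - oi for xi, oi in zip(x, off))
            if _inside(prev, shape) and levels[prev] == a:
                continue  # not a run start
            length = 1
            cur = x
            while True:
                nxt = tuple(ci + oi for ci, oi in zip(cur, off))
                if _inside(nxt, shape) and levels[nxt] == a:
                    length += 1
                    cur = nxt
                else:
                    break
            counts[(int(a), length)] = counts.get((int(a), length), 0) + 1
        if counts:
            per_dir.append(_rl_feats(counts, n_vox))
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM (flood-fill zones)
# ---------------------------------------------------------------------------


def oracle_glszm(levels):
    shape = levels.shape
    n_vox = int((levels > 0).sum())
    seen = np.zeros(shape, dtype=bool)
    counts = {}
    for x in np.ndindex(shape):
        if levels[x] == 0 or seen[x]:
            continue
        g = int(levels[x])
        stack = [x]
        seen[x] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in OFFSETS_26:
                y = tuple(ci + oi for ci, oi in zip(cur, off))
                if _inside(y, shape) and not seen[y] and levels[y] == g:
                    seen[y] = True
                    stack.append(y)
        counts[(g, size)] = counts.get((g, size), 0) + 1

    nz = sum(counts.values())
    pg = {}
    ps = {}
    for (i, s), c in counts.items():
        pg[i] = pg.get(i, 0) + c
        ps[s] = ps.get(s, 0) + c
    mu_i = sum(i * c for (i, s), c in counts.items()) / nz
    mu_s = sum(s * c for (i, s), c in counts.items()) / nz
    return {
        "Small Area Emphasis": sum(c / s ** 2 for (i, s), c in counts.items()) / nz,
        "Large Area Emphasis": sum(c * s ** 2 for (i, s), c in counts.items()) / nz,
        "Gray Level Non-Uniformity": sum(v ** 2 for v in pg.values()) / nz,
        "Gray Level Non-Uniformity Normalized": sum(v ** 2 for v in pg.values()) / nz ** 2,
        "Size Zone Non-Uniformity": sum(v ** 2 for v in ps.values()) / nz,
        "Size Zone Non-Uniformity Normalized": sum(v ** 2 for v in ps.values()) / nz ** 2,
        "Zone Percentage": nz / n_vox,
        "Gray Level Variance": sum(c * (i - mu_i) ** 2 for (i, s), c in counts.items()) / nz,
        "Zone Variance": sum(c * (s - mu_s) ** 2 for (i, s), c in counts.items()) / nz,
        "Zone Entropy": -sum((c / nz) * _log2(c / nz) for c in counts.values()),
        "Low Gray Level Zone Emphasis": sum(c / i ** 2 for (i, s), c in counts.items()) / nz,
        "High Gray Level Zone Emphasis": sum(c * i ** 2 for (i, s), c in counts.items()) / nz,
        "Small Area Low Gray Level Emphasis": sum(c / (i ** 2 * s ** 2) for (i, s), c in counts.items()) / nz,
        "Small Area High Gray Level Emphasis": sum(c * i ** 2 / s ** 2 for (i, s), c in counts.items()) / nz,
        "Large Area Low Gray Level Emphasis": sum(c * s ** 2 / i ** 2 for (i, s), c in counts.items()) / nz,
        "Large Area High Gray Level Emphasis": sum(c * i ** 2 * s ** 2 for (i, s), c in counts.items()) / nz,
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def oracle_ngtdm(levels, coarseness_cap=1.0e6):
    shape = levels.shape
    ng = int(levels.max())
    n = {}
    s = {}
    for x in np.ndindex(shape):
        a = levels[x]
        if a == 0:
            continue
        nb = []
        for off in OFFSETS_26:
            y = tuple(xi + oi for xi, oi in zip(x, off))
            if _inside(y, shape) and levels[y] > 0:
                nb.append(int(levels[y]))
        if not nb:
            continue
        abar = sum(nb) / len(nb)
        n[int(a)] = n.get(int(a), 0) + 1
        s[int(a)] = s.get(int(a), 0.0) + abs(int(a) - abar)

    nvp = sum(n.values())
    p = {i: n[i] / nvp for i in n}
    present = sorted(p)
    ngp = len(present)

    coars_den = sum(p[i] * s[i] for i in present)
    coarseness = min(1.0 / coars_den if coars_den > 0 else coarseness_cap, coarseness_cap)

    if ngp > 1:
        contrast = sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
        contrast /= ngp * (ngp - 1)
        contrast *= sum(s.values()) / nvp
        busy_den = sum(abs(i * p[i] - j * p[j]) for i in present for j in present)
        busyness = coars_den / busy_den if busy_den > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present for j in present
        ) / nvp
        s_tot = sum(s.values())
        strength = (sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / s_tot
                    if s_tot > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0

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


def oracle_first_order(intensities, levels):
    x = np.asarray(intensities, dtype=float)[levels > 0]
    lv = levels[levels > 0]
    n = len(x)
    hist = {}
    for v in lv:
        hist[int(v)] = hist.get(int(v), 0) + 1
    p = [c / n for c in hist.values()]
    mean = x.sum() / n
    m2 = sum((xi - mean) ** 2 for xi in x) / n
    m3 = sum((xi - mean) ** 3 for xi in x) / n
    m4 = sum((xi - mean) ** 4 for xi in x) / n
    p10, p90 = np.percentile(x, [10, 90])
    sub = [xi for xi in x if p10 <= xi <= p90]
    sm = sum(sub) / len(sub) if sub else 0.0
    return {
        "Entropy": -sum(pi * _log2(pi) for pi in p),
        "Uniformity": sum(pi ** 2 for pi in p),
        "Skewness": m3 / m2 ** 1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2 ** 2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Mean Absolute Deviation": sum(abs(xi - mean) for xi in x) / n,
        "Robust Mean Absolute Deviation": (sum(abs(v - sm) for v in sub) / len(sub)) if sub else 0.0,
    }
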