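"""Independent brute-force oracles used by the test suite.

Everything here is written as plain nested loops over voxels/levels, with
no shared code with the package implementation, so agreement is evidence
of correctness rather than self-consistency.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

NEIGHBORS_26 = [(dz, dy, dx) for dz, dy, dx in product((-1, 0, 1), repeat=3)
                if (dz, dy, dx) != (0, 0, 0)]


def _in_bounds(idx, shape):
    return all(0 <= i < s for i, s in zip(idx, shape))


# ----------------------------------------------------------------- GLCM

def glcm_pairs(levels, mask, offset, G):
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    P = np.zeros((G, G))
    shape = levels.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                nz, ny, nx = z + offset[0], y + offset[1], x + offset[2]
                if _in_bounds((nz, ny, nx), shape) and mask[nz, ny, nx]:
                    i, j = levels[z, y, x] - 1, levels[nz, ny, nx] - 1
                    P[i, j] += 1
                    P[j, i] += 1
    return P


def glcm_stats_naive(P):
    """The 13 co-occurrence statistics by direct double loops."""
    total = P.sum()
    out = {k: 0.0 for k in
           ("autocorrelation", "cluster_prominence", "cluster_shade",
            "cluster_tendency", "contrast", "correlation",
            "difference_entropy", "dissimilarity", "homogeneity",
            "joint_energy", "joint_entropy", "maximum_probability",
            "sum_average")}
    if total == 0:
        return out
    G = P.shape[0]
    p = P / total
    mu = 0.0
    for i in range(G):
        for j in range(G):
            mu += (i + 1) * p[i, j]
    var = 0.0
    for i in range(G):
        for j in range(G):
            var += (i + 1 - mu) ** 2 * p[i, j]
    pdiff = [0.0] * G
    psum = [0.0] * (2 * G + 1)
    corr_num = 0.0
    for i in range(G):
        for j in range(G):
            v = p[i, j]
            if v == 0:
                continue
            ii, jj = i + 1, j + 1
            out["autocorrelation"] += ii * jj * v
            out["cluster_prominence"] += (ii + jj - 2 * mu) ** 4 * v
            out["cluster_shade"] += (ii + jj - 2 * mu) ** 3 * v
            out["cluster_tendency"] += (ii + jj - 2 * mu) ** 2 * v
            out["contrast"] += (ii - jj) ** 2 * v
            corr_num += (ii - mu) * (jj - mu) * v
            out["dissimilarity"] += abs(ii - jj) * v
            out["homogeneity"] += v / (1 + (ii - jj) ** 2)
            out["joint_energy"] += v * v
            out["joint_entropy"] -= v * math.log2(v)
            pdiff[abs(ii - jj)] += v
            psum[ii + jj] += v
    out["correlation"] = corr_num / var if var > 0 else 1.0
    out["maximum_probability"] = float(p.max())
    out["difference_entropy"] = -sum(q * math.log2(q) for q in pdiff if q > 0)
    out["sum_average"] = sum(k * q for k, q in enumerate(psum))
    return out


# ----------------------------------------------------------------- runs

def run_list(levels, mask, offsets):
    """All maximal runs (level, length) along the given directions."""
    shape = levels.shape
    runs = []
    for off in offsets:
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    if not mask[z, y, x]:
                        continue
                    prev = (z - off[0], y - off[1], x - off[2])
                    if (_in_bounds(prev, shape) and mask[prev]
                            and levels[prev] == levels[z, y, x]):
                        continue   # not a run start
                    length = 1
                    cur = (z, y, x)
                    while True:
                        nxt = tuple(c + o for c, o in zip(cur, off))
                        if (_in_bounds(nxt, shape) and mask[nxt]
                                and levels[nxt] == levels[cur]):
                            length += 1
                            cur = nxt
                        else:
                            break
                    runs.append((int(levels[z, y, x]), length))
    return runs


def rl_matrix_from_runs(runs, G, max_len):
    R = np.zeros((G, max_len))
    for g, ln in runs:
        R[g - 1, ln - 1] += 1
    return R


# ----------------------------------------------------------------- zones

def zone_list(levels, mask):
    """26-connected equal-level zones by BFS flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                g = levels[z, y, x]
                stack = [(z, y, x)]
                seen[z, y, x] = True
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz, dy, dx in NEIGHBORS_26:
                        nb = (cz + dz, cy + dy, cx + dx)
                        if (_in_bounds(nb, shape) and mask[nb]
                                and not seen[nb] and levels[nb] == g):
                            seen[nb] = True
                            stack.append(nb)
                zones.append((int(g), size))
    return zones


# ------------------------------------------------------- rl/sz statistics

def rl_style_stats_naive(M, n_voxels, names):
    """Run-length / size-zone statistic set by explicit loops."""
    N = M.sum()
    out = {k: 0.0 for k in names}
    if N == 0:
        return out
    G, L = M.shape
    p = M / N
    mu_i = sum((i + 1) * p[i, j] for i in range(G) for j in range(L))
    mu_j = sum((j + 1) * p[i, j] for i in range(G) for j in range(L))
    acc = dict.fromkeys(range(16), 0.0)
    row = [M[i, :].sum() for i in range(G)]
    col = [M[:, j].sum() for j in range(L)]
    for i in range(G):
        for j in range(L):
            m = M[i, j]
            if m == 0:
                continue
            ii, jj = i + 1, j + 1
            acc[0] += m / jj ** 2
            acc[1] += m * jj ** 2
            acc[7] += (ii - mu_i) ** 2 * (m / N)
            acc[8] += (jj - mu_j) ** 2 * (m / N)
            acc[9] -= (m / N) * math.log2(m / N)
            acc[10] += m / ii ** 2
            acc[11] += m * ii ** 2
            acc[12] += m / (ii ** 2 * jj ** 2)
            acc[13] += m * ii ** 2 / jj ** 2
            acc[14] += m * jj ** 2 / ii ** 2
            acc[15] += m * ii ** 2 * jj ** 2
    vals = [acc[0] / N, acc[1] / N,
            sum(r ** 2 for r in row) / N, sum(r ** 2 for r in row) / N ** 2,
            sum(c ** 2 for c in col) / N, sum(c ** 2 for c in col) / N ** 2,
            N / n_voxels, acc[7], acc[8], acc[9],
            acc[10] / N, acc[11] / N, acc[12] / N, acc[13] / N,
            acc[14] / N, acc[15] / N]
    return dict(zip(names, vals))


# ----------------------------------------------------------------- GLDM

def gldm_counts(levels, mask, G):
    """Dependence matrix by per-voxel neighbor counting (alpha = 0)."""
    shape = levels.shape
    D = np.zeros((G, 27))
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                dep = 0
                for dz, dy, dx in NEIGHBORS_26:
                    nb = (z + dz, y + dy, x + dx)
                    if (_in_bounds(nb, shape) and mask[nb]
                            and levels[nb] == levels[z, y, x]):
                        dep += 1
                D[levels[z, y, x] - 1, dep] += 1
    return D


def gldm_stats_naive(D, n_voxels, names):
    N = D.sum()
    out = {k: 0.0 for k in names}
    if N == 0:
        return out
    G, K = D.shape
    p = D / N
    mu_i = sum((i + 1) * p[i, j] for i in range(G) for j in range(K))
    mu_j = sum((j + 1) * p[i, j] for i in range(G) for j in range(K))
    row = [D[i, :].sum() for i in range(G)]
    col = [D[:, j].sum() for j in range(K)]
    sde = lde = glv = dv = de = lgl = hgl = a = b = c = d = 0.0
    for i in range(G):
        for j in range(K):
            m = D[i, j]
            if m == 0:
                continue
            ii, jj = i + 1, j + 1
            sde += m / jj ** 2
            lde += m * jj ** 2
            glv += (ii - mu_i) ** 2 * m / N
            dv += (jj - mu_j) ** 2 * m / N
            de -= (m / N) * math.log2(m / N)
            lgl += m / ii ** 2
            hgl += m * ii ** 2
            a += m / (ii ** 2 * jj ** 2)
            b += m * ii ** 2 / jj ** 2
            c += m * jj ** 2 / ii ** 2
            d += m * ii ** 2 * jj ** 2
    vals = [sde / N, lde / N, sum(r ** 2 for r in row) / N,
            sum(q ** 2 for q in col) / N, sum(q ** 2 for q in col) / N ** 2,
            glv, dv, de, lgl / N, hgl / N, a / N, b / N, c / N, d / N]
    return dict(zip(names, vals))


# ----------------------------------------------------------------- NGTDM

def ngtdm_naive(levels, mask, G):
    shape = levels.shape
    n = [0.0] * G
    s = [0.0] * G
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                g = levels[z, y, x]
                nb = []
                for dz, dy, dx in NEIGHBORS_26:
                    q = (z + dz, y + dy, x + dx)
                    if _in_bounds(q, shape) and mask[q]:
                        nb.append(levels[q])
                n[g - 1] += 1
                if nb:
                    s[g - 1] += abs(g - sum(nb) / len(nb))
    return np.array(n), np.array(s)


def ngtdm_stats_naive(n, s):
    N = n.sum()
    out = dict.fromkeys(
        ("coarseness", "contrast", "busyness", "complexity", "strength"), 0.0)
    if N == 0:
        return out
    G = len(n)
    p = n / N
    idx = [i for i in range(G) if p[i] > 0]
    Ngp = len(idx)
    ps = sum(p[i] * s[i] for i in range(G))
    out["coarseness"] = 1.0 / ps if ps > 0 else 1e6
    if Ngp > 1:
        con = sum(p[i] * p[j] * (i - j) ** 2 for i in idx for j in idx)
        out["contrast"] = con / (Ngp * (Ngp - 1)) * s.sum() / N
        denom = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                    for i in idx for j in idx)
        out["busyness"] = ps / denom if denom > 0 else 0.0
        out["complexity"] = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in idx for j in idx) / N
        ssum = s.sum()
        out["strength"] = (sum((p[i] + p[j]) * (i - j) ** 2
                               for i in idx for j in idx) / ssum
                           if ssum > 0 else 0.0)
    return out


# --------------------------------------------------- survival / ML oracles

def harrell_c_naive(lp, time, event):
    """All-pairs audit of Harrell's C (higher lp = higher risk)."""
    n = len(lp)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i must be an observed event occurring before j's follow-up
            if event[i] == 1 and (time[i] < time[j]
                                  or (time[i] == time[j] and event[j] == 0)):
                den += 1
                if lp[i] > lp[j]:
                    num += 1
                elif lp[i] == lp[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den


def youden_scan_naive(scores, labels):
    """Exhaustive threshold scan; returns (best_J, smallest maximizer)."""
    best = (-np.inf, None)
    for c in sorted(set(scores)):
        tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= c)
        fn = sum(1 for s, y in zip(scores, labels) if y == 1 and s < c)
        tn = sum(1 for s, y in zip(scores, labels) if y == 0 and s < c)
        fp = sum(1 for s, y in zip(scores, labels) if y == 0 and s >= c)
        j = tp / (tp + fn) + tn / (tn + fp) - 1
        if j > best[0] + 1e-12:
            best = (j, c)
    return best


def auc_pair_count(scores, labels):
    """AUC by enumerating every positive-negative pair."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def cox_loglik_breslow(beta, x, time, event):
    """Breslow log partial likelihood for a single covariate by direct
    risk-set enumeration."""
    ll = 0.0
    for t in sorted({t for t, e in zip(time, event) if e == 1}):
        risk = [math.exp(beta * xi) for xi, ti in zip(x, time) if ti >= t]
        events_at_t = [(xi, ti) for xi, ti, e in zip(x, time, event)
                       if ti == t and e == 1]
        for xi, _ in events_at_t:
            ll += beta * xi
        ll -= len(events_at_t) * math.log(sum(risk))
    return ll


def logistic_loglik(params, X, y):
    """Bernoulli log-likelihood for a logistic model (intercept first)."""
    b0, bs = params[0], params[1:]
    ll = 0.0
    for xi, yi in zip(X, y):
        eta = b0 + sum(b * v for b, v in zip(bs, xi))
        ll += yi * eta - math.log(1 + math.exp(eta))
    return ll
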