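"""Independent reference computations used only by the tests.

These deliberately avoid the library's code paths: the Otsu oracle
evaluates the between-class-variance definition class by class with
explicit divisions, the texture oracles enumerate voxels naively, and
the AUC oracle uses the rank-statistic identity.
"""

from __future__ import annotations

import numpy as np


def otsu_bruteforce(hist: np.ndarray, tol: float = 1e-9):
    """Exhaustive (K1, K2) maximizer of the three-class between-class
    variance, with tie-averaged thresholds.  O(256^2) over the printed
    loop bounds 1..253 / K1+1..254."""
    p = np.asarray(hist, dtype=np.float64)
    i = np.arange(256, dtype=np.float64)
    m_g = float(i @ p)

    best = -1.0
    tied = []
    for k1 in range(1, 254):
        p1 = p[: k1 + 1].sum()
        m1 = (i[: k1 + 1] @ p[: k1 + 1]) / p1 if p1 > 0 else 0.0
        # vectorised over k2 but with the definition applied class by class
        k2s = np.arange(k1 + 1, 255)
        cp = np.cumsum(p)
        cm = np.cumsum(i * p)
        p2 = cp[k2s] - cp[k1]
        m2sum = cm[k2s] - cm[k1]
        p3 = 1.0 - cp[k2s]
        m3sum = m_g - cm[k2s]
        sigma = np.zeros(len(k2s))
        if p1 > 0:
            sigma += p1 * (m1 - m_g) ** 2
        nz2 = p2 > 0
        sigma[nz2] += p2[nz2] * (m2sum[nz2] / p2[nz2] - m_g) ** 2
        nz3 = p3 > 0
        sigma[nz3] += p3[nz3] * (m3sum[nz3] / p3[nz3] - m_g) ** 2
        for k2, s in zip(k2s, sigma):
            if s > best + tol * max(1.0, abs(best)):
                best = s
                tied = [(k1, int(k2))]
            elif s >= best - tol * max(1.0, abs(best)):
                tied.append((k1, int(k2)))
    k1_star = float(np.mean([t[0] for t in tied]))
    k2_star = float(np.mean([t[1] for t in tied]))
    return k1_star, k2_star, float(best)


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank-statistic identity U / (n1 * n0), ties -> 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * equal) / (len(pos) * len(neg))


def flood_fill_zones(lvl: np.ndarray):
    """(level, size) of 26-connected constant-level zones by explicit BFS."""
    visited = np.zeros(lvl.shape, dtype=bool)
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) != (0, 0, 0)]
    zones = []
    for start in np.argwhere(lvl > 0):
        start = tuple(start)
        if visited[start]:
            continue
        g = lvl[start]
        stack, size = [start], 0
        visited[start] = True
        while stack:
            z, y, x = stack.pop()
            size += 1
            for dz, dy, dx in offsets:
                q = (z + dz, y + dy, x + dx)
                if all(0 <= qi < ni for qi, ni in zip(q, lvl.shape)) \
                        and not visited[q] and lvl[q] == g:
                    visited[q] = True
                    stack.append(q)
        zones.append((int(g), size))
    return zones


def naive_neighbour_stats(lvl: np.ndarray):
    """NGTDM n_i, s_i and GLDM dependence counts by per-voxel loops."""
    shape = lvl.shape
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) != (0, 0, 0)]
    ng = int(lvl.max())
    n = np.zeros(ng)
    s = np.zeros(ng)
    dep = np.zeros(shape, dtype=int)
    for pos in np.argwhere(lvl > 0):
        z, y, x = pos
        vals = []
        for dz, dy, dx in offsets:
            q = (z + dz, y + dy, x + dx)
            if all(0 <= qi < ni for qi, ni in zip(q, shape)) and lvl[q] > 0:
                vals.append(lvl[q])
                if lvl[q] == lvl[z, y, x]:
                    dep[z, y, x] += 1
        if vals:
            g = lvl[z, y, x]
            n[g - 1] += 1
            s[g - 1] += abs(g - np.mean(vals))
    return n, s, dep


def naive_runs(lvl: np.ndarray, off):
    """All (level, run length) pairs along one direction by explicit walking."""
    shape = lvl.shape
    runs = []
    for pos in np.argwhere(lvl > 0):
        prev = tuple(pos - np.asarray(off))
        if all(0 <= pi < ni for pi, ni in zip(prev, shape)) and lvl[prev] == lvl[tuple(pos)]:
            continue  # not a run start
        g = lvl[tuple(pos)]
        length = 1
        cur = np.asarray(pos)
        while True:
            nxt = cur + np.asarray(off)
            if not all(0 <= qi < ni for qi, ni in zip(nxt, shape)) or lvl[tuple(nxt)] != g:
                break
            length += 1
            cur = nxt
        runs.append((int(g), length))
    return runs


def naive_conv3d(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """Direct-loop 3D convolution; x (N,C,D,H,W), w (Cout,Cin,k,k,k)."""
    n, cin, d, h, ww = x.shape
    cout, _, k, _, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    do = (d + 2 * pad - k) // stride + 1
    ho = (h + 2 * pad - k) // stride + 1
    wo = (ww + 2 * pad - k) // stride + 1
    out = np.zeros((n, cout, do, ho, wo))
    for ni in range(n):
        for co in range(cout):
            for z in range(do):
                for y in range(ho):
                    for xg in range(wo):
                        patch = xp[ni, :, z * stride:z * stride + k,
                                   y * stride:y * stride + k, xg * stride:xg * stride + k]
                        out[ni, co, z, y, xg] = np.sum(patch * w[co])
    return out
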