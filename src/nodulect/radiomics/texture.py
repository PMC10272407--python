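"""Gray-level texture matrices and their scalar features.

All matrix families share one quantization: masked intensities are
binned into ``n_gray_levels`` equal-width levels (1..Ng) over the masked
intensity range.  Directed statistics use the 13 unique 3D offsets;
neighbourhood statistics use the full 26-neighbourhood.

Degenerate-input conventions (so every feature stays finite):
correlation-type features are 1 when the gray-level variance is zero,
entropies use 0*log(0) = 0, NGTDM coarseness is capped at 1e6, and GLDM
dependence counts enter the emphasis formulas shifted by one (a voxel
with no dependent neighbours contributes at dependence size 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage

#: The 13 unique direction offsets (dz, dy, dx) of a 3D grid.
OFFSETS_13: List[Tuple[int, int, int]] = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1),
    (1, 0, 0), (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
]

_EPS = np.spacing(1.0)


@dataclass
class TextureMatrixConfig:
    """Shared parameters of the texture-matrix computations."""

    n_gray_levels: int = 32
    glcm_distance: int = 1
    directions: List[Tuple[int, int, int]] = field(default_factory=lambda: list(OFFSETS_13))
    symmetrize: bool = True

    def __post_init__(self) -> None:
        if self.n_gray_levels < 2:
            raise ValueError("need at least 2 gray levels")
        if self.glcm_distance < 1:
            raise ValueError("distance must be >= 1")


def quantize_levels(gray: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Bin masked intensities into levels 1..n_levels; 0 outside the mask."""
    gray = np.asarray(gray, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    lvl = np.zeros(gray.shape, dtype=np.int64)
    vals = gray[mask]
    if vals.size == 0:
        raise ValueError("mask selects no voxels")
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        bw = (hi - lo) / n_levels
        lvl[mask] = np.minimum((vals - lo) // bw, n_levels - 1).astype(np.int64) + 1
    else:
        lvl[mask] = 1
    return lvl


def _shifted(a: np.ndarray, off: Tuple[int, int, int], fill=0) -> np.ndarray:
    """out[p] = a[p + off] where defined, else fill."""
    out = np.full_like(a, fill)
    src, dst = [], []
    for o, n in zip(off, a.shape):
        if o >= 0:
            dst.append(slice(0, n - o))
            src.append(slice(o, n))
        else:
            dst.append(slice(-o, n))
            src.append(slice(0, n + o))
    out[tuple(dst)] = a[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(lvl: np.ndarray, cfg: TextureMatrixConfig) -> np.ndarray:
    """Direction-averaged, symmetrized, normalized co-occurrence matrix."""
    ng = cfg.n_gray_levels
    acc = np.zeros((ng, ng))
    used = 0
    for off in cfg.directions:
        off = tuple(int(o) * cfg.glcm_distance for o in off)
        nb = _shifted(lvl, off)
        valid = (lvl > 0) & (nb > 0)
        if not valid.any():
            continue
        pairs = (lvl[valid] - 1) * ng + (nb[valid] - 1)
        c = np.bincount(pairs, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
        if cfg.symmetrize:
            c = c + c.T
        acc += c / c.sum()
        used += 1
    if used == 0:
        raise ValueError("no co-occurring voxel pairs inside the mask")
    return acc / used


def glcm_features(gray: np.ndarray, mask: np.ndarray, cfg: TextureMatrixConfig | None = None) -> Dict[str, float]:
    """24 co-occurrence features from the direction-averaged matrix."""
    cfg = cfg or TextureMatrixConfig()
    lvl = quantize_levels(gray, mask, cfg.n_gray_levels)
    if int(np.count_nonzero(lvl)) < 2:
        raise ValueError("GLCM needs at least two masked voxels")
    p = glcm_matrix(lvl, cfg)
    ng = cfg.n_gray_levels
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(ng)                      # |i-j| = 0..ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())

    def ent(q: np.ndarray) -> float:
        nz = q[q > 0]
        return float(-np.sum(nz * np.log2(nz)))

    autocorr = float(np.sum(ii * jj * p))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    if var_x > 0 and var_y > 0:
        correlation = (autocorr - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        correlation = 1.0
    diff_avg = float(k_diff @ p_diff)
    joint_entropy = ent(p)

    hx, hy = ent(px), ent(py)
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-np.sum(p * log_pxy))
    hxy2 = float(-np.sum(pxy * log_pxy))
    div = max(hx, hy)
    imc1 = (joint_entropy - hxy1) / div if div > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    off_diag = np.abs(ii - jj) > 0
    inverse_variance = float(np.sum(p[off_diag] / (ii - jj)[off_diag] ** 2))

    # MCC: sqrt of the second-largest eigenvalue of Q(i,j) = sum_k p(i,k)p(j,k)/(px_i py_k)
    nzx, nzy = px > 0, py > 0
    if nzx.sum() > 1:
        psub = p[np.ix_(nzx, nzy)]
        q = (psub / px[nzx, None]) @ (psub / py[nzy]).T
        eig = np.sort(np.linalg.eigvals(q).real)
        mcc = float(np.sqrt(np.clip(eig[-2], 0.0, 1.0)))
    else:
        mcc = 1.0

    return {
        "Autocorrelation": autocorr,
        "JointAverage": mu_x,
        "ClusterProminence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - mu_x - mu_y) ** 2 * p)),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2) @ p_diff),
        "JointEnergy": float(np.sum(p ** 2)),
        "JointEntropy": joint_entropy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": inverse_variance,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(k_sum @ p_sum),
        "SumEntropy": ent(p_sum),
        "SumSquares": float(np.sum((ii - mu_x) ** 2 * p)),
        "MCC": mcc,
    }


# ---------------------------------------------------------------------------
# GLRLM


def run_length_matrix(lvl: np.ndarray, off: Tuple[int, int, int], max_len: int) -> np.ndarray:
    """Run-length counts along one direction; rows = levels, cols = lengths 1..max_len."""
    mask = lvl > 0
    back = tuple(-o for o in off)
    prev = _shifted(lvl, back)
    starts = mask & (prev != lvl)
    pos = np.argwhere(starts)
    ng = int(lvl.max())
    mat = np.zeros((ng, max_len))
    if len(pos) == 0:
        return mat
    g = lvl[tuple(pos.T)]
    lengths = np.ones(len(pos), dtype=np.int64)
    cur = pos.copy()
    active = np.ones(len(pos), dtype=bool)
    off_arr = np.asarray(off)
    shape = np.asarray(lvl.shape)
    while active.any():
        idx = np.flatnonzero(active)
        nxt = cur[idx] + off_arr
        inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
        cont = np.zeros(len(idx), dtype=bool)
        if inb.any():
            cont[inb] = lvl[tuple(nxt[inb].T)] == g[idx][inb]
        grow = idx[cont]
        lengths[grow] += 1
        cur[grow] = nxt[cont]
        active[idx[~cont]] = False
    np.add.at(mat, (g - 1, np.minimum(lengths, max_len) - 1), 1.0)
    return mat


def glrlm_features(gray: np.ndarray, mask: np.ndarray, cfg: TextureMatrixConfig | None = None) -> Dict[str, float]:
    """16 run-length features from the direction-averaged matrix."""
    cfg = cfg or TextureMatrixConfig()
    lvl = quantize_levels(gray, mask, cfg.n_gray_levels)
    n_masked = int(np.count_nonzero(lvl))
    max_len = int(np.ceil(np.sqrt(3) * max(lvl.shape))) + 1
    mats = [run_length_matrix(lvl, off, max_len) for off in cfg.directions]
    width = max(m.shape[1] for m in mats)
    p = np.zeros((cfg.n_gray_levels, width))
    for m in mats:
        p[: m.shape[0], : m.shape[1]] += m
    p /= len(mats)

    nr = p.sum()
    pn = p / nr
    i = np.arange(1, p.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, p.shape[1] + 1, dtype=np.float64)[None, :]
    pg = pn.sum(axis=1)          # marginal over levels
    pr = pn.sum(axis=0)          # marginal over lengths
    mu_i = float(np.sum(i * pn))
    mu_j = float(np.sum(j * pn))
    nz = pn[pn > 0]

    return {
        "ShortRunEmphasis": float(np.sum(pn / j ** 2)),
        "LongRunEmphasis": float(np.sum(pn * j ** 2)),
        "GrayLevelNonUniformity": float(np.sum(p.sum(axis=1) ** 2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg ** 2)),
        "RunLengthNonUniformity": float(np.sum(p.sum(axis=0) ** 2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(pr ** 2)),
        "RunPercentage": float(nr / n_masked),
        "GrayLevelVariance": float(np.sum(pn * (i - mu_i) ** 2)),
        "RunVariance": float(np.sum(pn * (j - mu_j) ** 2)),
        "RunEntropy": float(-np.sum(nz * np.log2(nz))),
        "LowGrayLevelRunEmphasis": float(np.sum(pn / i ** 2)),
        "HighGrayLevelRunEmphasis": float(np.sum(pn * i ** 2)),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(pn / (i ** 2 * j ** 2))),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(pn * i ** 2 / j ** 2)),
        "LongRunLowGrayLevelEmphasis": float(np.sum(pn * j ** 2 / i ** 2)),
        "LongRunHighGrayLevelEmphasis": float(np.sum(pn * i ** 2 * j ** 2)),
    }


# ---------------------------------------------------------------------------
# GLSZM


def size_zone_table(lvl: np.ndarray) -> List[Tuple[int, int]]:
    """(level, zone size) for every 26-connected constant-level zone."""
    structure = np.ones((3, 3, 3), dtype=int)
    zones = []
    for g in range(1, int(lvl.max()) + 1):
        lab, n = ndimage.label(lvl == g, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((g, int(s)) for s in sizes)
    return zones


def glszm_features(gray: np.ndarray, mask: np.ndarray, cfg: TextureMatrixConfig | None = None) -> Dict[str, float]:
    """16 size-zone features (26-connected constant-level zones)."""
    cfg = cfg or TextureMatrixConfig()
    lvl = quantize_levels(gray, mask, cfg.n_gray_levels)
    n_masked = int(np.count_nonzero(lvl))
    zones = size_zone_table(lvl)
    max_size = max(s for _, s in zones)
    p = np.zeros((cfg.n_gray_levels, max_size))
    for g, s in zones:
        p[g - 1, s - 1] += 1.0

    nz_total = p.sum()
    pn = p / nz_total
    i = np.arange(1, p.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, p.shape[1] + 1, dtype=np.float64)[None, :]
    pg = pn.sum(axis=1)
    ps = pn.sum(axis=0)
    mu_i = float(np.sum(i * pn))
    mu_j = float(np.sum(j * pn))
    nz = pn[pn > 0]

    return {
        "SmallAreaEmphasis": float(np.sum(pn / j ** 2)),
        "LargeAreaEmphasis": float(np.sum(pn * j ** 2)),
        "GrayLevelNonUniformity": float(np.sum(p.sum(axis=1) ** 2) / nz_total),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg ** 2)),
        "SizeZoneNonUniformity": float(np.sum(p.sum(axis=0) ** 2) / nz_total),
        "SizeZoneNonUniformityNormalized": float(np.sum(ps ** 2)),
        "ZonePercentage": float(nz_total / n_masked),
        "GrayLevelVariance": float(np.sum(pn * (i - mu_i) ** 2)),
        "ZoneVariance": float(np.sum(pn * (j - mu_j) ** 2)),
        "ZoneEntropy": float(-np.sum(nz * np.log2(nz))),
        "LowGrayLevelZoneEmphasis": float(np.sum(pn / i ** 2)),
        "HighGrayLevelZoneEmphasis": float(np.sum(pn * i ** 2)),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(pn / (i ** 2 * j ** 2))),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(pn * i ** 2 / j ** 2)),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(pn * j ** 2 / i ** 2)),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(pn * i ** 2 * j ** 2)),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(lvl: np.ndarray, n_levels: int) -> Tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i) per level: counts and summed |level - neighbourhood mean|.

    The neighbourhood mean at a voxel is the average quantized level of
    its masked 26-neighbours; voxels without any masked neighbour are
    excluded from the table.
    """
    mask = lvl > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve((lvl * mask).astype(np.float64), kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0)
    diff = np.zeros(lvl.shape)
    diff[valid] = np.abs(lvl[valid] - nb_sum[valid] / nb_cnt[valid])
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    levels = lvl[valid] - 1
    np.add.at(n, levels, 1.0)
    np.add.at(s, levels, diff[valid])
    return n, s


def ngtdm_features(gray: np.ndarray, mask: np.ndarray, cfg: TextureMatrixConfig | None = None) -> Dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength."""
    cfg = cfg or TextureMatrixConfig()
    lvl = quantize_levels(gray, mask, cfg.n_gray_levels)
    n, s = ngtdm_table(lvl, cfg.n_gray_levels)
    nvp = n.sum()
    if nvp == 0:
        raise ValueError("no masked voxel has a masked neighbour")
    p = n / nvp
    i = np.arange(1, cfg.n_gray_levels + 1, dtype=np.float64)
    present = p > 0
    ngp = int(present.sum())

    denom = float(np.sum(p * s))
    coarseness = min(1.0 / denom, 1e6) if denom > 0 else 1e6

    if ngp > 1:
        pi, pj = p[present][:, None], p[present][None, :]
        ii, jj = i[present][:, None], i[present][None, :]
        si, sj = s[present][:, None], s[present][None, :]
        contrast = float(np.sum(pi * pj * (ii - jj) ** 2)) / (ngp * (ngp - 1)) * float(s.sum()) / nvp
        busy_den = float(np.sum(np.abs(ii * pi - jj * pj)))
        busyness = denom / busy_den if busy_den > 0 else 0.0
        complexity = float(np.sum(np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj))) / nvp
        strength = float(np.sum((pi + pj) * (ii - jj) ** 2)) / s.sum() if s.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# GLDM


def dependence_matrix(lvl: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Counts of (level, number of dependent 26-neighbours).

    A neighbour is dependent when its level differs from the centre's by
    at most ``alpha``.  Columns index dependence counts 0..26.
    """
    mask = lvl > 0
    dep = np.zeros(lvl.shape, dtype=np.int64)
    for off in OFFSETS_13:
        for sgn in (1, -1):
            o = tuple(sgn * c for c in off)
            nb = _shifted(lvl, o)
            dep += (mask & (nb > 0) & (np.abs(nb - lvl) <= alpha)).astype(np.int64)
    ng = int(lvl.max())
    mat = np.zeros((ng, 27))
    np.add.at(mat, (lvl[mask] - 1, dep[mask]), 1.0)
    return mat


def gldm_features(gray: np.ndarray, mask: np.ndarray, cfg: TextureMatrixConfig | None = None,
                  alpha: int = 0) -> Dict[str, float]:
    """14 dependence-matrix features (dependence size = count + 1)."""
    cfg = cfg or TextureMatrixConfig()
    lvl = quantize_levels(gray, mask, cfg.n_gray_levels)
    p = dependence_matrix(lvl, alpha=alpha)
    nz_total = p.sum()
    pn = p / nz_total
    i = np.arange(1, p.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, p.shape[1] + 1, dtype=np.float64)[None, :]  # dependence size
    pg = pn.sum(axis=1)
    pd = pn.sum(axis=0)
    mu_i = float(np.sum(i * pn))
    mu_j = float(np.sum(j * pn))
    nz = pn[pn > 0]

    return {
        "SmallDependenceEmphasis": float(np.sum(pn / j ** 2)),
        "LargeDependenceEmphasis": float(np.sum(pn * j ** 2)),
        "GrayLevelNonUniformity": float(np.sum(p.sum(axis=1) ** 2) / nz_total),
        "DependenceNonUniformity": float(np.sum(p.sum(axis=0) ** 2) / nz_total),
        "DependenceNonUniformityNormalized": float(np.sum(pd ** 2)),
        "GrayLevelVariance": float(np.sum(pn * (i - mu_i) ** 2)),
        "DependenceVariance": float(np.sum(pn * (j - mu_j) ** 2)),
        "DependenceEntropy": float(-np.sum(nz * np.log2(nz))),
        "LowGrayLevelEmphasis": float(np.sum(pn / i ** 2)),
        "HighGrayLevelEmphasis": float(np.sum(pn * i ** 2)),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(pn / (i ** 2 * j ** 2))),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(pn * i ** 2 / j ** 2)),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(pn * j ** 2 / i ** 2)),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(pn * i ** 2 * j ** 2)),
    }
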