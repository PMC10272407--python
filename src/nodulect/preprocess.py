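"""Nodule cube extraction and two-threshold Otsu masking.

The preprocessing stage turns a CT volume (Hounsfield units) plus an
axis-aligned nodule bounding box into a cubic gray-level patch and a
binary retention mask.  The mask is derived by three-band Otsu
thresholding of the 256-level histogram: the gray axis is split at two
levels ``(K1, K2)`` chosen to maximise the between-class variance

    sigma^2(K1, K2) = sum_k P_k (m_k - m_G)^2,  k in {1, 2, 3}

and the upper two bands (everything strictly above ``K1``) are kept.
The lowest band captures aerated parenchyma while the upper bands keep
the solid nodule and its rim, discarding most vessel/air interference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "CTVolume",
    "NoduleAnnotation",
    "GrayCube",
    "ThresholdPair",
    "DEFAULT_HU_WINDOW",
    "MANUAL_HU_WINDOW",
    "quantize_to_gray",
    "normalized_histogram",
    "interclass_variance",
    "otsu_two_thresholds",
    "build_mask",
    "bbox_to_cube",
    "bbox_inner_slices",
    "resample_cube",
    "OtsuNodulePreprocessor",
]

#: Default HU window covering aerated lung through soft tissue.
DEFAULT_HU_WINDOW: Tuple[float, float] = (-1000.0, 400.0)

#: Manual comparator window (solid-tissue sensitive), kept for ablations.
MANUAL_HU_WINDOW: Tuple[float, float] = (0.0, 300.0)

#: Fill value (HU of air) used when padding cubes past the volume border.
PAD_FILL_HU: float = -1024.0

BENIGN, MALIGNANT = 0, 1


@dataclass(frozen=True)
class CTVolume:
    """A 3D scalar grid in Hounsfield units.

    Axes are ordered ``(z, y, x)``; ``spacing`` is ``(dz, dy, dx)`` in mm.
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError("CT volume must be a non-empty 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing components must be positive")
        object.__setattr__(self, "voxels", v)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class NoduleAnnotation:
    """Inclusive, 0-based voxel bounding box plus a benign/malignant label.

    Index order matches the volume axes: ``z`` is the slice axis.
    """

    xmin: int
    xmax: int
    ymin: int
    ymax: int
    zmin: int
    zmax: int
    label: int = BENIGN
    volume_id: str = ""

    def __post_init__(self) -> None:
        if not (self.xmin <= self.xmax and self.ymin <= self.ymax and self.zmin <= self.zmax):
            raise ValueError("bounding box min indices must not exceed max indices")
        if min(self.xmin, self.ymin, self.zmin) < 0:
            raise ValueError("bounding box indices must be non-negative")
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError(f"label must be 0 (benign) or 1 (malignant), got {self.label}")

    @property
    def extents(self) -> Tuple[int, int, int]:
        """Box edge lengths (D, H, W) in voxels, inclusive convention."""
        return (
            self.zmax - self.zmin + 1,
            self.ymax - self.ymin + 1,
            self.xmax - self.xmin + 1,
        )

    def check_inside(self, volume: CTVolume) -> None:
        nz, ny, nx = volume.shape
        if self.zmax >= nz or self.ymax >= ny or self.xmax >= nx:
            raise ValueError("annotation extends beyond the volume")


@dataclass(frozen=True)
class GrayCube:
    """Cubic patch quantized to integer gray levels 0..255."""

    voxels: np.ndarray
    window: Tuple[float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or len(set(v.shape)) != 1:
            raise ValueError("gray cube must have three equal edge lengths")
        if v.min() < 0 or v.max() > 255:
            raise ValueError("gray levels must lie in [0, 255]")
        object.__setattr__(self, "voxels", v.astype(np.int16))

    @property
    def side(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class ThresholdPair:
    """Optimal Otsu thresholds and the attained between-class variance.

    After tie-averaging the thresholds may be non-integer means of the
    tied candidate levels.
    """

    k1: float
    k2: float
    sigma2: float

    def __post_init__(self) -> None:
        if not (0 < self.k1 < self.k2 < 255):
            raise ValueError("thresholds must satisfy 0 < k1 < k2 < 255")


# ---------------------------------------------------------------------------
# gray-level quantization and histogram


def quantize_to_gray(volume_crop: np.ndarray, window: Tuple[float, float] = DEFAULT_HU_WINDOW) -> GrayCube:
    """Map an HU cube linearly onto integer gray levels 0..255.

    Values are clamped to ``window = (hu_lo, hu_hi)`` and mapped with
    ``floor(255 * (v - lo) / (hi - lo))``, clamped to 255 at the top.
    """
    v = np.asarray(volume_crop, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("HU volume contains non-finite voxels")
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"degenerate HU window {window!r}")
    scaled = np.floor(255.0 * (np.clip(v, lo, hi) - lo) / (hi - lo))
    return GrayCube(np.clip(scaled, 0, 255).astype(np.int16), window=(lo, hi))


def normalized_histogram(gray: GrayCube | np.ndarray) -> np.ndarray:
    """256-bin gray-level probability vector ``p_i = count(i) / N``."""
    v = gray.voxels if isinstance(gray, GrayCube) else np.asarray(gray)
    if v.size == 0:
        raise ValueError("cannot histogram an empty cube")
    counts = np.bincount(v.ravel().astype(np.int64), minlength=256)
    return counts / v.size


# ---------------------------------------------------------------------------
# two-threshold Otsu


def interclass_variance(hist: np.ndarray, k1: int, k2: int) -> float:
    """Between-class variance of the three bands split at (k1, k2).

    Bands are ``C1 = {0..k1}``, ``C2 = {k1+1..k2}``, ``C3 = {k2+1..255}``;
    the level at a threshold belongs to the lower band.  An empty band
    contributes zero.
    """
    if not (0 < k1 < k2 < 255):
        raise ValueError("need 0 < k1 < k2 < 255")
    p = np.asarray(hist, dtype=np.float64)
    i = np.arange(256)
    m_g = float(i @ p)
    total = 0.0
    for sl in (slice(0, k1 + 1), slice(k1 + 1, k2 + 1), slice(k2 + 1, 256)):
        pk = p[sl].sum()
        if pk > 0:
            mk = (i[sl] @ p[sl]) / pk
            total += pk * (mk - m_g) ** 2
    return total


def otsu_two_thresholds(hist: np.ndarray) -> ThresholdPair:
    """Exhaustive two-threshold Otsu search with tie-averaging.

    Scans ``1 <= K1 <= 253``, ``K1 < K2 <= 254``.  When several (K1, K2)
    pairs attain the maximal variance, each returned threshold is the
    arithmetic mean of its tied candidates.

    The search is vectorised via cumulative moments; it is numerically
    identical to evaluating :func:`interclass_variance` at every pair.
    """
    p = np.asarray(hist, dtype=np.float64)
    if p.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if (p > 0).sum() < 3:
        warnings.warn("histogram occupies fewer than 3 gray levels; thresholds are best-effort", stacklevel=2)

    i = np.arange(256, dtype=np.float64)
    cp = np.cumsum(p)          # cp[k]  = P(level <= k)
    cm = np.cumsum(i * p)      # cm[k]  = first moment up to k
    m_g = cm[-1]

    k1 = np.arange(1, 254)
    k2 = np.arange(2, 255)
    # class masses / moments on the (k1, k2) grid
    p1 = cp[k1][:, None]
    m1s = cm[k1][:, None]
    p2 = cp[k2][None, :] - p1
    m2s = cm[k2][None, :] - m1s
    p3 = 1.0 - cp[k2][None, :]
    m3s = m_g - cm[k2][None, :]

    def term(pk: np.ndarray, mks: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(pk > 0, (mks - pk * m_g) ** 2 / np.where(pk > 0, pk, 1.0), 0.0)
        return t

    sigma = term(p1, m1s) + term(p2, m2s) + term(p3, m3s)
    sigma[k1[:, None] >= k2[None, :]] = -np.inf

    best = sigma.max()
    # tie tolerance: wide enough that float rounding of mathematically
    # identical sums cannot split a tie class
    tied = np.argwhere(sigma >= best - 1e-9 * max(1.0, abs(best)))
    k1_star = float(np.mean(k1[tied[:, 0]]))
    k2_star = float(np.mean(k2[tied[:, 1]]))
    return ThresholdPair(k1=k1_star, k2=k2_star, sigma2=float(best))


def build_mask(gray: GrayCube, pair: ThresholdPair) -> np.ndarray:
    """Boolean retention mask keeping the upper two Otsu bands.

    A voxel is retained iff its gray level is strictly above
    ``round(k1)`` (the level at the threshold belongs to the discarded
    lowest band).  ``k1`` is rounded half-up since tie-averaged
    thresholds may be fractional.
    """
    k1 = int(np.floor(pair.k1 + 0.5))
    mask = gray.voxels > k1
    if not mask.any():
        warnings.warn("Otsu mask is empty: the nodule was filtered out entirely", stacklevel=2)
    return mask


# ---------------------------------------------------------------------------
# geometry


def bbox_to_cube(volume: CTVolume, ann: NoduleAnnotation, fill: float = PAD_FILL_HU) -> np.ndarray:
    """Crop the bounding box and pad it symmetrically into a cube.

    The cube side is the largest box extent; along shorter axes the box
    content is centered, with the extra voxel going to the high-index
    side when the shortfall is odd.  Padding voxels are set to ``fill``
    (air), so they are discarded by the retention mask; this also covers
    boxes flush against the volume border.
    """
    ann.check_inside(volume)
    extents = ann.extents
    if min(extents) < 1:
        raise ValueError("bounding box has a zero extent")
    side = max(extents)

    lows = (ann.zmin, ann.ymin, ann.xmin)
    out = np.full((side, side, side), fill, dtype=np.float64)
    src_sel, dst_sel = [], []
    for low, ext in zip(lows, extents):
        pad_lo = (side - ext) // 2
        src_sel.append(slice(low, low + ext))
        dst_sel.append(slice(pad_lo, pad_lo + ext))
    out[tuple(dst_sel)] = volume.voxels[tuple(src_sel)]
    return out


def bbox_inner_slices(ann: NoduleAnnotation) -> Tuple[slice, slice, slice]:
    """Slices of the original bbox content inside its padded cube."""
    extents = ann.extents
    side = max(extents)
    return tuple(slice((side - e) // 2, (side - e) // 2 + e) for e in extents)


def resample_cube(cube: np.ndarray, target_side: int, *, is_mask: bool = False) -> np.ndarray:
    """Resample a cube to ``target_side**3`` voxels.

    Trilinear interpolation for intensity cubes; nearest-neighbour for
    masks (boolean output stays boolean).
    """
    if target_side < 2:
        raise ValueError("target_side must be >= 2")
    cube = np.asarray(cube)
    src = cube.shape[0]
    if cube.shape != (src,) * 3:
        raise ValueError("input must be a cube")
    if src == target_side:
        return cube.copy()
    # endpoint-aligned sample grid so a linear ramp stays a linear ramp
    coords = np.linspace(0.0, src - 1.0, target_side)
    grid = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.stack([g.ravel() for g in grid])
    order = 0 if is_mask else 1
    vals = ndimage.map_coordinates(cube.astype(np.float64), pts, order=order, mode="nearest")
    out = vals.reshape((target_side,) * 3)
    return out > 0.5 if is_mask else out


# ---------------------------------------------------------------------------
# estimator facade


class OtsuNodulePreprocessor:
    """Transformer turning (volume, annotation) pairs into nodule samples.

    Parameters
    ----------
    window : tuple of float
        HU window applied before 256-level quantization.  The default
        spans aerated lung to soft tissue; ``threshold_mode="manual"``
        switches to the fixed solid-tissue window (0, 300) and uses the
        window itself as the retention rule (every voxel inside the
        window is kept), bypassing Otsu.
    target_side : int or None
        Edge length the masked cube is resampled to (None keeps the
        native cube size).
    threshold_mode : {"otsu", "manual"}
    apply_mask : bool
        Zero out discarded voxels in the returned cube.
    """

    def __init__(
        self,
        window: Tuple[float, float] = DEFAULT_HU_WINDOW,
        target_side: int | None = None,
        threshold_mode: str = "otsu",
        apply_mask: bool = True,
        fill: float = PAD_FILL_HU,
    ) -> None:
        self.window = window
        self.target_side = target_side
        self.threshold_mode = threshold_mode
        self.apply_mask = apply_mask
        self.fill = fill

    # sklearn-style param plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {
            "window": self.window,
            "target_side": self.target_side,
            "threshold_mode": self.threshold_mode,
            "apply_mask": self.apply_mask,
            "fill": self.fill,
        }

    def set_params(self, **params) -> "OtsuNodulePreprocessor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def transform_one(self, volume: CTVolume, ann: NoduleAnnotation):
        """Extract one nodule: returns ``(gray, mask, thresholds)``.

        ``gray`` is the quantized cube (masked if ``apply_mask``),
        ``mask`` the boolean retention mask, both at ``target_side``.
        """
        if self.threshold_mode not in ("otsu", "manual"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        hu = bbox_to_cube(volume, ann, fill=self.fill)
        if self.threshold_mode == "manual":
            window = MANUAL_HU_WINDOW
            gray = quantize_to_gray(hu, window)
            # manual rule: retain voxels inside the HU window
            mask = (hu >= window[0]) & (hu <= window[1])
            pair = None
        else:
            gray = quantize_to_gray(hu, self.window)
            # histogram over the true bbox content only: padding must not
            # claim the lowest band and promote parenchyma into a
            # retained band.  The threshold still applies to the whole
            # cube; padding (air, gray 0) always falls below k1.
            inner = gray.voxels[bbox_inner_slices(ann)]
            pair = otsu_two_thresholds(normalized_histogram(inner))
            mask = build_mask(gray, pair)
        g = gray.voxels.astype(np.float64)
        if self.target_side is not None:
            g = resample_cube(g, self.target_side)
            mask = resample_cube(mask, self.target_side, is_mask=True)
        if self.apply_mask:
            g = np.where(mask, g, 0.0)
        return g, mask, pair

    def transform(self, X: Sequence[Tuple[CTVolume, NoduleAnnotation]]):
        """Vector form of :meth:`transform_one` over (volume, annotation) pairs."""
        return [self.transform_one(v, a) for v, a in X]
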