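"""Class-conditional 3D augmentation of nodule cubes.

Cubes are randomly flipped, affine-transformed and rotated with
per-class probabilities (the minority benign class is augmented more
aggressively); radiomic feature vectors are never touched, and the
minority class can additionally be oversampled with augmented copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .preprocess import BENIGN, MALIGNANT

__all__ = ["AugmentPolicy", "TransformDraw", "draw_transforms",
           "apply_transforms", "augment_cube", "oversample_minority"]


@dataclass
class AugmentPolicy:
    """Per-class transform probabilities and ranges.

    Defaults: flips and affines with probability 0.7 (benign) / 0.4
    (malignant); rotations with the same per-class probabilities, about
    a random grid axis, by an angle uniform in (0, 35] degrees for
    benign and (0, 30] for malignant.  Affine ranges (scale 0.9-1.1,
    shear up to 5 degrees, translation up to 2 voxels) are mild enough
    to keep the nodule inside the cube.
    """

    flip_prob: Dict[int, float] = field(default_factory=lambda: {BENIGN: 0.7, MALIGNANT: 0.4})
    affine_prob: Dict[int, float] = field(default_factory=lambda: {BENIGN: 0.7, MALIGNANT: 0.4})
    rotate_prob: Dict[int, float] = field(default_factory=lambda: {BENIGN: 0.7, MALIGNANT: 0.4})
    max_angle_deg: Dict[int, float] = field(default_factory=lambda: {BENIGN: 35.0, MALIGNANT: 30.0})
    scale_range: Tuple[float, float] = (0.9, 1.1)
    max_shear_deg: float = 5.0
    max_translate_vox: float = 2.0

    def __post_init__(self) -> None:
        for probs in (self.flip_prob, self.affine_prob, self.rotate_prob):
            if any(not 0.0 <= p <= 1.0 for p in probs.values()):
                raise ValueError("probabilities must lie in [0, 1]")
        if any(a <= 0 for a in self.max_angle_deg.values()):
            raise ValueError("maximum rotation angles must be positive")

    @classmethod
    def identity(cls) -> "AugmentPolicy":
        zeros = {BENIGN: 0.0, MALIGNANT: 0.0}
        return cls(flip_prob=dict(zeros), affine_prob=dict(zeros), rotate_prob=dict(zeros))


def _affine_about_center(cube: np.ndarray, matrix: np.ndarray, offset_extra: np.ndarray) -> np.ndarray:
    center = (np.asarray(cube.shape) - 1) / 2.0
    offset = center - matrix @ center + offset_extra
    return ndimage.affine_transform(cube, matrix, offset=offset, order=1, mode="constant", cval=0.0)


def _rotation_matrix(axis: int, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    m = np.eye(3)
    a, b = [i for i in range(3) if i != axis]
    m[a, a], m[a, b], m[b, a], m[b, b] = c, -s, s, c
    return m


@dataclass
class TransformDraw:
    """One sampled augmentation: which transforms fire, with what parameters."""

    flip_axis: int | None = None
    affine: Tuple[np.ndarray, np.ndarray] | None = None   # (matrix, extra shift)
    rotation: Tuple[int, float] | None = None             # (axis, angle in degrees)


def draw_transforms(label: int, policy: AugmentPolicy, rng: np.random.Generator) -> TransformDraw:
    """Sample flip / affine / rotation per the label's probabilities."""
    if label not in (BENIGN, MALIGNANT):
        raise ValueError(f"unknown label {label!r}")
    draw = TransformDraw()
    if rng.random() < policy.flip_prob[label]:
        draw.flip_axis = int(rng.integers(3))
    if rng.random() < policy.affine_prob[label]:
        scale = rng.uniform(*policy.scale_range)
        shear = np.deg2rad(rng.uniform(-policy.max_shear_deg, policy.max_shear_deg))
        m = np.eye(3) * scale
        i, j = rng.choice(3, size=2, replace=False)
        m[i, j] += np.tan(shear)
        shift = rng.uniform(-policy.max_translate_vox, policy.max_translate_vox, size=3)
        draw.affine = (m, shift)
    if rng.random() < policy.rotate_prob[label]:
        draw.rotation = (int(rng.integers(3)), float(rng.uniform(0.0, policy.max_angle_deg[label])))
    return draw


def apply_transforms(cube: np.ndarray, draw: TransformDraw) -> np.ndarray:
    """Apply a sampled draw: flip -> affine -> rotation.

    Interpolation is trilinear with constant zero fill, matching the
    preprocessing conventions; the output is clipped to the input
    intensity range.
    """
    cube = np.asarray(cube, dtype=np.float64)
    if cube.ndim != 3 or len(set(cube.shape)) != 1:
        raise ValueError("augmentation expects a cubic 3D array")
    lo, hi = float(cube.min()), float(cube.max())
    out = cube
    if draw.flip_axis is not None:
        out = np.flip(out, axis=draw.flip_axis).copy()
    if draw.affine is not None:
        m, shift = draw.affine
        out = _affine_about_center(out, np.linalg.inv(m), shift)
    if draw.rotation is not None:
        axis, angle = draw.rotation
        out = _affine_about_center(out, _rotation_matrix(axis, np.deg2rad(angle)), np.zeros(3))
    return np.clip(out, lo, hi)


def augment_cube(cube: np.ndarray, label: int, policy: AugmentPolicy, rng: np.random.Generator) -> np.ndarray:
    """One stochastic augmentation of a single cube; features are never touched."""
    return apply_transforms(cube, draw_transforms(label, policy, rng))


def oversample_minority(
    samples: Sequence[dict],
    target_ratio: float,
    rng: np.random.Generator,
    policy: AugmentPolicy | None = None,
) -> List[dict]:
    """Duplicate-with-augmentation the minority class up to ``target_ratio``.

    ``samples`` are dicts with at least ``cube`` and ``label`` keys; any
    ``features`` entry is copied through untouched.  With ratio 1.0 the
    classes end up balanced.
    """
    labels = np.array([s["label"] for s in samples])
    n_by_class = {c: int((labels == c).sum()) for c in (BENIGN, MALIGNANT)}
    if min(n_by_class.values()) == 0:
        raise ValueError("oversampling needs both classes present")
    minority = min(n_by_class, key=n_by_class.get)
    majority_n = max(n_by_class.values())
    target_n = int(round(target_ratio * majority_n))
    deficit = target_n - n_by_class[minority]
    if deficit <= 0:
        return list(samples)

    pool = [s for s in samples if s["label"] == minority]
    policy = policy or AugmentPolicy()
    out = list(samples)
    for _ in range(deficit):
        src = pool[int(rng.integers(len(pool)))]
        dup = dict(src)
        dup["cube"] = augment_cube(src["cube"], minority, policy, rng)
        out.append(dup)
    return out
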