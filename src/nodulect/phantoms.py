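"""Synthetic CT phantoms with known ground truth.

Each phantom is a low-HU parenchyma background holding one bright,
roughly spherical solid nodule (optionally lobulated and spiculated),
tubular vessel distractors crossing the nodule's bounding box, small
air pockets, a scanner point-spread blur and additive Gaussian noise.  Benign and malignant
phantoms differ in geometry (radius, spiculation) and texture
(mean HU, HU spread), not in position, so both the visual and the
radiomics branch carry class signal.

HU palette: parenchyma -900..-700, nodule +20..+120, vessels +30..+80,
air pockets -1000.  Solid structures sit well above the parenchyma
band, so both the Otsu retention mask and the fixed manual window
(0..300) keep the nodule and discard the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .preprocess import BENIGN, MALIGNANT, CTVolume, NoduleAnnotation

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "CLASS_RANGES"]


@dataclass
class PhantomSpec:
    """Full description of one phantom; generation is a pure function of (spec, seed)."""

    volume_shape: Tuple[int, int, int] = (48, 48, 48)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: Tuple[float, float] = (-900.0, -700.0)
    nodule_center: Optional[Tuple[float, float, float]] = None
    nodule_radius: float = 5.0
    nodule_hu_mean: float = 45.0
    nodule_hu_sd: float = 12.0
    spiculation_count: int = 0
    spiculation_length: float = 2.5
    lobulation_amplitude: float = 0.08
    vessel_count: int = 2
    vessel_radius: float = 1.1
    vessel_hu: float = 55.0
    air_pocket_count: int = 1
    psf_sigma: float = 0.7
    noise_sd: float = 15.0
    label: int = BENIGN

    def __post_init__(self) -> None:
        if self.nodule_radius <= 0:
            raise ValueError("nodule radius must be positive")


#: Class-conditional parameter ranges: the study conditions of the
#: synthetic cohort.  Malignant nodules are larger, denser, more
#: spiculated and more heterogeneous; the ranges overlap slightly so the
#: task is learnable but not trivial.
CLASS_RANGES: Dict[int, Dict[str, Tuple[float, float]]] = {
    BENIGN: {
        "nodule_radius": (4.0, 6.0),
        "nodule_hu_mean": (25.0, 60.0),
        "nodule_hu_sd": (8.0, 15.0),
        "spiculation_count": (0, 1),
        "lobulation_amplitude": (0.02, 0.10),
    },
    MALIGNANT: {
        "nodule_radius": (6.0, 9.0),
        "nodule_hu_mean": (60.0, 115.0),
        "nodule_hu_sd": (20.0, 35.0),
        "spiculation_count": (4, 8),
        "lobulation_amplitude": (0.10, 0.22),
    },
}


def _smooth_noise(shape, rng: np.random.Generator, sigma: float = 1.2) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma)


def _nodule_mask(spec: PhantomSpec, center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Boolean nodule support: lobulated sphere plus Gaussian spicule bumps."""
    zz, yy, xx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in spec.volume_shape], indexing="ij")
    d = np.stack([zz - center[0], yy - center[1], xx - center[2]])
    dist = np.sqrt(np.sum(d ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(dist > 0, d / np.where(dist > 0, dist, 1.0), 0.0)

    # lobulation: smooth directional modulation from three random plane waves
    w = rng.standard_normal((3, 3))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    phase = rng.uniform(0, 2 * np.pi, 3)
    modulation = np.zeros(spec.volume_shape)
    for k in range(3):
        proj = np.tensordot(w[k], u, axes=(0, 0))
        modulation += np.sin(3.0 * proj + phase[k]) / 3.0
    radius = spec.nodule_radius * (1.0 + spec.lobulation_amplitude * modulation)

    # spicules: narrow radial bumps along random directions
    if spec.spiculation_count > 0:
        spike = np.zeros(spec.volume_shape)
        for _ in range(int(spec.spiculation_count)):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            cos = np.tensordot(v, u, axes=(0, 0))
            spike = np.maximum(spike, np.exp(-(1.0 - cos) / 0.02))
        radius = radius + spec.spiculation_length * spike
    return dist <= radius


def _add_cylinder(volume: np.ndarray, p0: np.ndarray, direction: np.ndarray,
                  radius: float, hu: float, exclude: np.ndarray) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in volume.shape], indexing="ij")
    p = np.stack([zz, yy, xx]) - p0[:, None, None, None]
    along = np.tensordot(direction, p, axes=(0, 0))
    perp2 = np.sum(p ** 2, axis=0) - along ** 2
    tube = (perp2 <= radius ** 2) & ~exclude
    volume[tube] = hu
    return tube


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator):
    """Render one phantom.

    Returns ``(volume, annotation, ground_truth_mask, label)`` where the
    annotation is the tight bounding box of the ground-truth nodule.
    """
    shape = spec.volume_shape
    margin = spec.nodule_radius + spec.spiculation_length + 2
    if 2 * margin >= min(shape):
        raise ValueError("nodule does not fit inside the volume")
    if spec.nodule_center is None:
        center = np.array([rng.uniform(margin, n - margin) for n in shape])
    else:
        center = np.asarray(spec.nodule_center, dtype=np.float64)
        if np.any(center < margin) or np.any(center > np.asarray(shape) - margin):
            raise ValueError("nodule center too close to the volume border")

    lo, hi = spec.background_hu
    volume = 0.5 * (lo + hi) + 0.5 * (hi - lo) * _smooth_noise(shape, rng)

    nodule = _nodule_mask(spec, center, rng)
    texture = spec.nodule_hu_mean + spec.nodule_hu_sd * _smooth_noise(shape, rng, sigma=0.8)
    volume[nodule] = texture[nodule]

    # vessels: tubes through points near the nodule surface, crossing the bbox
    for _ in range(int(spec.vessel_count)):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        offset = rng.standard_normal(3)
        offset /= np.linalg.norm(offset)
        p0 = center + offset * (spec.nodule_radius + rng.uniform(1.0, 3.0))
        _add_cylinder(volume, p0, direction, spec.vessel_radius,
                      spec.vessel_hu + rng.uniform(-15.0, 15.0), exclude=nodule)

    for _ in range(int(spec.air_pocket_count)):
        c = np.array([rng.uniform(3, n - 3) for n in shape])
        if np.linalg.norm(c - center) < spec.nodule_radius + 4:
            continue
        zz, yy, xx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
        pocket = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= rng.uniform(1.5, 3.0) ** 2
        volume[pocket & ~nodule] = -1000.0

    # scanner point-spread blur: creates the partial-volume rim real CT shows
    if spec.psf_sigma > 0:
        volume = ndimage.gaussian_filter(volume, spec.psf_sigma)
    if spec.noise_sd > 0:
        volume = volume + rng.normal(0.0, spec.noise_sd, shape)

    idx = np.argwhere(nodule)
    (zmin, ymin, xmin), (zmax, ymax, xmax) = idx.min(axis=0), idx.max(axis=0)
    ann = NoduleAnnotation(xmin=int(xmin), xmax=int(xmax), ymin=int(ymin), ymax=int(ymax),
                           zmin=int(zmin), zmax=int(zmax), label=spec.label)
    return CTVolume(volume, spacing=spec.spacing), ann, nodule, spec.label


def _draw_spec(label: int, rng: np.random.Generator, base: PhantomSpec) -> PhantomSpec:
    r = CLASS_RANGES[label]
    return PhantomSpec(
        volume_shape=base.volume_shape,
        spacing=base.spacing,
        background_hu=base.background_hu,
        nodule_radius=rng.uniform(*r["nodule_radius"]),
        nodule_hu_mean=rng.uniform(*r["nodule_hu_mean"]),
        nodule_hu_sd=rng.uniform(*r["nodule_hu_sd"]),
        spiculation_count=int(rng.integers(int(r["spiculation_count"][0]),
                                           int(r["spiculation_count"][1]) + 1)),
        lobulation_amplitude=rng.uniform(*r["lobulation_amplitude"]),
        vessel_count=int(rng.integers(1, base.vessel_count + 1)),
        vessel_radius=base.vessel_radius,
        air_pocket_count=base.air_pocket_count,
        noise_sd=base.noise_sd,
        label=label,
    )


def generate_dataset(n: int, class_ratio: float = 0.5, seed: int = 0,
                     base: PhantomSpec | None = None) -> List[dict]:
    """Generate ``n`` phantoms with the given malignant fraction.

    Returns per-sample dicts with keys ``volume``, ``annotation``,
    ``gt_mask``, ``label``, ``volume_id``.  Fully determined by the seed.
    """
    if n < 2 or not 0.0 < class_ratio < 1.0:
        raise ValueError("need n >= 2 and both classes requested")
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    n_mal = int(round(class_ratio * n))
    labels = np.array([MALIGNANT] * n_mal + [BENIGN] * (n - n_mal))
    labels = labels[rng.permutation(n)]
    samples = []
    for i, label in enumerate(labels):
        spec = _draw_spec(int(label), rng, base)
        volume, ann, gt, _ = generate_phantom(spec, rng)
        vid = f"phantom_{i:04d}"
        ann = NoduleAnnotation(**{**ann.__dict__, "volume_id": vid})
        samples.append({"volume": volume, "annotation": ann, "gt_mask": gt,
                        "label": int(label), "volume_id": vid})
    return samples
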