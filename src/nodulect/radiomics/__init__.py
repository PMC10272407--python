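"""Mask-aware radiomic feature extraction.

Eight feature classes (first-order statistics, 3D and 2D shape, GLCM,
GLRLM, GLSZM, NGTDM and GLDM) are computed from a quantized gray cube
and its binary retention mask.  The default profile emits the 107
features the fusion classifier's radiomics branch consumes; the full
catalogue holds 120.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import catalogue
from .catalogue import FEATURE_CLASSES, default_profile, feature_names, full_profile
from .firstorder import first_order
from .shape import largest_axial_slice, shape_2d, shape_3d
from .texture import (
    OFFSETS_13,
    TextureMatrixConfig,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    quantize_levels,
)

__all__ = [
    "FEATURE_CLASSES",
    "TextureMatrixConfig",
    "default_profile",
    "full_profile",
    "feature_names",
    "first_order",
    "shape_3d",
    "shape_2d",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "extract_profile",
    "RadiomicsExtractor",
]


def extract_profile(
    gray: np.ndarray,
    mask: np.ndarray,
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    profile: List[Tuple[str, str]] | None = None,
    cfg: TextureMatrixConfig | None = None,
) -> Tuple[np.ndarray, List[str]]:
    """Compute one ordered feature vector for a (gray, mask) pair.

    Returns ``(values, names)`` with entries in catalogue order for the
    requested profile (default: the 107-feature fusion profile).
    """
    gray = np.asarray(gray, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if gray.shape != mask.shape:
        raise ValueError("gray cube and mask shapes differ")
    if not mask.any():
        raise ValueError("cannot extract radiomics from an empty mask")
    profile = profile if profile is not None else default_profile()
    cfg = cfg or TextureMatrixConfig()

    wanted = {cls for cls, _ in profile}
    computed: Dict[str, Dict[str, float]] = {}
    if "first_order" in wanted:
        voxel_volume = float(np.prod(spacing))
        computed["first_order"] = first_order(gray[mask], voxel_volume, n_bins=cfg.n_gray_levels)
    if "shape3d" in wanted:
        computed["shape3d"] = shape_3d(mask, spacing)
    if "shape2d" in wanted:
        idx = largest_axial_slice(mask)
        computed["shape2d"] = shape_2d(mask[idx], spacing[1:])
    if "glcm" in wanted:
        computed["glcm"] = glcm_features(gray, mask, cfg)
    if "glrlm" in wanted:
        computed["glrlm"] = glrlm_features(gray, mask, cfg)
    if "glszm" in wanted:
        computed["glszm"] = glszm_features(gray, mask, cfg)
    if "ngtdm" in wanted:
        computed["ngtdm"] = ngtdm_features(gray, mask, cfg)
    if "gldm" in wanted:
        computed["gldm"] = gldm_features(gray, mask, cfg)

    values = np.array([computed[cls][name] for cls, name in profile], dtype=np.float64)
    if not np.all(np.isfinite(values)):
        bad = [f"{c}__{n}" for (c, n), v in zip(profile, values) if not np.isfinite(v)]
        raise AssertionError(f"non-finite radiomic features: {bad}")
    return values, feature_names(profile)


class RadiomicsExtractor:
    """sklearn-style transformer mapping nodule samples to feature rows.

    ``transform`` takes a sequence of ``(gray, mask)`` or
    ``(gray, mask, spacing)`` tuples and returns an ``(n, d)`` array
    aligned to the chosen profile.
    """

    def __init__(
        self,
        profile: str = "default",
        n_gray_levels: int = 32,
        glcm_distance: int = 1,
        spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    ) -> None:
        self.profile = profile
        self.n_gray_levels = n_gray_levels
        self.glcm_distance = glcm_distance
        self.spacing = spacing

    def get_params(self, deep: bool = True) -> dict:
        return {
            "profile": self.profile,
            "n_gray_levels": self.n_gray_levels,
            "glcm_distance": self.glcm_distance,
            "spacing": self.spacing,
        }

    def set_params(self, **params) -> "RadiomicsExtractor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _profile(self) -> List[Tuple[str, str]]:
        if self.profile == "default":
            return default_profile()
        if self.profile == "full":
            return full_profile()
        raise ValueError(f"unknown profile {self.profile!r}")

    def fit(self, X=None, y=None) -> "RadiomicsExtractor":
        """Stateless; records the output feature names."""
        self.feature_names_ = feature_names(self._profile())
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X: Sequence) -> np.ndarray:
        self.fit()
        cfg = TextureMatrixConfig(n_gray_levels=self.n_gray_levels, glcm_distance=self.glcm_distance)
        prof = self._profile()
        rows = []
        for sample in X:
            gray, mask = sample[0], sample[1]
            spacing = sample[2] if len(sample) > 2 else self.spacing
            values, _ = extract_profile(gray, mask, spacing, prof, cfg)
            rows.append(values)
        return np.vstack(rows)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit().transform(X)

    def to_frame(self, X: Sequence, ids: Sequence[str] | None = None, labels=None) -> pd.DataFrame:
        """Feature table with ``volume_id``/``label`` columns for CSV export."""
        arr = self.transform(X)
        df = pd.DataFrame(arr, columns=self.feature_names_)
        if labels is not None:
            df.insert(0, "label", list(labels))
        if ids is not None:
            df.insert(0, "volume_id", list(ids))
        return df
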