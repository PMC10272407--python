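"""The radiomic feature catalogue and extraction profiles.

The catalogue enumerates 120 features in eight classes; the default
fusion profile enables 107 of them (the dimensionality the radiomics
branch of the classifier expects).  The 107 are obtained by disabling
first-order standard deviation (the square root of variance), the two
shape compactnesses (monotone transforms of sphericity) and the whole
2D-shape class.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

FIRST_ORDER = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
    "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "StandardDeviation", "Skewness", "Kurtosis",
    "Variance", "Uniformity",
]

SHAPE3D = [
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Compactness1", "Compactness2", "Maximum3DDiameter",
    "Maximum2DDiameterSlice", "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow", "MajorAxisLength", "MinorAxisLength",
    "LeastAxisLength", "Elongation", "Flatness",
]

SHAPE2D = [
    "MeshSurface", "PixelSurface", "Perimeter", "PerimeterSurfaceRatio",
    "Sphericity", "SphericalDisproportion", "MaximumDiameter",
    "MajorAxisLength", "MinorAxisLength", "Elongation",
]

GLCM = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
]

GLRLM = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
]

GLSZM = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
]

NGTDM = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

GLDM = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]

FEATURE_CLASSES: Dict[str, List[str]] = {
    "first_order": FIRST_ORDER,
    "shape3d": SHAPE3D,
    "shape2d": SHAPE2D,
    "glcm": GLCM,
    "glrlm": GLRLM,
    "glszm": GLSZM,
    "ngtdm": NGTDM,
    "gldm": GLDM,
}

# features disabled in the default (fusion) profile
_DEFAULT_DISABLED = {
    ("first_order", "StandardDeviation"),
    ("shape3d", "Compactness1"),
    ("shape3d", "Compactness2"),
} | {("shape2d", name) for name in SHAPE2D}


def full_profile() -> List[Tuple[str, str]]:
    """All 120 catalogue features in class order."""
    return [(cls, name) for cls, names in FEATURE_CLASSES.items() for name in names]


def default_profile() -> List[Tuple[str, str]]:
    """The 107-feature profile feeding the fusion classifier."""
    return [entry for entry in full_profile() if entry not in _DEFAULT_DISABLED]


def feature_names(profile: List[Tuple[str, str]]) -> List[str]:
    """Flat ``<class>__<feature>`` names for CSV headers."""
    return [f"{cls}__{name}" for cls, name in profile]
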