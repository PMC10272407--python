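"""Volume and annotation-table readers/writers.

Supported volume formats: NIfTI (``.nii`` / ``.nii.gz``) via nibabel and
DICOM series directories via pydicom (HU restored from rescale
slope/intercept).  The annotation table is a CSV with header
``volume_id,xmin,xmax,ymin,ymax,zmin,zmax,label`` using 0-based
inclusive voxel indices and label 0 = benign, 1 = malignant.
"""

from __future__ import annotations

import os
from typing import List, Tuple

import numpy as np
import pandas as pd

from .preprocess import CTVolume, NoduleAnnotation

ANNOTATION_COLUMNS = ["volume_id", "xmin", "xmax", "ymin", "ymax", "zmin", "zmax", "label"]


def read_nifti(path: str) -> CTVolume:
    """Load a NIfTI volume as (z, y, x) HU voxels with mm spacing."""
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    # nibabel axes are (x, y, z); transpose to (z, y, x)
    voxels = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(voxels=voxels, spacing=spacing)


def write_nifti(path: str, voxels: np.ndarray, spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a (z, y, x) array to NIfTI; booleans are saved as uint8."""
    import nibabel as nib

    arr = np.asarray(voxels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    data = np.transpose(arr, (2, 1, 0))
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    nib.save(nib.Nifti1Image(data, affine), path)


def read_dicom_series(directory: str) -> CTVolume:
    """Load a DICOM series directory, sorted by slice position, in HU."""
    import pydicom

    files = [os.path.join(directory, f) for f in sorted(os.listdir(directory)) if not f.startswith(".")]
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "pixel_array"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM slices in {directory!r}")
    slices.sort(key=lambda ds: float(getattr(ds, "ImagePositionPatient", [0, 0, ds.InstanceNumber])[2]))
    arrs = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrs.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    voxels = np.stack(arrs, axis=0)
    ps = getattr(slices[0], "PixelSpacing", [1.0, 1.0])
    if len(slices) > 1 and hasattr(slices[0], "ImagePositionPatient"):
        dz = abs(float(slices[1].ImagePositionPatient[2]) - float(slices[0].ImagePositionPatient[2])) or 1.0
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    return CTVolume(voxels=voxels, spacing=(dz, float(ps[0]), float(ps[1])))


def read_volume(path: str) -> CTVolume:
    """Dispatch on path: NIfTI file or DICOM directory."""
    if os.path.isdir(path):
        return read_dicom_series(path)
    return read_nifti(path)


def read_annotations(path: str) -> List[NoduleAnnotation]:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return [
        NoduleAnnotation(
            xmin=int(r.xmin), xmax=int(r.xmax),
            ymin=int(r.ymin), ymax=int(r.ymax),
            zmin=int(r.zmin), zmax=int(r.zmax),
            label=int(r.label), volume_id=str(r.volume_id),
        )
        for r in df.itertuples()
    ]


def write_annotations(path: str, annotations: List[NoduleAnnotation]) -> None:
    rows = [
        {"volume_id": a.volume_id, "xmin": a.xmin, "xmax": a.xmax,
         "ymin": a.ymin, "ymax": a.ymax, "zmin": a.zmin, "zmax": a.zmax,
         "label": a.label}
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)
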