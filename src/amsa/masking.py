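"""Metric binary morphology and voxel filters for WM mask construction.

The analysis restricts voxels to an eroded white-matter mask (sphere,
r = 2 mm), removes crossing-fibre voxels (FA < 0.6 or peak quotient
> 0.3), and — in patients — removes lesions dilated by 1 mm to obtain the
normal-appearing white matter (NAWM) mask.  Per-ROI lesion load is the
lesion volume inside the ROI divided by the ROI volume.

Structuring elements are metric: an offset belongs to the sphere element
iff its physical displacement (offset times voxel size, Euclidean) is
within the radius, so anisotropic grids are handled.  Out-of-volume voxels
count as background during erosion (conservative at the edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "MaskVolume",
    "make_sphere_element",
    "erode_mask",
    "dilate_mask",
    "crossing_fibre_filter",
    "build_nawm_mask",
    "lesion_load",
    "read_mask_nifti",
    "write_mask_nifti",
]

#: closed-boundary crossing-fibre acceptance thresholds
FA_MIN = 0.6
PQ_MAX = 0.3


@dataclass
class MaskVolume:
    """A binary 3-D mask with physical voxel size in mm per axis."""

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3-D array")
        vs = self.voxel_size
        if np.isscalar(vs):
            vs = (float(vs),) * 3
        self.voxel_size = tuple(float(v) for v in vs)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (mm)")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def _check_same_grid(self, other: "MaskVolume") -> None:
        if self.data.shape != other.data.shape or self.voxel_size != other.voxel_size:
            raise ValueError("masks live on different grids (shape or voxel size mismatch)")


def make_sphere_element(radius_mm: float, voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Boolean sphere footprint: offsets with ||offset * voxel_size|| <= r.

    Returns an odd-shaped boolean array centred on the zero offset.  For
    r = 0 (or any radius below the smallest voxel dimension) the element
    degenerates to the single centre voxel.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    vs = np.asarray(voxel_size, dtype=float)
    if vs.size != 3 or np.any(vs <= 0):
        raise ValueError("voxel_size must be three positive lengths (mm)")
    half = np.floor(radius_mm / vs).astype(int)
    grids = np.meshgrid(*(np.arange(-h, h + 1) for h in half), indexing="ij")
    dist2 = sum((g * v) ** 2 for g, v in zip(grids, vs))
    return dist2 <= radius_mm**2 + 1e-9


def erode_mask(mask: MaskVolume, radius_mm: float) -> MaskVolume:
    """Keep a voxel iff the whole sphere element fits inside the mask."""
    elem = make_sphere_element(radius_mm, mask.voxel_size)
    if elem.size == 1:
        return MaskVolume(mask.data.copy(), mask.voxel_size)
    eroded = ndimage.binary_erosion(mask.data, structure=elem, border_value=0)
    return MaskVolume(eroded, mask.voxel_size)


def dilate_mask(mask: MaskVolume, radius_mm: float) -> MaskVolume:
    """Union of the sphere element placed at every foreground voxel."""
    elem = make_sphere_element(radius_mm, mask.voxel_size)
    if elem.size == 1:
        return MaskVolume(mask.data.copy(), mask.voxel_size)
    dilated = ndimage.binary_dilation(mask.data, structure=elem)
    return MaskVolume(dilated, mask.voxel_size)


def crossing_fibre_filter(
    samples: pd.DataFrame, fa_min: float = FA_MIN, pq_max: float = PQ_MAX
) -> pd.DataFrame:
    """Retain voxels with FA >= fa_min and PQ <= pq_max (closed boundary).

    Low-FA voxels lack a coherent principal fibre direction and high-PQ
    voxels contain crossing fibres; both make the fibre-to-field angle
    ill-defined and are excluded.  Idempotent by construction.
    """
    if "fa" not in samples.columns or "pq" not in samples.columns:
        raise ValueError("voxel table must carry 'fa' and 'pq' columns")
    if samples[["fa", "pq"]].isna().any().any():
        raise ValueError("missing FA/PQ values in voxel table")
    keep = (samples["fa"] >= fa_min) & (samples["pq"] <= pq_max)
    return samples.loc[keep].reset_index(drop=True)


def build_nawm_mask(
    wm_mask: MaskVolume, lesion_mask: MaskVolume, dilation_mm: float = 1.0
) -> MaskVolume:
    """NAWM = WM minus the lesion mask dilated by ``dilation_mm``."""
    wm_mask._check_same_grid(lesion_mask)
    dilated = dilate_mask(lesion_mask, dilation_mm)
    return MaskVolume(wm_mask.data & ~dilated.data, wm_mask.voxel_size)


def lesion_load(roi_mask: MaskVolume, lesion_mask: MaskVolume) -> float:
    """Fraction of the ROI volume occupied by lesions, in [0, 1]."""
    roi_mask._check_same_grid(lesion_mask)
    n_roi = roi_mask.n_voxels
    if n_roi == 0:
        raise ValueError("lesion load is undefined for an empty ROI")
    return float((roi_mask.data & lesion_mask.data).sum() / n_roi)


def read_mask_nifti(path, threshold: float = 0.5) -> MaskVolume:
    """Load a NIfTI volume as a binary mask (values > threshold)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj) > threshold
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MaskVolume(data, voxel_size)


def write_mask_nifti(mask: MaskVolume, path) -> None:
    """Write a binary mask as uint8 NIfTI with the voxel size in the affine."""
    import nibabel as nib

    affine = np.diag(list(mask.voxel_size) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.voxel_size)
    nib.save(img, str(path))
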