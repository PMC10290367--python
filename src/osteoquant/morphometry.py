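"""Callus segmentation and morphometry on calibrated density images.

New callus is separated from pre-existing cortical bone by excluding an
externally supplied old-bone mask (day-0 geometry; in synthetic studies the
generator's truth mask), thresholding on mineral density inside a
defect-centred axial region of interest, and removing small disconnected
islands. Outputs are the two morphometric endpoints: callus volume (cm^3)
and mean callus mineral density (mg HA/cm^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology

from .calibration import DensityImage

__all__ = [
    "CallusSegmentation",
    "MorphometryResult",
    "segment_callus",
    "compute_morphometry",
    "dice",
]

DEFAULT_MINERALIZATION_THRESHOLD = 450.0  # mg HA/cm^3


@dataclass
class CallusSegmentation:
    callus_mask: np.ndarray
    old_bone_mask: np.ndarray
    roi: tuple[float, float]  # axial slab, mm, half-open [lo, hi)
    mineralization_threshold: float  # mg HA/cm^3
    spacing: float  # mm


@dataclass(frozen=True)
class MorphometryResult:
    callus_volume: float  # cm^3
    callus_density: float  # mg HA/cm^3 (NaN when the mask is empty)
    voxel_count: int


def segment_callus(
    density: DensityImage,
    old_bone_mask: np.ndarray,
    roi: tuple[float, float] | None = None,
    mineralization_threshold: float = DEFAULT_MINERALIZATION_THRESHOLD,
    min_component_voxels: int = 50,
) -> CallusSegmentation:
    """Voxels >= threshold, inside the axial ROI, outside old bone, cleaned.

    ``roi`` is an axial slab in mm along the last axis (half-open); when
    omitted the whole axial extent is used. Connected components smaller
    than ``min_component_voxels`` are discarded as noise islands.
    """
    rho = density.data
    old = np.asarray(old_bone_mask, dtype=bool)
    if old.shape != rho.shape:
        raise ValueError("old-bone mask grid does not match the density image")
    nz = rho.shape[2]
    h = density.spacing
    if roi is None:
        roi = (0.0, nz * h)
    lo, hi = roi
    z_centers = (np.arange(nz) + 0.5) * h
    in_roi = (z_centers >= lo) & (z_centers < hi)
    if not in_roi.any():
        raise ValueError(f"ROI {roi} mm selects no slices (volume spans 0-{nz * h} mm)")

    mask = (rho >= mineralization_threshold) & ~old
    mask &= in_roi[None, None, :]
    if min_component_voxels > 1 and mask.any():
        # components strictly smaller than min_component_voxels are noise
        mask = morphology.remove_small_objects(mask, max_size=min_component_voxels - 1)
    return CallusSegmentation(mask, old, (float(lo), float(hi)),
                              mineralization_threshold, h)


def compute_morphometry(seg: CallusSegmentation, density: DensityImage) -> MorphometryResult:
    """Callus volume (voxel count x spacing^3, mm^3 -> cm^3) and mean density.

    An empty mask yields volume 0 and density NaN (undefined, not zero).
    """
    if seg.callus_mask.shape != density.data.shape:
        raise ValueError("segmentation grid does not match the density image")
    n = int(seg.callus_mask.sum())
    vol_cm3 = n * density.spacing**3 / 1000.0
    if n == 0:
        return MorphometryResult(0.0, float("nan"), 0)
    mean_rho = float(density.data[seg.callus_mask].mean())
    return MorphometryResult(vol_cm3, mean_rho, n)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap coefficient between two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
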