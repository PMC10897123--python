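"""Ventricular background ROI construction.

The contrast metrics reference the choroid plexus against the surrounding
ventricular CSF.  The background region is built exactly as the measurement
protocol prescribes: start from the lateral-ventricle mask, remove the union
of all ChP masks (every sequence, so no sequence's plexus voxels leak into
the background of another), then erode with a spherical kernel of 2 mm so
that only voxels whose whole neighbourhood is ventricular CSF survive.

The kernel radius is physical (mm): the structuring element enumerates voxel
offsets whose world-space Euclidean norm is within the radius, computed from
the mask's voxel size, so anisotropic grids erode correctly (a 2 mm radius
spans +/-2 voxels in a 1 mm direction but only +/-1 voxel in a 2 mm
direction).  Outside-grid voxels count as background, so border voxels erode
away — conservative for an ROI whose neighbourhood cannot be verified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image_io import BinaryMask, check_same_geometry

__all__ = ["StructuringElement", "erode", "build_background_roi"]


@dataclass(frozen=True)
class StructuringElement:
    """A closed-ball footprint in physical units.

    ``footprint`` is a boolean array of odd shape centred on the zero offset;
    a cell is True iff its voxel offset has mm-norm <= ``radius_mm`` under
    ``voxel_size``.  Inclusion uses <= so the on-axis voxels at exactly the
    radius are part of the ball.
    """

    radius_mm: float
    voxel_size: tuple[float, float, float]
    footprint: np.ndarray

    @classmethod
    def sphere(
        cls, radius_mm: float, voxel_size: Sequence[float]
    ) -> "StructuringElement":
        if radius_mm < 0:
            raise ValueError("radius_mm must be >= 0")
        vs = tuple(float(v) for v in voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive values: {vs}")
        # per-axis reach in whole voxels
        reach = [int(np.floor(radius_mm / v + 1e-9)) for v in vs]
        axes = [np.arange(-r, r + 1) for r in reach]
        ii, jj, kk = np.meshgrid(*axes, indexing="ij")
        dist2 = (ii * vs[0]) ** 2 + (jj * vs[1]) ** 2 + (kk * vs[2]) ** 2
        footprint = dist2 <= radius_mm**2 + 1e-9
        return cls(radius_mm=float(radius_mm), voxel_size=vs, footprint=footprint)

    @property
    def offsets(self) -> np.ndarray:
        """(m, 3) integer voxel displacements inside the ball."""
        centre = (np.array(self.footprint.shape) - 1) // 2
        return np.argwhere(self.footprint) - centre


def erode(mask: BinaryMask, se: StructuringElement) -> BinaryMask:
    """Morphological erosion: keep a voxel iff every SE offset lands on a 1.

    Offsets reaching outside the grid count as 0, so the mask retreats from
    the image border.
    """
    if se.footprint.size == 1:
        return BinaryMask(data=mask.data.copy(), affine=mask.affine)
    eroded = ndimage.binary_erosion(
        mask.data.astype(bool), structure=se.footprint, border_value=0
    )
    return BinaryMask(data=eroded.astype(np.uint8), affine=mask.affine)


def build_background_roi(
    ventricles: BinaryMask,
    chp_masks: Sequence[BinaryMask],
    erosion_radius_mm: float = 2.0,
) -> BinaryMask:
    """Ventricles minus the union of ChP masks, then eroded.

    The order is fixed: subtraction first, erosion second, so the erosion
    also pulls the ROI away from plexus surfaces, not only from the
    ventricle wall.

    Raises if the result is empty — that signals a geometry too small for the
    requested radius (or ChP masks covering the ventricles), never a usable
    measurement.
    """
    if erosion_radius_mm < 0:
        raise ValueError("erosion_radius_mm must be >= 0")
    for i, m in enumerate(chp_masks):
        check_same_geometry(ventricles, m, what=f"ventricles vs chp_masks[{i}]")
    region = ventricles.data.astype(bool)
    for m in chp_masks:
        region &= ~m.data.astype(bool)
    se = StructuringElement.sphere(erosion_radius_mm, ventricles.voxel_size)
    result = erode(
        BinaryMask(data=region.astype(np.uint8), affine=ventricles.affine), se
    )
    if result.voxel_count == 0:
        raise ValueError(
            "empty background ROI after exclusion and erosion "
            f"(radius {erosion_radius_mm} mm)"
        )
    return result
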