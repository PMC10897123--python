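"""NIfTI volume and binary-mask containers with a common-space contract.

Every downstream metric in this package assumes that the volumes of one
subject live on the same voxel grid with the same affine (co-registration
happens upstream).  This module provides the in-memory carriers
(:class:`VolumeImage`, :class:`BinaryMask`, :class:`SubjectBundle`), NIfTI
round-trip I/O via nibabel, and the validation that enforces the contract.

Volumes are used in their stored voxel grid; no reorientation is performed.
Which voxel axis corresponds to an anatomical axis (axial z, coronal y) is
declared in the run configuration, not inferred here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeImage",
    "BinaryMask",
    "SubjectBundle",
    "ValidationReport",
    "read_volume",
    "read_mask",
    "binarize",
    "write_volume",
    "validate_common_space",
    "check_same_geometry",
]

#: absolute tolerance for comparing affine entries; resampled NIfTI headers
#: carry float32 rounding, so exact equality is too strict.
AFFINE_TOL = 1e-4


@dataclass
class VolumeImage:
    """A 3D scalar grid with a voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got {self.data.ndim} axes {self.data.shape}"
            )
        if any(n <= 0 for n in self.data.shape):
            raise ValueError(f"every axis must have positive length: {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if not np.all(np.isfinite(self.affine)):
            raise ValueError("affine contains non-finite entries")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        vs = self.voxel_size
        if any(not np.isfinite(v) or v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be positive and finite: {vs}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """(dx, dy, dz) in mm: Euclidean norms of the affine's spatial columns."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


class BinaryMask(VolumeImage):
    """A :class:`VolumeImage` whose voxels are exactly 0 or 1."""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(
                f"mask values must be exactly 0 or 1; found {uniq[:10]}"
            )
        self.data = data.astype(np.uint8)
        super().__post_init__()

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def same_geometry_as(self, other: VolumeImage, tol: float = AFFINE_TOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, rtol=0.0, atol=tol
        )


@dataclass
class SubjectBundle:
    """One subject's co-registered volumes.

    ``chp_masks`` is keyed by ``(sequence, rater)``; the per-sequence mask used
    for the main metrics is the primary rater's.
    """

    subject_id: str
    intensities: Mapping[str, VolumeImage]
    chp_masks: Mapping[tuple[str, str], BinaryMask]
    ventricle_mask: BinaryMask

    def sequences(self) -> list[str]:
        return sorted(self.intensities)

    def raters(self) -> list[str]:
        return sorted({r for (_, r) in self.chp_masks})

    def mask(self, sequence: str, rater: str) -> BinaryMask:
        return self.chp_masks[(sequence, rater)]

    def all_members(self) -> dict[str, VolumeImage]:
        members: dict[str, VolumeImage] = {
            f"intensity[{s}]": v for s, v in self.intensities.items()
        }
        members.update(
            {f"chp[{s},{r}]": m for (s, r), m in self.chp_masks.items()}
        )
        members["ventricles"] = self.ventricle_mask
        return members


@dataclass
class ValidationReport:
    """Outcome of a common-space check; carries every mismatch found."""

    passed: bool
    mismatches: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def read_volume(path: str | Path) -> VolumeImage:
    """Read a 3D NIfTI volume.

    Trailing singleton axes are squeezed (a 181x217x181x1 file is accepted as
    3D); a genuine 4D file raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"expected 3D volume in {path.name}, got shape {data.shape}"
        )
    return VolumeImage(data=np.asarray(data, dtype=np.float64), affine=img.affine)


def binarize(v: VolumeImage, threshold: float) -> BinaryMask:
    """Threshold a volume into a mask: voxel is 1 iff value > threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return BinaryMask(data=(v.data > threshold).astype(np.uint8), affine=v.affine)


def read_mask(path: str | Path, threshold: float = 0.5) -> BinaryMask:
    """Read a NIfTI mask; non-binary files are binarized at ``threshold``.

    Interpolated masks are common after resampling, so non-{0,1} values are
    accepted with a warning rather than rejected.
    """
    v = read_volume(path)
    uniq = np.unique(v.data)
    if not np.all(np.isin(uniq, (0, 1))):
        warnings.warn(
            f"{Path(path).name}: non-binary mask values; binarizing at > {threshold}",
            stacklevel=2,
        )
    return binarize(v, threshold)


def write_volume(v: VolumeImage, path: str | Path) -> None:
    """Write a volume as NIfTI-1. Masks round-trip bit-exactly (uint8)."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    if isinstance(v, BinaryMask):
        data = v.data.astype(np.uint8)
    else:
        data = np.asarray(v.data, dtype=np.float64)
    nib.save(nib.Nifti1Image(data, v.affine), str(path))


def check_same_geometry(
    a: VolumeImage, b: VolumeImage, tol: float = AFFINE_TOL, what: str = "volumes"
) -> None:
    """Raise ValueError if two volumes do not share shape and affine."""
    if a.shape != b.shape:
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
    if not np.allclose(a.affine, b.affine, rtol=0.0, atol=tol):
        raise ValueError(f"{what}: affine mismatch beyond tol {tol}")


def validate_common_space(
    bundle: SubjectBundle, tol: float = AFFINE_TOL
) -> ValidationReport:
    """Check that every member of a bundle shares shape and affine.

    The ventricle mask is the reference member; the report names every
    mismatching member so a broken cohort is diagnosable in one pass.
    """
    members = bundle.all_members()
    if not members:
        raise ValueError("empty bundle")
    ref_name = "ventricles"
    ref = members[ref_name]
    mismatches: list[str] = []
    for name, vol in members.items():
        if name == ref_name:
            continue
        if vol.shape != ref.shape:
            mismatches.append(
                f"{name}: shape {vol.shape} != {ref.shape} ({ref_name})"
            )
        elif not np.allclose(vol.affine, ref.affine, rtol=0.0, atol=tol):
            mismatches.append(f"{name}: affine differs from {ref_name} beyond {tol}")
    return ValidationReport(passed=not mismatches, mismatches=mismatches)
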