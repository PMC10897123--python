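"""Template-space spatial variability: slice-error profiles and frequency maps.

The slice-error profile measures, for each slice i along a template axis,

    err_s(i) = 100 · (count_seg(i) − count_ref(i)) / count_ref_total

per subject s, then reports mean and SD over subjects.  The denominator is
the subject's total reference volume, not the per-slice count (which can be
zero), so the per-subject profile sums exactly to that subject's signed
ΔVol% — a conservation identity the tests assert.

The frequency map is the per-voxel fraction of subjects whose mask covers
the voxel: an empirical probability atlas.  Maps are neither thresholded nor
smoothed; differences between maps are plain voxel-wise subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image_io import BinaryMask, VolumeImage, check_same_geometry

__all__ = [
    "SliceErrorProfile",
    "FrequencyMap",
    "slice_error_profile",
    "frequency_map",
    "frequency_difference_map",
]


@dataclass
class SliceErrorProfile:
    """Per-slice signed volume error (% of reference volume) along one axis."""

    axis: str
    voxel_axis: int
    slice_world_mm: np.ndarray  # dominant world coordinate of slice centres
    mean_error_pct: np.ndarray
    sd_error_pct: np.ndarray
    n_subjects: int
    per_subject: np.ndarray  # (n_subjects, n_slices) signed errors

    def __len__(self) -> int:
        return self.slice_world_mm.size


@dataclass
class FrequencyMap:
    """Per-voxel probability of membership across a cohort of masks."""

    data: np.ndarray
    affine: np.ndarray
    n_subjects: int
    label: str = ""

    def as_volume(self) -> VolumeImage:
        return VolumeImage(data=self.data, affine=self.affine)


def _slice_world_coordinates(affine: np.ndarray, axis: int, n: int) -> np.ndarray:
    """World coordinate of slice centres along a voxel axis.

    Reports the dominant world component of the axis direction (for an RAS
    grid with the axial axis on voxel axis 2 this is the z coordinate).
    """
    direction = affine[:3, axis]
    world_row = int(np.argmax(np.abs(direction)))
    idx = np.arange(n, dtype=float)
    return affine[world_row, axis] * idx + affine[world_row, 3]


def slice_error_profile(
    seg_masks: Sequence[BinaryMask],
    ref_masks: Sequence[BinaryMask],
    voxel_axis: int,
    axis_name: str = "",
) -> SliceErrorProfile:
    if len(seg_masks) != len(ref_masks) or not seg_masks:
        raise ValueError("need equally many (>=1) seg and ref masks")
    if voxel_axis not in (0, 1, 2):
        raise ValueError("voxel_axis must be 0, 1 or 2")
    template = ref_masks[0]
    n_slices = template.shape[voxel_axis]
    sum_axes = tuple(a for a in range(3) if a != voxel_axis)
    errors = np.empty((len(seg_masks), n_slices), dtype=float)
    for s, (seg, ref) in enumerate(zip(seg_masks, ref_masks)):
        check_same_geometry(seg, template, what=f"seg[{s}] vs template")
        check_same_geometry(ref, template, what=f"ref[{s}] vs template")
        ref_total = int(ref.data.sum())
        if ref_total == 0:
            raise ValueError(f"empty reference mask for subject index {s}")
        seg_counts = seg.data.sum(axis=sum_axes, dtype=np.int64)
        ref_counts = ref.data.sum(axis=sum_axes, dtype=np.int64)
        errors[s] = 100.0 * (seg_counts - ref_counts) / ref_total
    return SliceErrorProfile(
        axis=axis_name or f"voxel-axis-{voxel_axis}",
        voxel_axis=voxel_axis,
        slice_world_mm=_slice_world_coordinates(template.affine, voxel_axis, n_slices),
        mean_error_pct=errors.mean(axis=0),
        sd_error_pct=errors.std(axis=0, ddof=1) if len(seg_masks) > 1
        else np.zeros(n_slices),
        n_subjects=len(seg_masks),
        per_subject=errors,
    )


def frequency_map(masks: Sequence[BinaryMask], label: str = "") -> FrequencyMap:
    """Voxel value = (# subjects whose mask is 1 there) / n_subjects."""
    if not masks:
        raise ValueError("need at least one mask")
    template = masks[0]
    counts = np.zeros(template.shape, dtype=np.int64)
    for s, m in enumerate(masks):
        check_same_geometry(m, template, what=f"mask[{s}] vs template")
        counts += m.data
    return FrequencyMap(
        data=counts / float(len(masks)),
        affine=template.affine.copy(),
        n_subjects=len(masks),
        label=label,
    )


def frequency_difference_map(seq_map: FrequencyMap, ref_map: FrequencyMap) -> FrequencyMap:
    """freq(sequence) − freq(reference), voxel-wise, values in [−1, 1]."""
    if seq_map.n_subjects != ref_map.n_subjects:
        raise ValueError(
            "frequency maps built from different cohort sizes: "
            f"{seq_map.n_subjects} vs {ref_map.n_subjects}"
        )
    if seq_map.data.shape != ref_map.data.shape or not np.allclose(
        seq_map.affine, ref_map.affine, rtol=0.0, atol=1e-4
    ):
        raise ValueError("frequency maps do not share a grid")
    return FrequencyMap(
        data=seq_map.data - ref_map.data,
        affine=seq_map.affine.copy(),
        n_subjects=seq_map.n_subjects,
        label=f"{seq_map.label}-minus-{ref_map.label}",
    )
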