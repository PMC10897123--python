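"""SNR and CNR between a ChP ROI and the ventricular background.

Definitions (both dimensionless):

    SNR = mean(intensity | ROI) / sd(intensity | background)
    CNR = (mean(intensity | ROI) - mean(intensity | background)) / sd(...)

The SD is the sample SD (n-1 denominator): the background is treated as a
sample of the noise process.  The population form is available via ``ddof=0``
for exact replication attempts.  Intensities are used raw; both metrics are
ratio-scaled, so any global positive scaling cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import BinaryMask, VolumeImage, check_same_geometry

__all__ = ["ContrastResult", "snr", "cnr", "contrast_result"]


@dataclass(frozen=True)
class ContrastResult:
    subject_id: str
    sequence: str
    snr: float
    cnr: float
    roi_n: int
    background_n: int


def _roi_background_values(
    intensity: VolumeImage, roi: BinaryMask, background: BinaryMask
) -> tuple[np.ndarray, np.ndarray]:
    check_same_geometry(intensity, roi, what="intensity vs roi")
    check_same_geometry(intensity, background, what="intensity vs background")
    roi_vals = intensity.data[roi.data.astype(bool)]
    bg_vals = intensity.data[background.data.astype(bool)]
    if roi_vals.size < 1:
        raise ValueError("empty ROI")
    if bg_vals.size < 2:
        raise ValueError("background needs >= 2 voxels for an SD")
    return roi_vals, bg_vals


def _background_sd(bg_vals: np.ndarray, ddof: int) -> float:
    sd = float(np.std(bg_vals, ddof=ddof))
    if sd == 0.0:
        raise ValueError("zero background SD (constant region)")
    return sd


def snr(
    intensity: VolumeImage, roi: BinaryMask, background: BinaryMask, ddof: int = 1
) -> float:
    """mean(ROI) / sd(background)."""
    roi_vals, bg_vals = _roi_background_values(intensity, roi, background)
    return float(np.mean(roi_vals)) / _background_sd(bg_vals, ddof)


def cnr(
    intensity: VolumeImage, roi: BinaryMask, background: BinaryMask, ddof: int = 1
) -> float:
    """(mean(ROI) - mean(background)) / sd(background). May be negative."""
    roi_vals, bg_vals = _roi_background_values(intensity, roi, background)
    return (float(np.mean(roi_vals)) - float(np.mean(bg_vals))) / _background_sd(
        bg_vals, ddof
    )


def contrast_result(
    subject_id: str,
    sequence: str,
    intensity: VolumeImage,
    roi: BinaryMask,
    background: BinaryMask,
    ddof: int = 1,
) -> ContrastResult:
    """Both metrics in one pass over the voxel values."""
    roi_vals, bg_vals = _roi_background_values(intensity, roi, background)
    sd = _background_sd(bg_vals, ddof)
    roi_mean = float(np.mean(roi_vals))
    bg_mean = float(np.mean(bg_vals))
    return ContrastResult(
        subject_id=subject_id,
        sequence=sequence,
        snr=roi_mean / sd,
        cnr=(roi_mean - bg_mean) / sd,
        roi_n=int(roi_vals.size),
        background_n=int(bg_vals.size),
    )
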