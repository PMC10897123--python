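"""Overlap and volume agreement metrics: Dice, volumes, ΔVol%, Pearson, ICC.

Per-pair metrics operate on binary masks sharing one voxel grid; cohort
metrics (Pearson correlation of volumes, inter-rater ICC) operate on
per-subject absolute volumes in mL.

The ICC is the two-way random-effects, absolute-agreement, single-measure
form — Shrout & Fleiss ICC(2,1) — computed from the two-way ANOVA mean
squares:

    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

with n subjects (rows), k raters (columns), MS_R/MS_C/MS_E the row, column
and residual mean squares.  The consistency form ICC(3,1) is available as a
variant; the variant used is always recorded in output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .image_io import BinaryMask, check_same_geometry

__all__ = [
    "OverlapResult",
    "dice",
    "volume_ml",
    "percent_volume_difference",
    "abs_percent_volume_difference",
    "overlap_result",
    "pearson_volume_correlation",
    "icc_absolute_volume",
]


@dataclass(frozen=True)
class OverlapResult:
    subject_id: str
    seg_label: str
    ref_label: str
    dsc: float
    vol_seg_ml: float
    vol_ref_ml: float
    dvol_pct: float
    abs_dvol_pct: float


def dice(seg: BinaryMask, ref: BinaryMask) -> float:
    """Dice similarity coefficient 2·TP / (2·TP + FP + FN), symmetric.

    Two empty masks raise: that configuration signals broken upstream masks,
    never a real measurement.
    """
    check_same_geometry(seg, ref, what="seg vs ref")
    a = seg.data.astype(bool)
    b = ref.data.astype(bool)
    tp = int(np.count_nonzero(a & b))
    fp = int(np.count_nonzero(a & ~b))
    fn = int(np.count_nonzero(~a & b))
    denom = 2 * tp + fp + fn
    if denom == 0:
        raise ValueError("Dice undefined: both masks are empty")
    return 2.0 * tp / denom


def volume_ml(mask: BinaryMask) -> float:
    """voxel_count x voxel volume, mm^3 -> mL."""
    return mask.voxel_count * mask.voxel_volume_mm3 / 1000.0


def percent_volume_difference(seg: BinaryMask, ref: BinaryMask) -> float:
    """Signed 100·(V_seg − V_ref)/V_ref; positive means overestimation."""
    check_same_geometry(seg, ref, what="seg vs ref")
    v_ref = volume_ml(ref)
    if v_ref == 0.0:
        raise ValueError("percentage volume difference undefined for empty reference")
    return 100.0 * (volume_ml(seg) - v_ref) / v_ref


def abs_percent_volume_difference(seg: BinaryMask, ref: BinaryMask) -> float:
    return abs(percent_volume_difference(seg, ref))


def overlap_result(
    subject_id: str, seg_label: str, ref_label: str, seg: BinaryMask, ref: BinaryMask
) -> OverlapResult:
    dvol = percent_volume_difference(seg, ref)
    return OverlapResult(
        subject_id=subject_id,
        seg_label=seg_label,
        ref_label=ref_label,
        dsc=dice(seg, ref),
        vol_seg_ml=volume_ml(seg),
        vol_ref_ml=volume_ml(ref),
        dvol_pct=dvol,
        abs_dvol_pct=abs(dvol),
    )


def pearson_volume_correlation(vols_a, vols_b) -> float:
    """Product-moment correlation of per-subject volumes (one point each)."""
    a = np.asarray(vols_a, dtype=float)
    b = np.asarray(vols_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("volume vectors must be 1D and of equal length")
    if a.size < 3:
        raise ValueError("need >= 3 subjects for a correlation")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("zero variance in a volume vector")
    return float(sps.pearsonr(a, b).statistic)


def _two_way_mean_squares(m: np.ndarray) -> tuple[float, float, float]:
    n, k = m.shape
    grand = m.mean()
    ss_rows = k * float(((m.mean(axis=1) - grand) ** 2).sum())
    ss_cols = n * float(((m.mean(axis=0) - grand) ** 2).sum())
    ss_tot = float(((m - grand) ** 2).sum())
    ss_err = ss_tot - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_absolute_volume(ratings, variant: str = "icc2") -> float:
    """Intraclass correlation of an n_subjects x n_raters volume matrix.

    ``variant``: ``"icc2"`` (absolute agreement, default) or ``"icc3"``
    (consistency).  An all-identical matrix returns 1.0 with a warning — the
    raters agree perfectly, but the data carry no subject variance to attest
    it.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("ratings must be an n>=2 x k>=2 matrix")
    if np.isnan(m).any():
        raise ValueError("ratings matrix has missing cells")
    if variant not in ("icc2", "icc3"):
        raise ValueError(f"unknown ICC variant {variant!r}")
    if np.ptp(m) == 0.0:
        warnings.warn(
            "degenerate ratings matrix (all values identical); ICC defined as 1",
            stacklevel=2,
        )
        return 1.0
    n, k = m.shape
    ms_r, ms_c, ms_e = _two_way_mean_squares(m)
    if variant == "icc3":
        return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)
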