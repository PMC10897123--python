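"""Phantom cohorts with known ground truth for every pipeline stage.

The phantom emulates the anatomy the pipeline measures at desk scale: two
ellipsoidal ventricle-like compartments, each containing a thin curved
choroid-plexus-like tube, on a 1 mm isotropic grid.  Per sequence, the
intensity model is piecewise constant (``chp_mean`` inside the true plexus,
``background_mean`` in the rest of the ventricle, zero outside) plus
stationary Gaussian noise — the contrast metrics involve only first and
second moments, so this is exactly the regime in which their targets
(SNR = chp_mean/noise_sd, CNR = (chp_mean − background_mean)/noise_sd) are
known in closed form.

Segmentation imperfection is modelled by :func:`perturb_mask`: a controlled
signed volume bias implemented as physical-distance growth or shrinkage of
the truth surface (boundary blur is a distance effect, which is why a
FLAIR-like sequence overestimates), followed by symmetric random boundary
flips that degrade Dice without moving the expected volume.  Default
sequence parameters reproduce the contrast and bias regime of routine
T1w / FLAIR / CE-T1w imaging of the plexus: CE-T1w-like contrast highest and
unbiased, FLAIR-like volume inflated by ~+28%, T1w-like nearly unbiased.

All randomness flows from a single integer seed; each subject draws from a
fixed substream, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import BinaryMask, SubjectBundle, VolumeImage, write_volume

__all__ = [
    "SequenceModel",
    "PhantomSpec",
    "Cohort",
    "perturb_mask",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
    "DEFAULT_SEQUENCES",
]


@dataclass(frozen=True)
class SequenceModel:
    """Intensity and mask-perturbation model for one MRI sequence analogue."""

    chp_mean: float
    background_mean: float
    noise_sd: float
    bias_percent: float  # signed target ΔVol% of the drawn mask vs truth
    boundary_noise: float  # flip probability on the mask boundary shell

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.boundary_noise < 0 or self.boundary_noise > 1:
            raise ValueError("boundary_noise must be in [0, 1]")


# Contrast targets follow reported in-vivo values for plexus vs ventricular
# CSF (SNR 13.73 / 13.09 / 23.77 and CNR 7.44 / 10.77 / 18.49 for
# T1w / FLAIR / CE-T1w), realised here with a common noise SD of 25.
# FLAIR-like masks carry the ~+28% systematic inflation seen in vivo;
# the CE-T1w-like reference is unbiased.  Boundary-noise values are set so
# that drawn masks sit in the reported disagreement regime (DSC vs the
# CE-like mask in the high 0.6s).
DEFAULT_SEQUENCES: dict[str, SequenceModel] = {
    "T1w": SequenceModel(343.25, 157.25, 25.0, 3.52, 0.39),
    "FLAIR": SequenceModel(327.25, 58.0, 25.0, 28.02, 0.28),
    "CE-T1w": SequenceModel(594.25, 132.0, 25.0, 0.0, 0.10),
}

#: extra boundary-flip probability per rater; the primary rater R1 is the
#: sequence mask itself.
DEFAULT_RATERS: dict[str, float] = {"R1": 0.0, "R2": 0.12}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity, and perturbation parameters of a phantom cohort."""

    n_subjects: int = 30
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # two lateral-ventricle-like ellipsoids, centres in mm relative to the
    # grid centre, radii in mm
    ventricle_centers_mm: tuple[tuple[float, float, float], ...] = (
        (-16.0, 0.0, 0.0),
        (16.0, 0.0, 0.0),
    )
    ventricle_radii_mm: tuple[float, float, float] = (11.0, 26.0, 13.0)
    ventricle_jitter_sd_mm: float = 1.0
    # thin curved plexus-like tube inside each ventricle
    chp_thickness_mm: float = 2.9
    chp_length_frac: float = 0.75  # fraction of the ventricle y-radius spanned
    chp_jitter_sd_mm: float = 0.5
    sequences: Mapping[str, SequenceModel] = field(
        default_factory=lambda: dict(DEFAULT_SEQUENCES)
    )
    raters: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RATERS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(n < 4 for n in self.grid_shape):
            raise ValueError("grid too small")
        mm = (
            list(self.voxel_size)
            + list(self.ventricle_radii_mm)
            + [self.chp_thickness_mm]
        )
        if any(v <= 0 for v in mm):
            raise ValueError("all mm parameters must be > 0")
        if self.ventricle_jitter_sd_mm < 0 or self.chp_jitter_sd_mm < 0:
            raise ValueError("jitter SDs must be >= 0")
        if not self.sequences:
            raise ValueError("at least one sequence model required")

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        # centre the world origin on the grid centre
        aff[:3, 3] = -(np.array(self.grid_shape) - 1) / 2.0 * np.array(self.voxel_size)
        return aff


@dataclass
class Cohort:
    """Generated bundles plus the ground truth needed for recovery tests."""

    subjects: list[SubjectBundle]
    truth_chp: dict[str, BinaryMask]
    params: pd.DataFrame  # one row per subject x sequence with targets
    spec: PhantomSpec


def _stochastic_round(x: float, rng: np.random.Generator) -> int:
    lo = int(np.floor(x))
    return lo + int(rng.random() < (x - lo))


_SHELL_STRUCT = np.ones((3, 3, 3), dtype=bool)


def perturb_mask(
    truth: BinaryMask,
    container: BinaryMask,
    target_bias_percent: float,
    boundary_noise: float,
    seed: int | np.random.Generator,
) -> BinaryMask:
    """Draw an imperfect segmentation of ``truth`` inside ``container``.

    The signed volume bias is applied first: the target voxel delta
    (stochastically rounded so its expectation is exact) is added by turning
    on the container voxels nearest to the truth surface in physical mm, or
    removed by turning off the shallowest truth voxels — growth and shrinkage
    are distance-ordered, mimicking boundary blur.  Boundary noise then flips
    ``Binomial(n0, p)`` outer-shell voxels on and, independently,
    ``Binomial(n0, p)`` inner-shell voxels off, with ``n0`` the smaller shell
    size, so the expected net volume change of the noise stage is zero while
    overlap with the truth strictly degrades.

    Deterministic given the seed.  The result is always a subset of
    ``container``.
    """
    if target_bias_percent <= -100.0:
        raise ValueError(
            "target bias <= -100% would remove the entire structure"
        )
    if not (0.0 <= boundary_noise <= 1.0):
        raise ValueError("boundary_noise must be in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t = truth.data.astype(bool)
    c = container.data.astype(bool)
    if np.any(t & ~c):
        raise ValueError("truth must be a subset of the container")
    n_true = int(t.sum())
    if n_true == 0:
        raise ValueError("empty truth mask")
    vs = truth.voxel_size

    delta = _stochastic_round(n_true * target_bias_percent / 100.0, rng)
    mask = t.copy()
    if delta > 0:
        dist_out = ndimage.distance_transform_edt(~t, sampling=vs)
        cand = np.argwhere(c & ~t)
        if len(cand) < delta:
            raise ValueError(
                f"unreachable bias: container offers {len(cand)} voxels, "
                f"need {delta}"
            )
        d = dist_out[tuple(cand.T)]
        order = np.lexsort((rng.random(len(cand)), d))
        mask[tuple(cand[order[:delta]].T)] = True
    elif delta < 0:
        n_del = -delta
        if n_del >= n_true:
            raise ValueError("unreachable bias: would empty the structure")
        dist_in = ndimage.distance_transform_edt(t, sampling=vs)
        cand = np.argwhere(t)
        d = dist_in[tuple(cand.T)]
        order = np.lexsort((rng.random(len(cand)), d))
        mask[tuple(cand[order[:n_del]].T)] = False

    if boundary_noise > 0.0 and mask.any():
        outer = ndimage.binary_dilation(mask, _SHELL_STRUCT) & ~mask & c
        inner = mask & ~ndimage.binary_erosion(
            mask, _SHELL_STRUCT, border_value=0
        )
        oc = np.argwhere(outer)
        ic = np.argwhere(inner)
        n0 = min(len(oc), len(ic))
        if n0 > 0:
            m_add = int(rng.binomial(n0, boundary_noise))
            m_rem = int(rng.binomial(n0, boundary_noise))
            if m_add:
                mask[tuple(oc[rng.choice(len(oc), m_add, replace=False)].T)] = True
            if m_rem:
                mask[tuple(ic[rng.choice(len(ic), m_rem, replace=False)].T)] = False

    return BinaryMask(data=mask.astype(np.uint8), affine=truth.affine)


def _world_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    aff = spec.affine()
    coords = [
        aff[i, i] * np.arange(spec.grid_shape[i]) + aff[i, 3] for i in range(3)
    ]
    return np.meshgrid(*coords, indexing="ij")  # type: ignore[return-value]


def _subject_geometry(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[BinaryMask, BinaryMask]:
    """One subject's ventricle and true ChP masks, with inter-subject jitter."""
    aff = spec.affine()
    X, Y, Z = _world_grids(spec)
    vent = np.zeros(spec.grid_shape, dtype=bool)
    curve = np.zeros(spec.grid_shape, dtype=bool)
    inv3 = np.linalg.inv(aff[:3, :3])
    for base_centre in spec.ventricle_centers_mm:
        centre = np.array(base_centre) + rng.normal(
            0.0, spec.ventricle_jitter_sd_mm, 3
        )
        radii = np.array(spec.ventricle_radii_mm) + rng.normal(
            0.0, spec.ventricle_jitter_sd_mm / 2.0, 3
        )
        radii = np.maximum(radii, 3.0)
        q = (
            ((X - centre[0]) / radii[0]) ** 2
            + ((Y - centre[1]) / radii[1]) ** 2
            + ((Z - centre[2]) / radii[2]) ** 2
        )
        vent |= q <= 1.0
        # plexus centreline: a gentle arc through the ellipsoid, parametrised
        # in the ellipsoid's scaled coordinates so it stays well inside
        t = np.linspace(0.0, 1.0, 256)
        u = 0.30 * np.sin(np.pi * t) + rng.normal(0, spec.chp_jitter_sd_mm / 10.0)
        v = spec.chp_length_frac * (2.0 * t - 1.0)
        w = 0.25 * np.cos(np.pi * t) + rng.normal(0, spec.chp_jitter_sd_mm / 10.0)
        pts = np.stack(
            [
                centre[0] + u * radii[0],
                centre[1] + v * radii[1],
                centre[2] + w * radii[2],
            ],
            axis=1,
        )
        ijk = np.rint(inv3 @ (pts - aff[:3, 3]).T).astype(int).T
        ok = np.all((ijk >= 0) & (ijk < np.array(spec.grid_shape)), axis=1)
        curve[tuple(ijk[ok].T)] = True
        # interior margin: keep the tube away from the ventricle wall so the
        # truth is a strict subset with room for dilation-type bias
    if not curve.any():
        raise ValueError("ChP centreline left the grid: grid too coarse")
    dist_curve = ndimage.distance_transform_edt(~curve, sampling=spec.voxel_size)
    tube = dist_curve <= spec.chp_thickness_mm
    interior = ndimage.binary_erosion(
        vent, _SHELL_STRUCT, iterations=2, border_value=0
    )
    chp = tube & interior
    if not chp.any():
        raise ValueError("empty ChP truth region: grid too coarse for geometry")
    if np.any(chp & ~vent) or chp.sum() >= vent.sum():
        raise ValueError("ChP truth is not a strict subset of the ventricles")
    return (
        BinaryMask(data=vent.astype(np.uint8), affine=aff),
        BinaryMask(data=chp.astype(np.uint8), affine=aff),
    )


def generate_subject(
    spec: PhantomSpec, index: int
) -> tuple[SubjectBundle, BinaryMask]:
    """Generate one subject (bundle + truth mask) from its fixed substream."""
    rng = np.random.default_rng([spec.seed, index])
    subject_id = f"sub-{index + 1:03d}"
    vent, chp_truth = _subject_geometry(spec, rng)
    aff = spec.affine()

    intensities: dict[str, VolumeImage] = {}
    chp_masks: dict[tuple[str, str], BinaryMask] = {}
    for seq_name in sorted(spec.sequences):
        model = spec.sequences[seq_name]
        vol = np.zeros(spec.grid_shape, dtype=np.float64)
        vol[vent.data.astype(bool)] = model.background_mean
        vol[chp_truth.data.astype(bool)] = model.chp_mean
        vol += rng.normal(0.0, model.noise_sd, spec.grid_shape)
        intensities[seq_name] = VolumeImage(data=vol, affine=aff)
        # hierarchical rater model: the sequence's appearance (contrast,
        # blur) drives a shared consensus mask; raters deviate from that
        # consensus by small independent boundary flips, so inter-rater
        # Dice stays high while every rater carries the sequence bias
        seq_mask = perturb_mask(
            chp_truth, vent, model.bias_percent, model.boundary_noise, rng
        )
        for rater in sorted(spec.raters):
            extra = spec.raters[rater]
            if extra <= 0.0:
                chp_masks[(seq_name, rater)] = seq_mask
            else:
                chp_masks[(seq_name, rater)] = perturb_mask(
                    seq_mask, vent, 0.0, extra, rng
                )
    bundle = SubjectBundle(
        subject_id=subject_id,
        intensities=intensities,
        chp_masks=chp_masks,
        ventricle_mask=vent,
    )
    return bundle, chp_truth


def generate_cohort(spec: PhantomSpec) -> Cohort:
    """Deterministically generate ``spec.n_subjects`` bundles plus truth."""
    subjects: list[SubjectBundle] = []
    truth: dict[str, BinaryMask] = {}
    rows = []
    for i in range(spec.n_subjects):
        bundle, chp_truth = generate_subject(spec, i)
        subjects.append(bundle)
        truth[bundle.subject_id] = chp_truth
        for seq_name, model in spec.sequences.items():
            rows.append(
                {
                    "subject_id": bundle.subject_id,
                    "sequence": seq_name,
                    "target_bias_percent": model.bias_percent,
                    "target_snr": model.chp_mean / model.noise_sd,
                    "target_cnr": (model.chp_mean - model.background_mean)
                    / model.noise_sd,
                    "truth_voxels": chp_truth.voxel_count,
                }
            )
    return Cohort(
        subjects=subjects,
        truth_chp=truth,
        params=pd.DataFrame(rows),
        spec=spec,
    )


def write_cohort(cohort: Cohort, root: str | Path) -> Path:
    """Write a cohort as one directory per subject plus a ground-truth table.

    Layout: ``<root>/<subject>/<sequence>.nii.gz``,
    ``<sequence>_chp_<rater>.nii.gz``, ``ventricles.nii.gz``,
    ``truth_chp.nii.gz``; targets in ``<root>/ground_truth.tsv``.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for bundle in cohort.subjects:
        sdir = root / bundle.subject_id
        sdir.mkdir(exist_ok=True)
        for seq, vol in bundle.intensities.items():
            write_volume(vol, sdir / f"{seq}.nii.gz")
        for (seq, rater), m in bundle.chp_masks.items():
            write_volume(m, sdir / f"{seq}_chp_{rater}.nii.gz")
        write_volume(bundle.ventricle_mask, sdir / "ventricles.nii.gz")
        write_volume(cohort.truth_chp[bundle.subject_id], sdir / "truth_chp.nii.gz")
    cohort.params.to_csv(root / "ground_truth.tsv", sep="\t", index=False)
    return root


def scaled_spec(spec: PhantomSpec, factor: float) -> PhantomSpec:
    """A geometrically shrunken variant of a spec (for quick tests)."""
    return replace(
        spec,
        grid_shape=tuple(max(8, int(n * factor)) for n in spec.grid_shape),
        ventricle_centers_mm=tuple(
            tuple(c * factor for c in cc) for cc in spec.ventricle_centers_mm
        ),
        ventricle_radii_mm=tuple(r * factor for r in spec.ventricle_radii_mm),
    )
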