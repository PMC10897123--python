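"""Cohort-level orchestration: from a directory tree to tables, maps, a log.

Expected cohort layout (one directory per subject)::

    <root>/<subject>/<sequence>.nii.gz           intensity volume
    <root>/<subject>/<sequence>_chp_<rater>.nii.gz  ChP mask
    <root>/<subject>/ventricles.nii.gz           lateral-ventricle mask

The run is deterministic given the configuration and cohort: subjects,
sequences and raters are iterated in sorted order and tables are written
with a fixed float format, so two runs produce byte-identical outputs.
Per-subject failures (missing files, geometry mismatches) are logged and
the subject is skipped; the report records them so a caller can exit
non-zero.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import (
    dice,
    icc_absolute_volume,
    overlap_result,
    pearson_volume_correlation,
    volume_ml,
)
from .background import build_background_roi
from .contrast import contrast_result
from .image_io import (
    BinaryMask,
    SubjectBundle,
    read_mask,
    read_volume,
    validate_common_space,
    write_volume,
)
from .spatial import frequency_difference_map, frequency_map, slice_error_profile
from .stats import one_way_anova, posthoc_pairwise_t, t_test

__all__ = ["RunConfig", "RunReport", "load_subject", "run_pipeline"]

_FLOAT_FMT = "%.17g"


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    cohort_root: str
    output_dir: str
    sequences: tuple[str, ...] = ("CE-T1w", "FLAIR", "T1w")
    reference: str = "CE-T1w"
    raters: tuple[str, ...] = ("R1", "R2")
    primary_rater: str = "R1"
    erosion_radius_mm: float = 2.0
    # voxel axis carrying each anatomical direction (template-resampled data)
    axial_axis: int = 2
    coronal_axis: int = 1
    icc_variant: str = "icc2"
    equal_var: bool = True
    paired: bool = False
    bonferroni: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.sequences = tuple(self.sequences)
        self.raters = tuple(self.raters)
        if self.reference not in self.sequences:
            raise ValueError(
                f"reference {self.reference!r} not among sequences {self.sequences}"
            )
        if self.primary_rater not in self.raters:
            raise ValueError("primary_rater must be among raters")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analysis settings (paths excluded, so the same
        analysis run into two directories reports the same hash)."""
        payload = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("cohort_root", "output_dir")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    output_dir: Path
    n_subjects: int
    skipped: list[str] = field(default_factory=list)
    tables: dict[str, Path] = field(default_factory=dict)
    log_lines: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.skipped and self.n_subjects > 0


def load_subject(subject_dir: Path, config: RunConfig) -> SubjectBundle:
    """Read one subject's bundle; raises on missing members."""

    def find(stem: str) -> Path:
        for ext in (".nii.gz", ".nii"):
            p = subject_dir / f"{stem}{ext}"
            if p.exists():
                return p
        raise FileNotFoundError(f"{subject_dir.name}: missing {stem}.nii[.gz]")

    intensities = {s: read_volume(find(s)) for s in sorted(config.sequences)}
    chp_masks = {
        (s, r): read_mask(find(f"{s}_chp_{r}"))
        for s in sorted(config.sequences)
        for r in sorted(config.raters)
    }
    ventricles = read_mask(find("ventricles"))
    bundle = SubjectBundle(
        subject_id=subject_dir.name,
        intensities=intensities,
        chp_masks=chp_masks,
        ventricle_mask=ventricles,
    )
    report = validate_common_space(bundle)
    if not report:
        raise ValueError(
            f"{subject_dir.name}: common-space violation: "
            + "; ".join(report.mismatches)
        )
    return bundle


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every analysis stage over the cohort and write all outputs."""
    root = Path(config.cohort_root)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(output_dir=out, n_subjects=0)
    log = report.log_lines
    log.append(f"chpmetrics {__version__} | config hash {config.config_hash()}")
    log.append(
        "libs: "
        + ", ".join(
            f"{m}={v}"
            for m, v in (
                ("numpy", np.__version__),
                ("pandas", pd.__version__),
            )
        )
    )
    for k, v in sorted(asdict(config).items()):
        log.append(f"config {k} = {v}")

    subject_dirs = sorted(
        d for d in root.iterdir() if d.is_dir() and not d.name.startswith(".")
    )
    bundles: list[SubjectBundle] = []
    for sdir in subject_dirs:
        try:
            bundles.append(load_subject(sdir, config))
        except (FileNotFoundError, ValueError) as exc:
            report.skipped.append(sdir.name)
            log.append(f"SKIP {sdir.name}: {exc}")
    report.n_subjects = len(bundles)
    if not bundles:
        log.append("no usable subjects")
        _finish(report, config)
        return report

    ref = config.reference
    pr = config.primary_rater
    non_ref = [s for s in config.sequences if s != ref]

    # --- contrast: shared background ROI per subject, own-mask ROI ---------
    contrast_rows = []
    for b in bundles:
        background = build_background_roi(
            b.ventricle_mask,
            [b.mask(s, pr) for s in sorted(config.sequences)],
            config.erosion_radius_mm,
        )
        for s in sorted(config.sequences):
            contrast_rows.append(
                asdict_flat(
                    contrast_result(
                        b.subject_id, s, b.intensities[s], b.mask(s, pr), background
                    )
                )
            )
    contrast_df = pd.DataFrame(contrast_rows)
    report.tables["contrast"] = _write_tsv(contrast_df, out / "contrast.tsv")

    # --- overlap/volume vs the reference sequence --------------------------
    overlap_rows = [
        asdict_flat(
            overlap_result(b.subject_id, s, ref, b.mask(s, pr), b.mask(ref, pr))
        )
        for b in bundles
        for s in non_ref
    ]
    overlap_df = pd.DataFrame(overlap_rows)
    report.tables["overlap"] = _write_tsv(overlap_df, out / "overlap.tsv")

    # --- inter-rater agreement --------------------------------------------
    rater_rows = []
    if len(config.raters) >= 2:
        r_sorted = sorted(config.raters)
        for b in bundles:
            for s in sorted(config.sequences):
                for i in range(len(r_sorted)):
                    for j in range(i + 1, len(r_sorted)):
                        ri, rj = r_sorted[i], r_sorted[j]
                        rater_rows.append(
                            {
                                "subject_id": b.subject_id,
                                "sequence": s,
                                "rater_a": ri,
                                "rater_b": rj,
                                "dsc": dice(b.mask(s, ri), b.mask(s, rj)),
                                "vol_a_ml": volume_ml(b.mask(s, ri)),
                                "vol_b_ml": volume_ml(b.mask(s, rj)),
                            }
                        )
    interrater_df = pd.DataFrame(rater_rows)
    if not interrater_df.empty:
        report.tables["interrater"] = _write_tsv(
            interrater_df, out / "interrater.tsv"
        )

    # --- cohort summary -----------------------------------------------------
    summary_rows = []
    vols = {
        s: np.array([volume_ml(b.mask(s, pr)) for b in bundles])
        for s in sorted(config.sequences)
    }
    for s in sorted(config.sequences):
        sub = contrast_df[contrast_df["sequence"] == s]
        row: dict[str, object] = {
            "sequence": s,
            "n": len(bundles),
            "snr_mean": sub["snr"].mean(),
            "snr_sd": sub["snr"].std(ddof=1),
            "cnr_mean": sub["cnr"].mean(),
            "cnr_sd": sub["cnr"].std(ddof=1),
            "vol_ml_mean": vols[s].mean(),
            "vol_ml_sd": vols[s].std(ddof=1) if len(bundles) > 1 else np.nan,
        }
        if s != ref:
            osub = overlap_df[overlap_df["seg_label"] == s]
            row.update(
                dsc_mean=osub["dsc"].mean(),
                dsc_sd=osub["dsc"].std(ddof=1),
                dvol_pct_mean=osub["dvol_pct"].mean(),
                dvol_pct_sd=osub["dvol_pct"].std(ddof=1),
                abs_dvol_pct_mean=osub["abs_dvol_pct"].mean(),
                abs_dvol_pct_sd=osub["abs_dvol_pct"].std(ddof=1),
            )
            if len(bundles) >= 3 and np.std(vols[s]) > 0 and np.std(vols[ref]) > 0:
                row["pearson_r_vs_ref"] = pearson_volume_correlation(
                    vols[s], vols[ref]
                )
            else:
                row["pearson_r_vs_ref"] = np.nan
                log.append(f"summary: insufficient n for Pearson ({s})")
        if len(config.raters) >= 2 and len(bundles) >= 2:
            ratings = np.column_stack(
                [
                    [volume_ml(b.mask(s, r)) for b in bundles]
                    for r in sorted(config.raters)
                ]
            )
            row["icc"] = icc_absolute_volume(ratings, config.icc_variant)
            row["icc_variant"] = config.icc_variant
        else:
            row["icc"] = np.nan
            row["icc_variant"] = "insufficient n"
            log.append(f"summary: insufficient n for ICC ({s})")
        summary_rows.append(row)
    report.tables["summary"] = _write_tsv(
        pd.DataFrame(summary_rows), out / "summary.tsv"
    )

    # --- statistics ----------------------------------------------------------
    stats_rows = []
    seqs = sorted(config.sequences)

    def add(res) -> None:
        stats_rows.append(
            {
                "test": res.name,
                "groups": " vs ".join(res.groups),
                "statistic": res.statistic,
                "df": str(res.df),
                "p_value": res.p_value,
                "significant": res.significant,
                "alpha": res.alpha,
            }
        )

    def battery(values_by_seq: dict[str, np.ndarray], metric: str) -> None:
        groups = [values_by_seq[s] for s in seqs]
        labels = [f"{metric}[{s}]" for s in seqs]
        try:
            add(one_way_anova(groups, labels, config.alpha))
            for r in posthoc_pairwise_t(
                groups,
                labels,
                paired=config.paired,
                equal_var=config.equal_var,
                bonferroni=config.bonferroni,
                alpha=config.alpha,
            ):
                add(r)
        except ValueError as exc:
            log.append(f"stats: {metric}: {exc}")

    if len(bundles) >= 2:
        battery(
            {
                s: contrast_df[contrast_df["sequence"] == s]["snr"].to_numpy()
                for s in seqs
            },
            "SNR",
        )
        battery(
            {
                s: contrast_df[contrast_df["sequence"] == s]["cnr"].to_numpy()
                for s in seqs
            },
            "CNR",
        )
        battery(vols, "volume")
        if not interrater_df.empty:
            battery(
                {
                    s: interrater_df[interrater_df["sequence"] == s][
                        "dsc"
                    ].to_numpy()
                    for s in seqs
                },
                "inter-rater DSC",
            )
        for s in non_ref:
            dv = overlap_df[overlap_df["seg_label"] == s]["dvol_pct"].to_numpy()
            try:
                add(
                    t_test(
                        dv,
                        mode="one-sample",
                        mu0=0.0,
                        alpha=config.alpha,
                        labels=(f"dVol%[{s} vs {ref}]", "mu0=0"),
                    )
                )
            except ValueError as exc:
                log.append(f"stats: one-sample dVol% {s}: {exc}")
        for i in range(len(non_ref)):
            for j in range(i + 1, len(non_ref)):
                a, bseq = non_ref[i], non_ref[j]
                for col in ("dvol_pct", "abs_dvol_pct"):
                    va = overlap_df[overlap_df["seg_label"] == a][col].to_numpy()
                    vb = overlap_df[overlap_df["seg_label"] == bseq][col].to_numpy()
                    try:
                        add(
                            t_test(
                                va,
                                vb,
                                mode="paired" if config.paired else "two-sample",
                                equal_var=config.equal_var,
                                alpha=config.alpha,
                                labels=(f"{col}[{a}]", f"{col}[{bseq}]"),
                            )
                        )
                    except ValueError as exc:
                        log.append(f"stats: {col} {a} vs {bseq}: {exc}")
    else:
        log.append("stats: insufficient n, skipped")
    if stats_rows:
        report.tables["stats"] = _write_tsv(
            pd.DataFrame(stats_rows), out / "stats.tsv"
        )

    # --- spatial variability -------------------------------------------------
    same_grid = all(
        b.ventricle_mask.same_geometry_as(bundles[0].ventricle_mask)
        for b in bundles
    )
    if same_grid:
        ref_masks = [b.mask(ref, pr) for b in bundles]
        axis_map = {"axial-z": config.axial_axis, "coronal-y": config.coronal_axis}
        profile_rows = []
        for s in non_ref:
            seg_masks = [b.mask(s, pr) for b in bundles]
            for axis_name, vaxis in sorted(axis_map.items()):
                prof = slice_error_profile(seg_masks, ref_masks, vaxis, axis_name)
                for i in range(len(prof)):
                    profile_rows.append(
                        {
                            "sequence": s,
                            "axis": axis_name,
                            "slice_mm": prof.slice_world_mm[i],
                            "mean_error_pct": prof.mean_error_pct[i],
                            "sd_error_pct": prof.sd_error_pct[i],
                            "n": prof.n_subjects,
                        }
                    )
        report.tables["slice_profiles"] = _write_tsv(
            pd.DataFrame(profile_rows), out / "slice_profiles.tsv"
        )
        fmaps = {
            s: frequency_map([b.mask(s, pr) for b in bundles], label=s)
            for s in sorted(config.sequences)
        }
        for s, fm in sorted(fmaps.items()):
            write_volume(fm.as_volume(), out / f"freqmap_{s}.nii.gz")
        for s in non_ref:
            dmap = frequency_difference_map(fmaps[s], fmaps[ref])
            write_volume(dmap.as_volume(), out / f"freqdiff_{s}_minus_{ref}.nii.gz")
    else:
        log.append("spatial: subjects not on a shared grid; maps/profiles skipped")

    _finish(report, config)
    return report


def asdict_flat(obj) -> dict:
    from dataclasses import asdict as _asdict

    return _asdict(obj)


def _finish(report: RunReport, config: RunConfig) -> None:
    report.log_lines.append(
        f"done: {report.n_subjects} subjects, {len(report.skipped)} skipped"
    )
    with open(report.output_dir / "run_log.txt", "w") as fh:
        fh.write("\n".join(report.log_lines) + "\n")
    config.to_yaml(report.output_dir / "config_used.yaml")
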