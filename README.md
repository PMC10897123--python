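# chpmetrics

Quantitative comparison of choroid-plexus (ChP) segmentations across MRI
sequences and raters.

The choroid plexus — the CSF-producing vascular tissue in the brain's
lateral ventricles — is usually delineated on contrast-enhanced T1-weighted
MRI (CE-T1w), but gadolinium injection is not always possible or desirable.
Researchers therefore need to know how well segmentations drawn on
non-contrast sequences (T1w, FLAIR) agree with the CE-T1w standard, both in
contrast available to the rater and in the volumes and shapes produced.
`chpmetrics` packages that entire evaluation as a reusable pipeline for
co-registered NIfTI data, and ships a phantom generator with known ground
truth so every stage can be validated without patient data.

## What it computes

For each subject (all volumes on one grid, registration upstream):

- **Contrast** between the ChP region of interest and a ventricular
  background ROI. The background is the lateral-ventricle mask minus the
  union of all sequences' ChP masks, eroded with a spherical kernel of
  radius 2 mm (in physical mm, anisotropy-aware):

  SNR = mean(ROI) / sd(background),
  CNR = (mean(ROI) − mean(background)) / sd(background).

- **Overlap and volume agreement** of each sequence's mask against the
  reference sequence: Dice coefficient DSC = 2·TP / (2·TP + FP + FN),
  absolute volume in mL, signed and absolute percentage volume difference
  ΔVol% = 100·(V_seg − V_ref)/V_ref, cohort Pearson correlation of volumes,
  and inter-rater agreement (pairwise DSC and two-way random-effects
  absolute-agreement ICC(2,1) on absolute volumes).

- **Spatial variability** in template space: slice-wise error profiles
  100·(count_seg(i) − count_ref(i))/V_ref along the axial and coronal axes
  (per subject these sum exactly to ΔVol%), and voxel-wise frequency maps
  (the fraction of subjects whose mask covers each voxel) with difference
  maps against the reference sequence.

- **Statistics**: one-way ANOVA across sequences with uncorrected post hoc
  t-tests, one-sample t-tests of ΔVol% against zero, and two-sample t-tests
  between the non-contrast sequences, all two-tailed at α = 0.05.

## Worked example

```python
from chpmetrics import (PhantomSpec, generate_cohort, build_background_roi,
                        snr, cnr, dice, volume_ml, percent_volume_difference)

spec = PhantomSpec(n_subjects=5, seed=42)      # default phantom conditions
cohort = generate_cohort(spec)
b = cohort.subjects[0]
truth = cohort.truth_chp[b.subject_id]
bg = build_background_roi(b.ventricle_mask,
                          [b.mask(s, "R1") for s in sorted(spec.sequences)])
for s in ("T1w", "FLAIR", "CE-T1w"):
    m = b.mask(s, "R1")
    print(s, snr(b.intensities[s], m, bg), cnr(b.intensities[s], m, bg),
          volume_ml(m), dice(m, b.mask("CE-T1w", "R1")),
          percent_volume_difference(m, truth))
```

prints (formatted):

```
T1w     SNR= 11.54 CNR=  5.25 vol=2.263 mL DSC(vs CE)=0.675 dVol%(vs truth)= +0.94
FLAIR   SNR=  9.02 CNR=  6.68 vol=2.857 mL DSC(vs CE)=0.671 dVol%(vs truth)=+27.43
CE-T1w  SNR= 22.57 CNR= 17.27 vol=2.240 mL DSC(vs CE)=1.000 dVol%(vs truth)= -0.09
```

Read: the CE-T1w-like sequence offers by far the best contrast (SNR 22.6,
CNR 17.3); the FLAIR-like masks inflate the plexus volume by ~+27% while the
T1w-like masks are nearly unbiased; both non-contrast masks overlap the
CE-like reference at DSC ≈ 0.67. (The measured SNR through a *drawn* mask is
lower than the sequence's nominal contrast because mis-segmented voxels
dilute the ROI — that dilution is part of what the pipeline measures.)

## Command line

```bash
chpmetrics simulate cohort/ --seed 1 --n-subjects 10   # phantom cohort
chpmetrics run-all cohort/ results/                     # full pipeline
```

`run-all` writes `contrast.tsv`, `overlap.tsv`, `interrater.tsv`,
`summary.tsv`, `stats.tsv`, `slice_profiles.tsv`, per-sequence frequency
maps and difference maps (NIfTI), a run log and the resolved config. Cohort
layout is one directory per subject: `<sequence>.nii.gz`,
`<sequence>_chp_<rater>.nii.gz`, `ventricles.nii.gz`.

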