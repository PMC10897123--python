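# Methods

## Problem and scope

`chpmetrics` quantifies how choroid-plexus (ChP) segmentations drawn on
different MRI sequences (T1w, FLAIR, contrast-enhanced T1w) or by different
raters agree, given per-subject co-registered volumes on a single voxel
grid. Registration, ventricle segmentation and the act of manual
delineation are upstream of the package: it consumes intensity volumes, ChP
masks per (sequence, rater), and a lateral-ventricle mask, all NIfTI.

## Metric definitions and numerical choices

**Contrast.** The ChP ROI for a sequence is that sequence's own drawn mask
(primary rater). The background ROI is shared across sequences within a
subject: lateral ventricles minus the union of every sequence's ChP mask,
then eroded by a closed ball of radius 2 mm. The order (subtract first,
erode second) matters: erosion then also retreats from plexus surfaces.
SNR = mean(ROI)/sd(bg), CNR = (mean(ROI) − mean(bg))/sd(bg). The SD uses
the n−1 denominator — the background is a sample of the noise process — with
`ddof=0` available for replication against population-SD conventions. The
identity SNR − CNR = mean(bg)/sd(bg) holds to machine precision and is
asserted in tests.

**Erosion kernel.** The ball is built in world mm from the voxel size:
offset (i,j,k) belongs to the kernel iff ‖(i·dx, j·dy, k·dz)‖ ≤ r (closed
ball, so the on-axis voxels at exactly r are included; a strict inequality
would drop them). On anisotropic grids the kernel reach therefore differs
per axis. Voxels outside the grid count as background, so border voxels
erode away — conservative for a noise-reference ROI. The 2 mm figure is
interpreted as a radius; a different radius (e.g. 1 mm for a
diameter-reading sensitivity check) is a configuration option.

**Overlap/volume.** DSC = 2·TP/(2·TP + FP + FN); Dice of two empty masks
raises rather than returning a value, since that configuration always means
broken upstream masks. Volumes are voxel count × voxel volume (mm³→mL),
computed in the space the masks live in. ΔVol% = 100·(V_seg − V_ref)/V_ref
(positive = overestimation). Pearson correlation is across subjects on mL
volumes, one point per subject.

**ICC.** Inter-rater agreement on absolute volumes uses the two-way
random-effects, absolute-agreement, single-measure form ICC(2,1) =
(MS_R − MS_E)/(MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)), computed directly
from the two-way ANOVA mean squares. Absolute agreement is the right target
when the question is whether two specific raters produce the *same volume*,
not merely correlated volumes. The consistency form ICC(3,1) is available
(`variant="icc3"`); the variant used is recorded in output metadata. An
all-identical matrix returns 1.0 with a warning. A useful check: with two
columns of equal mean and variance, ICC(3,1) equals the Pearson correlation
exactly, while ICC(2,1) equals r/(1 − (1−r)/n) and only converges to it —
the tests assert the exact identity on the consistency form.

**Slice profiles.** err_s(i) = 100·(count_seg(i) − count_ref(i))/V_ref,total
per subject s and slice i along a chosen voxel axis. The denominator is the
subject's whole reference volume, not the per-slice count (which can be
zero): this makes every slice well-defined and yields the conservation law
Σ_i err_s(i) = ΔVol%_s exactly, which the tests assert to 1e-9 on every
phantom subject and both axes. Cohort curves are the arithmetic mean ± SD
over subjects of the per-subject normalized errors. Slice coordinates are
reported as world mm of slice centres via the affine; which voxel axis is
"axial z" or "coronal y" is declared in the run configuration, because the
package never reorients data.

**Frequency maps.** Voxel value = k/n over the cohort's masks; maps are not
thresholded or smoothed, and difference maps are plain voxel-wise
subtraction. They require all subjects on one grid (i.e. template-space
input); the pipeline skips this stage, with a log entry, when grids differ.

**Statistics.** One-way ANOVA (F with (k−1, N−k) df) plus uncorrected post
hoc pairwise t-tests (a Bonferroni option exists, default off, and the
setting is logged); one-sample, two-sample and paired t-tests, two-tailed.
Two-sample tests default to the pooled equal-variance form — the classical
post hoc companion of one-way ANOVA — with Welch as an option. The
cross-sequence comparisons are run unpaired by default even though the
design is repeated-measures; a paired flag exists for sensitivity analysis.
Zero-variance inputs raise instead of returning a silent p-value. Type-I
error of all three tests is verified at α = 0.05 against a [0.03, 0.07]
band over 1,000 null simulations.

## The phantom generator

Every analysis stage is validated on synthetic cohorts with known ground
truth. Per subject, the phantom builds two ellipsoidal ventricle-like
compartments (radii ≈ 11×26×13 mm, centres ±16 mm lateral, ~1 mm
inter-subject jitter) each containing a thin curved plexus-like tube
(radius 2.9 mm around an arc spanning 75% of the ventricle's length, kept
off the ventricle wall so the truth is a strict subset with room to
dilate), on a 96³ grid at 1 mm isotropic — the resolution at which such
data are typically acquired. Truth volumes come out near 2.3 mL, in the
range reported for adult plexus.

**Intensity model.** Piecewise constant + stationary Gaussian noise:
`background_mean` inside the ventricle, `chp_mean` inside the true plexus,
0 outside, noise SD `noise_sd` everywhere. The contrast metrics involve
only first and second moments, so Rician/bias-field realism would add cost
without changing what the targets test. Defaults realise the in-vivo
contrast ordering with a common noise SD of 25: T1w-like SNR/CNR
13.73/7.44, FLAIR-like 13.09/10.77, CE-T1w-like 23.77/18.49 (i.e.
`chp_mean = SNR·σ`, `background_mean = (SNR − CNR)·σ`).

**Mask perturbation.** `perturb_mask` applies a signed volume bias and then
boundary noise, all inside the ventricle container:

1. The target voxel delta (bias% × truth volume, stochastically rounded so
   its expectation is exact) is added by switching on container voxels
   nearest to the truth surface in physical mm (or removed shallowest-first
   for negative bias). Distance-ordered growth mimics boundary blur — the
   mechanism behind FLAIR's systematic overestimation — rather than
   sprinkling volume at random.
2. Boundary noise flips Binomial(n₀, p) outer-shell voxels on and,
   independently, Binomial(n₀, p) inner-shell voxels off (n₀ = smaller
   shell). The expected net volume change of this stage is zero, so the
   achieved ΔVol% is an unbiased realisation of the target and one-sample
   t-tests on a zero-bias condition remain correctly calibrated, while
   overlap with the truth strictly degrades as p grows (asserted as a
   monotonicity property over paired seeds).

**Rater model.** Rater masks are hierarchical: each sequence first gets a
consensus mask (sequence bias + sequence boundary noise); the primary rater
R1 uses it directly and each further rater re-perturbs it with zero bias
and a small rater-level boundary noise. Disagreement between sequences is
therefore much larger than disagreement between raters, matching practice.

**Default disagreement regime.** Sequence boundary noise (T1w 0.39, FLAIR
0.28, CE-T1w 0.10) and rater noise (0.12) were fixed once so the default
phantom reproduces the reported regime for this problem: non-contrast vs
CE-like mask DSC in the high 0.6s, inter-rater DSC in the high 0.8s, and
FLAIR-like bias +28% with T1w-like +3.5%.

**Determinism.** One integer seed feeds a named generator; subject i draws
from the fixed substream `default_rng([seed, i])`. Cohorts, and the whole
pipeline over them, are byte-reproducible (gzip output is written without
timestamps); the end-to-end identity of two repeat runs is a test.

## What the phantom does and does not show

Passing recovery tests shows the *measurement* code is correct and
calibrated: SNR/CNR estimated on the ground-truth ROI recover the generator
parameters within 3·SEM over 30 subjects, cohort-mean ΔVol% recovers the
per-sequence bias targets, the ANOVA flags the FLAIR-like inflation, and
the zero-bias condition stays non-significant. It does not show how real
plexus anatomy, partial-volume effects, registration error or rater
cognition behave: phantom geometry is schematic (no atlas), noise is
Gaussian and stationary, the per-sequence bias is a constant target rather
than varying per subject (so the phantom's |ΔVol%| ≈ |mean bias|, unlike
in-vivo cohorts where inter-subject spread dominates that statistic), and
inter-subject anatomical variation is limited to mm-scale jitter — which is
also why the cohort Pearson correlation between sequences is small and
unstable on phantoms. The folded-normal behaviour of |ΔVol%| under
subject-varying bias is exercised separately in tests by drawing per-draw
bias targets from N(0, 12%).

## Problem sizes used in validation

Unit and property tests run on 16³–64³ grids and 3–5-subject cohorts; the
parameter-recovery and calibration checks use the full default conditions
(30 subjects, 96³, 1 mm isotropic; 1,000 null simulations), the scale at
which the generator's targets are specified.

## Known limitations

- Inputs must already share a grid per subject (and across subjects for
  template-space stages); the package refuses rather than resamples.
- The slice-profile axis mapping is configuration, not read from NIfTI
  orientation codes; misdeclared axes silently swap "axial" and "coronal"
  labels (coordinates remain correct world mm).
- ICC assumes a complete ratings matrix; missing cells raise.
- Post hoc tests are uncorrected by default by design; enable Bonferroni
  when the analysis calls for it.
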