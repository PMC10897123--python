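import numpy as np
import pytest

from chpmetrics.agreement import dice, percent_volume_difference
from chpmetrics.synthetic import (
    PhantomSpec,
    SequenceModel,
    generate_cohort,
    generate_subject,
    perturb_mask,
)

from conftest import mask_from


@pytest.fixture(scope="module")
def tube_and_container():
    """A small truth tube inside a roomy container, for perturbation tests."""
    container = np.zeros((24, 24, 24), bool)
    container[2:22, 2:22, 2:22] = True
    truth = np.zeros_like(container)
    truth[10:14, 4:20, 10:13] = True  # 4 x 16 x 3 slab, 192 voxels
    return mask_from(truth), mask_from(container)


class TestPerturbMask:
    def test_zero_perturbation_returns_truth(self, tube_and_container):
        truth, container = tube_and_container
        out = perturb_mask(truth, container, 0.0, 0.0, seed=1)
        np.testing.assert_array_equal(out.data, truth.data)
        assert dice(out, truth) == 1.0

    def test_deterministic_given_seed(self, tube_and_container):
        truth, container = tube_and_container
        a = perturb_mask(truth, container, 15.0, 0.2, seed=42)
        b = perturb_mask(truth, container, 15.0, 0.2, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_positive_bias_hits_target_volume(self, tube_and_container):
        truth, container = tube_and_container
        out = perturb_mask(truth, container, 30.0, 0.0, seed=2)
        achieved = percent_volume_difference(out, truth)
        assert achieved == pytest.approx(30.0, abs=2.0)

    def test_negative_bias(self, tube_and_container):
        truth, container = tube_and_container
        out = perturb_mask(truth, container, -20.0, 0.0, seed=3)
        assert percent_volume_difference(out, truth) == pytest.approx(-20.0, abs=2.0)

    def test_result_stays_inside_container(self, tube_and_container):
        truth, container = tube_and_container
        out = perturb_mask(truth, container, 40.0, 0.3, seed=4)
        assert not np.any(out.data.astype(bool) & ~container.data.astype(bool))

    def test_total_removal_rejected(self, tube_and_container):
        truth, container = tube_and_container
        with pytest.raises(ValueError, match="-100"):
            perturb_mask(truth, container, -100.0, 0.0, seed=5)

    def test_unreachable_bias_rejected(self):
        truth = np.zeros((8, 8, 8), bool)
        truth[2:6, 2:6, 2:6] = True
        tight = mask_from(truth)  # container == truth: no room to grow
        with pytest.raises(ValueError, match="unreachable"):
            perturb_mask(tight, tight, 50.0, 0.0, seed=6)

    def test_truth_outside_container_rejected(self, tube_and_container):
        truth, container = tube_and_container
        with pytest.raises(ValueError, match="subset"):
            perturb_mask(container, truth, 0.0, 0.0, seed=7)

    def test_bias_unbiased_over_replicates(self, tube_and_container):
        """Mean achieved dVol% over 25 draws recovers the target within
        3 SEM (stochastic rounding + symmetric boundary flips)."""
        truth, container = tube_and_container
        target = 28.0
        achieved = np.array(
            [
                percent_volume_difference(
                    perturb_mask(truth, container, target, 0.15, seed=100 + i),
                    truth,
                )
                for i in range(25)
            ]
        )
        sem = achieved.std(ddof=1) / np.sqrt(len(achieved))
        assert abs(achieved.mean() - target) < 3 * max(sem, 0.3)

    def test_dice_monotone_in_boundary_noise(self, tube_and_container):
        """Expected Dice vs truth strictly decreases as boundary noise
        grows (paired seeds, 50 replicates)."""
        truth, container = tube_and_container
        levels = [0.05, 0.15, 0.30]
        means = []
        for p in levels:
            d = [
                dice(perturb_mask(truth, container, 0.0, p, seed=i), truth)
                for i in range(50)
            ]
            means.append(np.mean(d))
        assert means[0] > means[1] > means[2]


class TestGenerateCohort:
    def test_determinism_bit_identical(self, small_spec):
        b1, t1 = generate_subject(small_spec, 0)
        b2, t2 = generate_subject(small_spec, 0)
        np.testing.assert_array_equal(t1.data, t2.data)
        for s in b1.intensities:
            np.testing.assert_array_equal(
                b1.intensities[s].data, b2.intensities[s].data
            )
        for key in b1.chp_masks:
            np.testing.assert_array_equal(
                b1.chp_masks[key].data, b2.chp_masks[key].data
            )

    def test_noiseless_zero_perturbation_degenerate(self):
        spec = PhantomSpec(
            n_subjects=1,
            seed=5,
            grid_shape=(48, 48, 48),
            ventricle_centers_mm=((-8.0, 0.0, 0.0), (8.0, 0.0, 0.0)),
            ventricle_radii_mm=(6.0, 13.0, 7.0),
            chp_thickness_mm=1.8,
            sequences={"SEQ": SequenceModel(500.0, 100.0, 1e-9, 0.0, 0.0)},
            raters={"R1": 0.0},
        )
        cohort = generate_cohort(spec)
        b = cohort.subjects[0]
        truth = cohort.truth_chp[b.subject_id]
        m = b.mask("SEQ", "R1")
        assert dice(m, truth) == 1.0
        assert percent_volume_difference(m, truth) == 0.0

    def test_truth_strict_subset_of_ventricles(self, small_cohort):
        for b in small_cohort.subjects:
            t = small_cohort.truth_chp[b.subject_id].data.astype(bool)
            v = b.ventricle_mask.data.astype(bool)
            assert not np.any(t & ~v)
            assert t.sum() < v.sum()

    def test_empirical_snr_on_truth_roi(self):
        """chp_mean 500, noise 25 gives SNR ~ 20 measured over the truth ROI
        and a pure-noise background region (sampling-theory tolerance)."""
        spec = PhantomSpec(
            n_subjects=1,
            seed=6,
            grid_shape=(48, 48, 48),
            ventricle_centers_mm=((-8.0, 0.0, 0.0), (8.0, 0.0, 0.0)),
            ventricle_radii_mm=(6.0, 13.0, 7.0),
            chp_thickness_mm=1.8,
            sequences={"SEQ": SequenceModel(500.0, 100.0, 25.0, 0.0, 0.0)},
            raters={"R1": 0.0},
        )
        cohort = generate_cohort(spec)
        b = cohort.subjects[0]
        truth = cohort.truth_chp[b.subject_id]
        vol = b.intensities["SEQ"].data
        roi_vals = vol[truth.data.astype(bool)]
        bg = b.ventricle_mask.data.astype(bool) & ~truth.data.astype(bool)
        est_snr = roi_vals.mean() / vol[bg].std(ddof=1)
        se = 20.0 * np.sqrt(1.0 / roi_vals.size + 1.0 / (2 * bg.sum()))
        assert abs(est_snr - 20.0) < 3 * se + 0.05

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(n_subjects=0)
        with pytest.raises(ValueError):
            PhantomSpec(chp_thickness_mm=-1.0)
        with pytest.raises(ValueError):
            SequenceModel(1.0, 0.0, 0.0, 0.0, 0.0)  # zero noise SD
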