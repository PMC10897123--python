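import numpy as np
import pytest

from chpmetrics.agreement import (
    abs_percent_volume_difference,
    dice,
    icc_absolute_volume,
    pearson_volume_correlation,
    percent_volume_difference,
    volume_ml,
)

from conftest import mask_from, random_mask

# frozen from an independent two-way ANOVA mean-squares computation
# (MS_rows=9.6, MS_cols=0.4, MS_err=0.4 -> ICC(2,1)=0.92)
ICC_MATRIX = [[10, 11], [12, 12], [8, 9], [15, 14], [11, 12]]
ICC_EXPECTED = 0.92


def _pair(n_a, n_b, overlap, shape=(12, 12, 12)):
    a = np.zeros(shape, bool).ravel()
    b = np.zeros(shape, bool).ravel()
    a[:n_a] = True
    b[n_a - overlap: n_a - overlap + n_b] = True
    return mask_from(a.reshape(shape)), mask_from(b.reshape(shape))


class TestDice:
    def test_identical_masks(self):
        rng = np.random.default_rng(9)
        m = random_mask(rng)
        assert dice(m, m) == 1.0

    def test_hand_count(self):
        seg, ref = _pair(4, 4, 2)
        assert dice(seg, ref) == pytest.approx(0.5)

    def test_disjoint(self):
        seg, ref = _pair(4, 4, 0)
        assert dice(seg, ref) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(10)
        a, b = random_mask(rng), random_mask(rng)
        assert dice(a, b) == dice(b, a)

    def test_both_empty_raises(self):
        e = mask_from(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="both masks are empty"):
            dice(e, e)

    def test_superset_closed_form(self):
        """If seg contains ref, Dice = 2|ref|/(|seg|+|ref|) and dVol >= 0."""
        ref = np.zeros((12, 12, 12), bool)
        ref[4:8, 4:8, 4:8] = True
        seg = np.zeros_like(ref)
        seg[3:9, 3:9, 3:9] = True
        m_ref, m_seg = mask_from(ref), mask_from(seg)
        nr, ns = m_ref.voxel_count, m_seg.voxel_count
        assert dice(m_seg, m_ref) == pytest.approx(2 * nr / (ns + nr))
        assert percent_volume_difference(m_seg, m_ref) >= 0


class TestVolume:
    def test_count_scaling_1mm(self):
        data = np.zeros((20, 20, 20))
        data.ravel()[:3073] = 1
        assert volume_ml(mask_from(data)) == pytest.approx(3.073)

    def test_empty(self):
        assert volume_ml(mask_from(np.zeros((4, 4, 4)))) == 0.0

    def test_anisotropic_voxels(self):
        aff = np.diag([1.0, 1.0, 2.0, 1.0])
        data = np.zeros((10, 10, 10))
        data.ravel()[:100] = 1
        assert volume_ml(mask_from(data, aff)) == pytest.approx(0.2)

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(11)
        a = rng.random((10, 10, 10)) < 0.3
        b = (rng.random((10, 10, 10)) < 0.3) & ~a
        total = volume_ml(mask_from(a | b))
        assert total == pytest.approx(volume_ml(mask_from(a)) + volume_ml(mask_from(b)))


class TestVolumeDifference:
    def test_signed_value(self):
        seg, _ = _pair(110, 1, 1)
        _, ref = _pair(1, 100, 1)
        assert percent_volume_difference(seg, ref) == pytest.approx(10.0)

    def test_zero_for_equal(self):
        rng = np.random.default_rng(12)
        m = random_mask(rng)
        assert percent_volume_difference(m, m) == 0.0

    def test_abs_of_negative(self):
        seg, _ = _pair(90, 1, 1)
        _, ref = _pair(1, 100, 1)
        assert percent_volume_difference(seg, ref) == pytest.approx(-10.0)
        assert abs_percent_volume_difference(seg, ref) == pytest.approx(10.0)

    def test_empty_reference_raises(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError, match="empty reference"):
            percent_volume_difference(random_mask(rng), mask_from(np.zeros((16, 16, 16))))


class TestPearson:
    def test_affine_invariance(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert pearson_volume_correlation(a, [2 * x for x in a]) == pytest.approx(1.0)
        assert pearson_volume_correlation(a, [-x + 7 for x in a]) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson_volume_correlation([1, 2, 3], [1, 2, 4]) == pytest.approx(
            0.981980506062, abs=1e-9
        )

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_volume_correlation([1, 2, 3], [5, 5, 5])


class TestICC:
    def test_matches_mean_squares_oracle(self):
        assert icc_absolute_volume(ICC_MATRIX, "icc2") == pytest.approx(
            ICC_EXPECTED, abs=1e-9
        )

    def test_duplicated_columns_give_one(self):
        m = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert icc_absolute_volume(m) == pytest.approx(1.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(14)
        vals = [
            icc_absolute_volume(rng.normal(size=(200, 2))) for _ in range(50)
        ]
        assert abs(np.mean(vals)) < 0.1

    def test_matches_pingouin_on_random_matrices(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(15)
        for _ in range(5):
            m = rng.normal(10, 2, size=(8, 3)) + rng.normal(
                0, 3, size=(8, 1)
            )  # subject effect
            df = pd.DataFrame(
                {
                    "t": np.repeat(np.arange(8), 3),
                    "r": list(range(3)) * 8,
                    "y": m.ravel(),
                }
            )
            res = pg.intraclass_corr(df, targets="t", raters="r", ratings="y")
            # row 1 is the absolute-agreement single-measure form, row 2 the
            # consistency form (pingouin's fixed ordering)
            expect2 = float(res["ICC"].iloc[1])
            expect3 = float(res["ICC"].iloc[2])
            assert icc_absolute_volume(m, "icc2") == pytest.approx(expect2, abs=1e-9)
            assert icc_absolute_volume(m, "icc3") == pytest.approx(expect3, abs=1e-9)

    def test_consistency_icc_equals_pearson_for_equal_moments(self):
        """With two columns of equal mean and variance, the consistency ICC
        coincides with the Pearson correlation."""
        rng = np.random.default_rng(16)
        a = rng.normal(size=40)
        b = 0.7 * a + 0.5 * rng.normal(size=40)
        b = (b - b.mean()) / b.std(ddof=1) * a.std(ddof=1) + a.mean()
        r = pearson_volume_correlation(a, b)
        assert icc_absolute_volume(np.column_stack([a, b]), "icc3") == pytest.approx(
            r, abs=1e-6
        )

    def test_degenerate_all_identical_warns_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert icc_absolute_volume(np.full((4, 2), 3.0)) == 1.0

    def test_invalid_shapes(self):
        with pytest.raises(ValueError):
            icc_absolute_volume(np.ones((1, 2)))
        with pytest.raises(ValueError):
            icc_absolute_volume(np.ones(5))


class TestFoldedNormalAbsDvol:
    def test_symmetric_bias_gives_folded_normal_mean(self):
        """With per-draw signed biases ~ N(0, 12%), the mean absolute
        percentage volume difference approaches 12*sqrt(2/pi) (folded
        normal), checked within 3 SEM."""
        from chpmetrics.synthetic import perturb_mask

        container = np.zeros((24, 24, 24), bool)
        container[2:22, 2:22, 2:22] = True
        truth = np.zeros_like(container)
        truth[8:16, 4:20, 8:14] = True
        truth_m, cont_m = mask_from(truth), mask_from(container)
        rng = np.random.default_rng(17)
        targets = rng.normal(0.0, 12.0, size=40)
        achieved = np.array(
            [
                abs_percent_volume_difference(
                    perturb_mask(truth_m, cont_m, t, 0.0, seed=500 + i), truth_m
                )
                for i, t in enumerate(targets)
            ]
        )
        expected = 12.0 * np.sqrt(2.0 / np.pi)
        sem = achieved.std(ddof=1) / np.sqrt(len(achieved))
        assert abs(achieved.mean() - expected) < 3 * sem


class TestPhantomBiasRecovery:
    def test_cohort_mean_dvol_recovers_targets(self, small_cohort):
        spec = small_cohort.spec
        for s, model in spec.sequences.items():
            dv = np.array(
                [
                    percent_volume_difference(
                        b.mask(s, "R1"), small_cohort.truth_chp[b.subject_id]
                    )
                    for b in small_cohort.subjects
                ]
            )
            sem = dv.std(ddof=1) / np.sqrt(len(dv))
            assert abs(dv.mean() - model.bias_percent) < 3 * max(sem, 0.05)
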