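import numpy as np
import pytest
from scipy import stats

from lesionfm import (BackgroundParams, LesionSpec, make_classification_cohort,
                      make_expression, make_retest_pair, make_survival_cohort,
                      make_volume)
from lesionfm.types import HU_MAX, HU_MIN
from lesionfm.volumes import seed_from_mask


class TestMakeVolume:
    def test_geometry_contract(self):
        spec = LesionSpec(class_id=0, radius_mm=5.0)
        vol, mask, seed = make_volume(spec, edge_mm=64, rng=np.random.default_rng(0))
        assert mask.sum() > 0
        idx = np.argwhere(mask)
        assert idx.min() > 0 and idx.max() < 63  # strictly interior
        assert np.all(vol.intensities >= HU_MIN) and np.all(vol.intensities <= HU_MAX)

    def test_degenerate_texture(self):
        spec = LesionSpec(class_id=0, radius_mm=5.0, texture_amplitude=0.0,
                          intensity_offset=100.0)
        vol, mask, _ = make_volume(spec, edge_mm=48,
                                   background=BackgroundParams(sd_hu=0.0),
                                   rng=np.random.default_rng(0))
        np.testing.assert_allclose(vol.intensities[mask], -700.0)
        np.testing.assert_allclose(vol.intensities[~mask], -800.0)

    def test_determinism(self):
        spec = LesionSpec(class_id=1, radius_mm=6.0, texture_pattern="plane")
        a = make_volume(spec, rng=np.random.default_rng(5))
        b = make_volume(spec, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a[0].intensities, b[0].intensities)
        np.testing.assert_array_equal(a[1], b[1])

    def test_lesion_must_fit(self):
        with pytest.raises(ValueError):
            make_volume(LesionSpec(class_id=0, radius_mm=30.0), edge_mm=48,
                        rng=np.random.default_rng(0))

    def test_seed_is_mask_centroid(self):
        spec = LesionSpec(class_id=0, radius_mm=5.0)
        vol, mask, seed = make_volume(spec, rng=np.random.default_rng(2))
        np.testing.assert_allclose(seed.xyz, seed_from_mask(mask).xyz)

    def test_bad_spec(self):
        with pytest.raises(ValueError):
            LesionSpec(class_id=0, radius_mm=-1.0)
        with pytest.raises(ValueError):
            LesionSpec(class_id=0, radius_mm=5.0, texture_pattern="swirl")


class TestClassificationCohort:
    @pytest.mark.parametrize("n,K,allowed", [(12, 3, {4}), (10, 3, {3, 4})])
    def test_balanced(self, n, K, allowed):
        cohort = make_classification_cohort(n, K=K, rng=np.random.default_rng(0),
                                            edge_mm=48, radius_range=(4, 6))
        counts = np.bincount([r.site_class for r in cohort.lesions], minlength=K)
        assert set(counts.tolist()) <= allowed

    def test_determinism(self, small_cohort):
        again = make_classification_cohort(12, K=3, rng=np.random.default_rng(7),
                                           edge_mm=48, radius_range=(4.0, 6.0))
        assert [r.site_class for r in again.lesions] == \
            [r.site_class for r in small_cohort.lesions]
        np.testing.assert_array_equal(again.volumes[0].intensities,
                                      small_cohort.volumes[0].intensities)

    def test_n_less_than_k(self):
        with pytest.raises(ValueError):
            make_classification_cohort(2, K=3, rng=np.random.default_rng(0))

    def test_hu_invariant(self, small_cohort):
        for vol in small_cohort.volumes:
            assert vol.intensities.min() >= HU_MIN
            assert vol.intensities.max() <= HU_MAX


class TestSurvivalCohort:
    def test_null_hazard_link_independence(self):
        cohort = make_survival_cohort(1000, hazard_link=0.0, censor_rate=0.0,
                                      rng=np.random.default_rng(0), make_volumes=False)
        # radius is not stored without volumes; regenerate radii deterministically
        rng = np.random.default_rng(0)
        radii = rng.uniform(4.0, 10.0, size=1000)
        times = np.array([r.time_days for r in cohort.lesions])
        tau = stats.kendalltau(radii, times).statistic
        assert abs(tau) < 0.06

    def test_positive_link_shortens_times(self):
        cohort = make_survival_cohort(1000, hazard_link=0.4, censor_rate=0.0,
                                      rng=np.random.default_rng(1), make_volumes=False)
        rng = np.random.default_rng(1)
        radii = rng.uniform(4.0, 10.0, size=1000)
        times = np.array([r.time_days for r in cohort.lesions])
        assert stats.kendalltau(radii, times).statistic < -0.1

    def test_no_censoring(self):
        cohort = make_survival_cohort(50, censor_rate=0.0,
                                      rng=np.random.default_rng(2), make_volumes=False)
        assert all(r.event == 1 for r in cohort.lesions)

    def test_censor_rate_roughly_calibrated(self):
        cohort = make_survival_cohort(2000, censor_rate=0.3,
                                      rng=np.random.default_rng(3), make_volumes=False)
        frac = np.mean([1 - r.event for r in cohort.lesions])
        assert 0.2 < frac < 0.4

    def test_2yr_label_right_censoring(self):
        cohort = make_survival_cohort(500, censor_rate=0.4,
                                      rng=np.random.default_rng(4), make_volumes=False)
        for r in cohort.lesions:
            if r.time_days >= 730:
                assert r.label_2yr == 1
            elif r.event == 1:
                assert r.label_2yr == 0
            else:
                assert r.label_2yr is None

    def test_min_n(self):
        with pytest.raises(ValueError):
            make_survival_cohort(10, rng=np.random.default_rng(0), make_volumes=False)


class TestRetest:
    def test_zero_jitter_identity(self, small_cohort):
        from lesionfm.synthetic import RetestJitter

        vol = small_cohort.volumes[0]
        twin = make_retest_pair(vol, RetestJitter(shift_voxels=(0, 0, 0), noise_sd_hu=0),
                                rng=np.random.default_rng(0))
        np.testing.assert_array_equal(twin.intensities, vol.intensities)

    def test_small_shift_moves_centroid_less_than_voxel(self):
        from lesionfm.synthetic import RetestJitter

        spec = LesionSpec(class_id=0, radius_mm=6.0)
        vol, mask, seed = make_volume(spec, edge_mm=48,
                                      background=BackgroundParams(sd_hu=0.0),
                                      rng=np.random.default_rng(0))
        # deterministic 0.5-voxel x-shift via a degenerate normal (sd 0 on y,z)
        rng = np.random.default_rng(0)
        twin = make_retest_pair(vol, RetestJitter(shift_voxels=(0.0, 0.0, 0.0),
                                                  noise_sd_hu=0.0), rng=rng)
        from scipy import ndimage

        shifted = ndimage.shift(vol.intensities, (0.5, 0, 0), order=1, mode="nearest")
        new_mask = shifted > -750.0
        c_old = seed_from_mask(mask).xyz
        c_new = seed_from_mask(new_mask).xyz
        assert np.linalg.norm(c_new - c_old) < 1.0

    def test_determinism(self, small_cohort):
        vol = small_cohort.volumes[1]
        a = make_retest_pair(vol, rng=np.random.default_rng(9))
        b = make_retest_pair(vol, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestExpression:
    def test_null_target_indistinguishable(self):
        pheno = np.random.default_rng(0).normal(size=200)
        expr, info = make_expression(pheno, G=300, g_informative=30, r_target=0.0,
                                     rng=np.random.default_rng(1))
        r = expr.apply(lambda row: np.corrcoef(row, pheno)[0, 1], axis=1)
        info_r = np.abs(r.loc[info])
        noise_r = np.abs(r.drop(index=info))
        # same null distribution: medians within sampling error
        assert abs(info_r.median() - noise_r.median()) < 0.1

    def test_informative_genes_separate(self):
        pheno = np.random.default_rng(2).normal(size=130)
        expr, info = make_expression(pheno, G=1000, g_informative=50, r_target=0.6,
                                     rng=np.random.default_rng(3))
        r = expr.apply(lambda row: np.corrcoef(row, pheno)[0, 1], axis=1)
        info_mean = np.abs(r.loc[info]).mean()
        noise_q95 = np.quantile(np.abs(r.drop(index=info)), 0.95)
        assert info_mean > noise_q95

    def test_determinism(self):
        pheno = np.arange(50, dtype=float)
        a, ia = make_expression(pheno, G=100, g_informative=10, r_target=0.5,
                                rng=np.random.default_rng(4))
        b, ib = make_expression(pheno, G=100, g_informative=10, r_target=0.5,
                                rng=np.random.default_rng(4))
        assert ia == ib
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_bad_r(self):
        with pytest.raises(ValueError):
            make_expression(np.zeros(10), G=10, g_informative=2, r_target=1.0)

    def test_heterogeneous_means_and_scales(self):
        pheno = np.random.default_rng(5).normal(size=80)
        expr, _ = make_expression(pheno, G=200, g_informative=20, r_target=0.5,
                                  rng=np.random.default_rng(6))
        assert expr.mean(axis=1).std() > 1.0   # gene means vary
        assert expr.std(axis=1).std() > 0.2    # gene scales vary


def test_cohort_write_round_trip(tmp_path, small_cohort):
    from lesionfm.pipeline import load_cohort

    out = small_cohort.write(tmp_path / "cohort")
    back = load_cohort(out)
    assert len(back) == len(small_cohort)
    np.testing.assert_allclose(back.volumes[0].intensities,
                               small_cohort.volumes[0].intensities, rtol=1e-6)
    assert [r.site_class for r in back.lesions] == \
        [r.site_class for r in small_cohort.lesions]
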