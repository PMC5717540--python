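"""FWE procedures: Bonferroni, random field theory, sign-flip permutation."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from eitmap import (
    VoxelGrid,
    bonferroni_alpha,
    bonferroni_threshold,
    ec_density_t,
    estimate_smoothness,
    expected_euler_characteristic,
    mc_error,
    rft_threshold,
    significant_volume,
    temporal_correction,
)
from eitmap.fwe import (
    MaxStatNull,
    SmoothnessEstimate,
    box_resels,
    max_t_distribution,
    permutation_threshold,
    sign_flip_permutation,
)
from eitmap.synthetic import smooth_unit_field


class TestTemporalCorrection:
    def test_study_design_gives_five_independent_tests(self):
        alpha_bin, n_indep = temporal_correction(0.05, 21, 2.0, 8.0)
        assert n_indep == 5
        assert alpha_bin == pytest.approx(0.01)

    def test_same_window_different_binning(self):
        alpha_bin, n_indep = temporal_correction(0.05, 41, 1.0, 8.0)
        assert n_indep == 5
        assert alpha_bin == pytest.approx(0.01)

    def test_single_bin_uncorrected(self):
        alpha_bin, n_indep = temporal_correction(0.05, 1, 2.0, 2.0)
        assert n_indep == 1
        assert alpha_bin == pytest.approx(0.05)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            temporal_correction(1.5, 21, 2.0, 8.0)


class TestBonferroni:
    def test_ten_thousand_voxels(self):
        assert bonferroni_alpha(0.05, 10_000) == pytest.approx(5e-6)

    def test_single_test(self):
        assert bonferroni_alpha(0.05, 1) == pytest.approx(0.05)

    def test_full_image_voxel_count(self):
        assert bonferroni_alpha(0.01, 6_254_041) == pytest.approx(1.59897e-9, rel=1e-5)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)

    def test_threshold_median_is_zero(self):
        assert bonferroni_threshold(0.5, 7) == pytest.approx(0.0, abs=1e-12)

    def test_threshold_t_table(self):
        assert bonferroni_threshold(0.05, 21) == pytest.approx(1.7207, abs=5e-4)

    def test_threshold_monotone_in_alpha(self):
        alphas = np.logspace(-6, -1, 12)
        thr = [bonferroni_threshold(a, 21) for a in alphas]
        assert np.all(np.diff(thr) < 0)


class TestMcError:
    def test_study_value(self):
        assert mc_error(0.01, 1000) == pytest.approx(0.0063, abs=5e-5)

    def test_degenerate_p(self):
        assert mc_error(0.0, 100) == 0.0

    def test_plug_in(self):
        assert mc_error(0.5, 100) == pytest.approx(0.1)


class TestSignificantVolume:
    def test_empty_mask(self):
        grid = VoxelGrid((4, 4, 4))
        assert significant_volume(np.zeros(grid.dims, bool), grid) == 0.0

    def test_64_voxels_at_25um(self):
        grid = VoxelGrid((8, 8, 8), (25.0, 25.0, 25.0))
        mask = np.zeros(grid.dims, bool)
        mask[:4, :4, :4] = True
        assert significant_volume(mask, grid) == pytest.approx(1.0e-3)

    def test_cubic_mm(self):
        grid = VoxelGrid((10, 10, 10), (100.0, 100.0, 100.0))
        assert significant_volume(np.ones(grid.dims, bool), grid) == pytest.approx(1.0)


class TestEcDensities:
    def test_rho0_at_zero(self):
        assert ec_density_t(0, 0.0, 21) == pytest.approx(0.5)

    def test_rho1_at_zero_df_independent(self):
        expected = math.sqrt(4 * math.log(2)) / (2 * math.pi)
        for df in (5, 21, 100):
            assert ec_density_t(1, 0.0, df) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.26500, abs=2e-5)

    @pytest.mark.parametrize("t", [0.5, 2.0, 4.0])
    def test_gaussian_limit(self, t):
        df = 10**6
        ln4 = 4 * math.log(2)
        gauss = {
            0: stats.norm.sf(t),
            1: math.sqrt(ln4) / (2 * math.pi) * math.exp(-t * t / 2),
            2: ln4 / (2 * math.pi) ** 1.5 * t * math.exp(-t * t / 2),
            3: ln4**1.5 / (2 * math.pi) ** 2 * (t * t - 1) * math.exp(-t * t / 2),
        }
        for d in range(4):
            assert ec_density_t(d, t, df) == pytest.approx(gauss[d], abs=1e-3)

    def test_invalid_dimension_rejected(self):
        with pytest.raises(ValueError):
            ec_density_t(4, 1.0, 21)


class TestSmoothnessEstimation:
    def test_box_resels_example(self):
        assert box_resels((60, 60, 60), (6.0, 6.0, 6.0)) == (1.0, 30.0, 300.0, 1000.0)

    def test_known_kernel_recovery(self):
        grid = VoxelGrid((48, 48, 48))
        ss = np.random.SeedSequence(21).spawn(22)
        x = np.stack([smooth_unit_field(np.random.default_rng(s), grid, 150.0) for s in ss])
        resid = x - x.mean(axis=0)
        resid /= np.sqrt((resid**2).sum(axis=0))
        sm = estimate_smoothness(resid, np.ones(grid.dims, bool), grid)
        for f in sm.fwhm_voxels:
            assert 5.1 <= f <= 6.9

    def test_anisotropic_recovery(self):
        grid = VoxelGrid((48, 48, 48))
        fwhms = (4.0, 6.0, 8.0)
        ss = np.random.SeedSequence(22).spawn(22)
        white = [np.random.default_rng(s).standard_normal(grid.dims) for s in ss]
        from scipy import ndimage

        from eitmap.synthetic import _gaussian_kernel_l2, fwhm_to_sigma

        sigmas = [fwhm_to_sigma(f) for f in fwhms]
        norm = np.prod([_gaussian_kernel_l2(s) for s in sigmas])
        x = np.stack(
            [ndimage.gaussian_filter(w, sigma=sigmas, mode="wrap", truncate=4.0) / norm for w in white]
        )
        resid = x - x.mean(axis=0)
        resid /= np.sqrt((resid**2).sum(axis=0))
        sm = estimate_smoothness(resid, np.ones(grid.dims, bool), grid)
        assert sm.fwhm_voxels[0] < sm.fwhm_voxels[1] < sm.fwhm_voxels[2]
        for est, true in zip(sm.fwhm_voxels, fwhms):
            assert abs(est - true) / true < 0.15

    def test_flat_residuals_rejected(self):
        resid = np.zeros((3, 4, 4, 4))
        resid[0] = 1.0  # constant along every axis
        with pytest.raises(ValueError, match="flat|smoothness"):
            estimate_smoothness(resid, np.ones((4, 4, 4), bool), VoxelGrid((4, 4, 4)))


class TestRftThreshold:
    def test_zero_dimensional_domain_matches_t_quantile(self):
        sm = SmoothnessEstimate((6.0, 6.0, 6.0), (1.0, 0.0, 0.0, 0.0), 1)
        # a single resel point: E[EC] = rho0 = upper tail probability
        thr = rft_threshold(sm, 21, 0.05)
        assert thr == pytest.approx(stats.t.isf(0.05, 21), abs=1e-5)

    def test_threshold_increases_with_search_volume(self):
        thresholds = []
        for side in (10, 20, 40, 80):
            resels = box_resels((side,) * 3, (5.0,) * 3)
            sm = SmoothnessEstimate((5.0, 5.0, 5.0), resels, side**3)
            thresholds.append(rft_threshold(sm, 21, 0.05))
        assert np.all(np.diff(thresholds) > 0)

    def test_capped_at_bonferroni(self):
        # tiny mask: Bonferroni over n_masked_voxels is the binding constraint
        sm = SmoothnessEstimate((2.0, 2.0, 2.0), box_resels((4, 4, 4), (2.0,) * 3), 64)
        thr = rft_threshold(sm, 21, 0.05)
        t_bonf = bonferroni_threshold(bonferroni_alpha(0.05, 64), 21)
        assert thr <= t_bonf + 1e-12

    def test_expected_ec_at_threshold_equals_alpha(self):
        resels = box_resels((32, 32, 32), (4.0,) * 3)
        sm = SmoothnessEstimate((4.0, 4.0, 4.0), resels, 32**3)
        thr = rft_threshold(sm, 21, 0.05)
        t_bonf = bonferroni_threshold(bonferroni_alpha(0.05, 32**3), 21)
        if thr < t_bonf:  # uncapped: the threshold is the root of E[EC] = alpha
            assert expected_euler_characteristic(thr, resels, 21) == pytest.approx(0.05, rel=1e-3)
        else:
            assert thr == pytest.approx(t_bonf, abs=1e-9)

    def test_low_df_heavy_tail_hits_bonferroni_cap(self):
        """At low df the EC tail decays polynomially and Bonferroni binds."""
        resels = box_resels((32, 32, 32), (4.0,) * 3)
        sm = SmoothnessEstimate((4.0, 4.0, 4.0), resels, 32**3)
        thr = rft_threshold(sm, 11, 0.05)
        t_bonf = bonferroni_threshold(bonferroni_alpha(0.05, 32**3), 11)
        assert thr <= t_bonf + 1e-12


def _brute_force_max_t(data: np.ndarray) -> np.ndarray:
    """Independent oracle: enumerate all sign patterns with scipy's t-test."""
    n = data.shape[0]
    maxima = []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        flipped = np.asarray(signs)[:, None] * data
        t, _ = stats.ttest_1samp(flipped, 0.0, axis=0)
        maxima.append(t.max())
    return np.sort(maxima)


class TestSignFlipPermutation:
    def test_total_relabelings_for_22_recordings(self):
        assert 2**22 == 4_194_304

    def test_exhaustive_matches_brute_force_oracle(self, rng):
        data = rng.normal(size=(4, 3, 1, 1)) + 0.5
        mask = np.ones((3, 1, 1), bool)
        null = max_t_distribution(data, mask, n_perms=16)
        assert null.exhaustive
        assert null.n_perms == 16
        oracle = _brute_force_max_t(data.reshape(4, -1))
        np.testing.assert_allclose(null.max_values, oracle, atol=1e-12)

    def test_identity_always_included(self, rng):
        data = rng.normal(size=(8, 4, 4, 2)) + 0.3
        mask = np.ones((4, 4, 2), bool)
        grid = VoxelGrid((4, 4, 2))
        t_obs = stats.ttest_1samp(data.reshape(8, -1), 0.0, axis=0)[0].reshape(4, 4, 2)
        null, result = sign_flip_permutation(t_obs, data, mask, 50, 0.1, seed=3, grid=grid)
        obs_max = t_obs.max()
        assert np.any(np.isclose(null.max_values, obs_max, atol=1e-12))
        # corrected p of the observed maximum is at least 1/n_perms
        assert np.nanmin(result.corrected_p) >= 1.0 / null.n_perms

    def test_monte_carlo_within_mc_error_of_exhaustive(self, rng):
        """n=10: the 1000-perm threshold sits inside the mc-error band of the exact one."""
        data = rng.normal(size=(10, 5, 5, 4)) + 0.2
        mask = np.ones((5, 5, 4), bool)
        alpha = 0.1
        exact = permutation_threshold(max_t_distribution(data, mask, 1024), alpha)
        mc = max_t_distribution(data, mask, 1000, seed=9)
        assert not mc.exhaustive
        half_width = mc_error(alpha, 1000)
        lo = permutation_threshold(mc, alpha + half_width)
        hi = permutation_threshold(mc, max(alpha - half_width, 1.5 / 1000))
        assert lo - 1e-12 <= exact <= hi + 1e-12

    def test_unattainable_alpha_rejected(self, rng):
        data = rng.normal(size=(6, 3, 3, 3))
        null = max_t_distribution(data, np.ones((3, 3, 3), bool), 64)
        with pytest.raises(ValueError, match="unattainable"):
            permutation_threshold(null, 0.01)

    def test_sig_mask_consistent_with_threshold(self, rng):
        data = rng.normal(size=(8, 6, 6, 3)) + 0.8
        grid = VoxelGrid((6, 6, 3))
        mask = np.ones(grid.dims, bool)
        t_obs = stats.ttest_1samp(data.reshape(8, -1), 0.0, axis=0)[0].reshape(grid.dims)
        _, result = sign_flip_permutation(t_obs, data, mask, 200, 0.05, seed=5, grid=grid)
        np.testing.assert_array_equal(result.sig_mask, (t_obs > result.t_threshold) & mask)
        assert result.sig_volume_mm3 == pytest.approx(
            result.n_sig_voxels * grid.voxel_volume_mm3
        )

    def test_volume_monotone_in_threshold(self, rng):
        """Fewer voxels survive as the threshold rises."""
        data = rng.normal(size=(10, 8, 8, 4)) + 0.5
        grid = VoxelGrid((8, 8, 4))
        t_obs = stats.ttest_1samp(data.reshape(10, -1), 0.0, axis=0)[0].reshape(grid.dims)
        counts = [(t_obs > thr).sum() for thr in (1.0, 2.0, 3.0, 4.0)]
        assert np.all(np.diff(counts) <= 0)

    def test_ties_resolved_conservatively(self):
        null = MaxStatNull(np.array([1.0, 2.0, 3.0, 3.0, 3.0, 4.0, 5.0, 5.0, 6.0, 7.0]), 10, True)
        thr = permutation_threshold(null, 0.2)
        # ceil(0.8 * 10) = 8th smallest = 5.0; only t strictly above 5 is significant
        assert thr == 5.0
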