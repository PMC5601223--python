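"""Single-case GLM, Crawford-Howell oracle, field smoothness and FWE thresholds."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy import stats as sps

from vbmcase.single_case import (
    DesignSpec,
    crawford_howell_t,
    estimate_smoothness_fwhm,
    expected_ec,
    resel_counts,
    rft_critical_t,
    single_case_glm,
    threshold_map,
)


class TestCrawfordHowell:
    def test_worked_example(self):
        t, df = crawford_howell_t(6.0, [1, 2, 3, 4, 5])
        assert t == pytest.approx(1.7321, abs=1e-4)
        assert df == 4

    def test_zero_at_control_mean(self):
        t, _ = crawford_howell_t(3.0, [1, 2, 3, 4, 5])
        assert t == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            crawford_howell_t(1.0, [2.0, 2.0, 2.0])


class TestSingleCaseGlm:
    def test_matches_crawford_howell_voxelwise(self):
        """Covariate-free GLM equals the closed form at every voxel (1e-10)."""
        rng = np.random.default_rng(0)
        controls = rng.standard_normal((8, 9, 9, 9))
        patient = rng.standard_normal((9, 9, 9))
        tmap = single_case_glm(patient, controls)
        assert tmap.df == 7
        expected = np.empty_like(patient)
        for idx in np.ndindex(patient.shape):
            expected[idx] = crawford_howell_t(patient[idx], controls[(slice(None), *idx)])[0]
        assert np.allclose(tmap.t.data, expected, atol=1e-10)

    def test_worked_example_voxel(self):
        controls = np.array([1, 2, 3, 4, 5], dtype=float).reshape(5, 1, 1, 1)
        tmap = single_case_glm(np.full((1, 1, 1), 6.0), controls)
        assert tmap.t.data[0, 0, 0] == pytest.approx(1.7321, abs=1e-4)
        assert tmap.df == 4

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(1)
        controls = rng.standard_normal((6, 4, 4, 4))
        patient = rng.standard_normal((4, 4, 4))
        a = single_case_glm(patient, controls)
        b = single_case_glm(patient + 11.0, controls + 11.0)
        assert np.allclose(a.t.data, b.t.data, atol=1e-10)

    def test_covariate_model_matches_statsmodels(self):
        """With age+TIV covariates the patient-indicator t matches an OLS oracle."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n_c = 12
        controls = rng.standard_normal((n_c, 3, 3, 3))
        patient = rng.standard_normal((3, 3, 3))
        cov = rng.standard_normal((n_c + 1, 2))
        design = DesignSpec(covariates=cov, covariate_names=("age", "tiv"))
        tmap = single_case_glm(patient, controls, design=design)
        assert tmap.df == (n_c + 1) - 4
        for idx in [(0, 0, 0), (1, 2, 0), (2, 2, 2)]:
            y = np.r_[controls[(slice(None), *idx)], patient[idx]]
            x = np.column_stack([np.ones(n_c + 1), np.r_[np.zeros(n_c), 1.0],
                                 cov - cov.mean(0)])
            fit = sm.OLS(y, x).fit()
            assert tmap.t.data[idx] == pytest.approx(fit.tvalues[1], abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(3)
        controls = rng.standard_normal((6, 2, 2, 2))
        patient = rng.standard_normal((2, 2, 2))
        cov = np.ones((7, 1))  # collinear with intercept
        with pytest.raises(ValueError, match="rank-deficient"):
            single_case_glm(patient, controls, design=DesignSpec(covariates=cov))

    def test_too_few_controls_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            single_case_glm(rng.standard_normal((2, 2, 2)),
                            rng.standard_normal((2, 2, 2, 2)))


class TestSmoothness:
    def test_white_noise_fwhm_matches_simulation_oracle(self):
        """i.i.d. residuals: lambda = 2 (unit-variance differences) gives
        FWHM = sqrt(4 ln 2 / 2) ~ 1.18 voxels; estimator within 15% of the
        Monte-Carlo value (clipping at 1 voxel applies below)."""
        rng = np.random.default_rng(5)
        resid = rng.standard_normal((20, 40, 40, 40))
        fwhm = estimate_smoothness_fwhm(resid)
        closed_form = np.sqrt(4 * np.log(2) / 2.0)
        assert np.all(np.abs(fwhm / max(closed_form, 1.0) - 1.0) < 0.15)

    def test_presmoothed_residuals_recover_kernel_fwhm(self):
        rng = np.random.default_rng(6)
        sigma = 2.0
        resid = np.stack([ndi.gaussian_filter(rng.standard_normal((40, 40, 40)), sigma,
                                              mode="wrap") for _ in range(20)])
        fwhm = estimate_smoothness_fwhm(resid)
        expected = sigma * np.sqrt(8 * np.log(2))
        assert np.all(np.abs(fwhm / expected - 1.0) < 0.10)

    def test_anisotropic_smoothing_orders_axes(self):
        rng = np.random.default_rng(7)
        resid = np.stack([ndi.gaussian_filter(rng.standard_normal((40, 40, 40)),
                                              (3.0, 2.0, 1.0), mode="wrap")
                          for _ in range(15)])
        fwhm = estimate_smoothness_fwhm(resid)
        assert fwhm[0] > fwhm[1] > fwhm[2]

    def test_preconditions(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            estimate_smoothness_fwhm(rng.standard_normal((5, 8, 8, 8)))
        with pytest.raises(ValueError):
            estimate_smoothness_fwhm(np.zeros((12, 8, 8, 8)))


class TestRftThreshold:
    def test_single_resel_reduces_to_t_quantile(self):
        crit = rft_critical_t((1, 0, 0, 0), df=20, alpha=0.05)
        assert crit == pytest.approx(sps.t.isf(0.05, 20), abs=1e-5)

    def test_monotone_in_search_volume(self):
        small = rft_critical_t((1.0, 24.0, 192.0, 512.0), df=20, alpha=0.05)
        large = rft_critical_t((1.0, 24.0, 192.0, 1024.0), df=20, alpha=0.05)
        assert large > small

    def test_expected_ec_at_threshold_equals_alpha(self):
        resels = resel_counts(np.ones((32, 32, 32), bool), 6.0)
        crit = rft_critical_t(resels, df=47, alpha=0.05)
        assert expected_ec(crit, resels, 47) == pytest.approx(0.05, abs=1e-4)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            rft_critical_t((1, 0, 0, 0), df=20, alpha=1.5)


class TestThresholdMap:
    def _tmap(self, tail="one_tailed_increase"):
        rng = np.random.default_rng(9)
        controls = rng.standard_normal((21, 16, 16, 16))
        patient = rng.standard_normal((16, 16, 16))
        design = DesignSpec(map_kind="NFSI" if tail == "one_tailed_increase" else "GMC",
                            tail=tail)
        return single_case_glm(patient, controls, design=design)

    def test_uncorrected_critical_t_is_quantile(self):
        tmap = self._tmap()
        cs = threshold_map(tmap, mode="uncorrected", alpha=1e-4)
        assert cs.threshold["critical_t"] == pytest.approx(sps.t.isf(1e-4, tmap.df))
        # every suprathreshold voxel appears in exactly one cluster
        supra = np.argwhere(tmap.t.data > cs.threshold["critical_t"])
        all_vox = np.concatenate([c.voxels for c in cs.clusters]) if cs.clusters else \
            np.empty((0, 3), int)
        assert len(all_vox) == len(supra)
        assert len({tuple(v) for v in all_vox}) == len(all_vox)  # disjoint

    def test_bonferroni_per_voxel_alpha(self):
        tmap = self._tmap()
        n = int(tmap.mask.data.sum())
        cs = threshold_map(tmap, mode="fwe_bonferroni", alpha=0.05)
        assert cs.threshold["critical_t"] == pytest.approx(sps.t.isf(0.05 / n, tmap.df))
        assert 0.05 / 100 == 5e-4  # worked arithmetic: 100 voxels at alpha .05

    def test_fwe_exceeds_uncorrected_at_equal_alpha(self):
        tmap = self._tmap()
        unc = threshold_map(tmap, mode="uncorrected", alpha=0.05)
        bon = threshold_map(tmap, mode="fwe_bonferroni", alpha=0.05)
        rft = threshold_map(tmap, mode="fwe_rft", alpha=0.05, fwhm_vox=(3.0, 3.0, 3.0))
        assert bon.threshold["critical_t"] > unc.threshold["critical_t"]
        assert rft.threshold["critical_t"] > unc.threshold["critical_t"]

    def test_two_tailed_labels_signs(self):
        rng = np.random.default_rng(10)
        controls = rng.standard_normal((21, 12, 12, 12)) * 0.1
        patient = np.zeros((12, 12, 12))
        patient[2, 2, 2] = 5.0
        patient[8, 8, 8] = -5.0
        tmap = single_case_glm(patient, controls,
                               design=DesignSpec(map_kind="GMC", tail="two_tailed"))
        cs = threshold_map(tmap, mode="uncorrected", alpha=1e-4)
        signs = {c.peak_ijk: c.sign for c in cs.clusters}
        assert signs[(2, 2, 2)] == 1 and signs[(8, 8, 8)] == -1

    def test_rft_mode_estimates_smoothness_from_residuals(self):
        """fwe_rft without an explicit FWHM falls back to residual smoothness."""
        tmap = self._tmap()
        cs = threshold_map(tmap, mode="fwe_rft", alpha=0.05)
        unc = threshold_map(tmap, mode="uncorrected", alpha=0.05)
        assert cs.threshold["critical_t"] > unc.threshold["critical_t"]

    def test_null_exceedance_rate_calibrated_on_unsmoothed_maps(self):
        """Uncorrected p<1e-4 on independent-voxel null maps: the per-voxel
        exceedance rate matches 1e-4 within Monte-Carlo error."""
        rng = np.random.default_rng(11)
        exceed, total = 0, 0
        for _ in range(30):
            controls = rng.standard_normal((21, 24, 24, 24))
            patient = rng.standard_normal((24, 24, 24))
            tmap = single_case_glm(patient, controls,
                                   design=DesignSpec(map_kind="NFSI",
                                                     tail="one_tailed_increase"))
            crit = sps.t.isf(1e-4, tmap.df)
            exceed += int((tmap.t.data > crit).sum())
            total += tmap.t.data.size
        rate = exceed / total
        # ~41 expected exceedances; allow generous Monte-Carlo slack
        assert 0.4e-4 < rate < 2.0e-4, f"rate {rate:.2e}"

    def test_min_cluster_filters_small_clusters(self):
        tmap = self._tmap()
        cs_all = threshold_map(tmap, mode="uncorrected", alpha=0.01)
        cs_big = threshold_map(tmap, mode="uncorrected", alpha=0.01, min_cluster=5)
        assert all(c.size >= 5 for c in cs_big.clusters)
        assert len(cs_big) <= len(cs_all)
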