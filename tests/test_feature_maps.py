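"""The four feature maps: smoothing, masking, and the per-map definitions."""

import numpy as np
import pytest

from vbmcase import phantom as ph
from vbmcase.feature_maps import (
    FWHM_TO_SIGMA,
    DegenerateContrastError,
    brain_mask,
    gaussian_smooth,
    gmc_map,
    gmv_map,
    junction_map,
    nfsi_map,
)
from vbmcase.volume import Volume


def _vol(data, voxel=1.5):
    return Volume.from_voxel_size(np.asarray(data, dtype=float), voxel)


class TestGaussianSmooth:
    def test_sigma_from_fwhm(self):
        # 8 mm FWHM -> sigma 3.3972 mm -> 2.2648 voxels at 1.5 mm
        sigma_mm = 8.0 * FWHM_TO_SIGMA
        assert sigma_mm == pytest.approx(3.3972, abs=1e-4)
        assert sigma_mm / 1.5 == pytest.approx(2.2648, abs=1e-4)

    def test_interior_impulse_mass_conserved(self):
        img = np.zeros((33, 33, 33))
        img[16, 16, 16] = 1.0
        out = gaussian_smooth(_vol(img), fwhm_mm=8.0)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-3)

    def test_constant_image_unchanged(self):
        out = gaussian_smooth(_vol(np.full((24, 24, 24), 3.5)), fwhm_mm=6.0)
        interior = out.data[8:-8, 8:-8, 8:-8]
        assert np.allclose(interior, 3.5, atol=1e-6)

    def test_anisotropic_voxels_use_per_axis_sigma(self):
        img = np.zeros((41, 41, 41))
        img[20, 20, 20] = 1.0
        vol = Volume.from_voxel_size(img, (1.0, 2.0, 4.0))
        out = gaussian_smooth(vol, fwhm_mm=8.0).data
        # spread (in voxels) must shrink as voxel size grows
        px = (out[:, 20, 20] > 1e-5).sum()
        pz = (out[20, 20, :] > 1e-5).sum()
        assert px > pz

    def test_invalid_fwhm(self):
        with pytest.raises(ValueError):
            gaussian_smooth(_vol(np.zeros((24, 24, 24))), fwhm_mm=0.0)


class TestBrainMask:
    def test_crisp_segmentation_recovers_template_extent(self, clean_subject, clean_seg):
        mask = brain_mask(clean_seg)
        assert np.array_equal(mask.data.astype(bool), clean_subject.true_labels.data > 0)

    def test_empty_mask_raises(self, clean_seg):
        import copy

        seg = copy.copy(clean_seg)
        zero = clean_seg.grid.like(np.zeros(clean_seg.grid.shape))
        one = clean_seg.grid.like(np.ones(clean_seg.grid.shape))
        seg.probabilities = {"background": one, "csf": zero, "gm": zero, "wm": zero}
        with pytest.raises(ValueError):
            brain_mask(seg)

    def test_threshold_out_of_range(self, clean_seg):
        with pytest.raises(ValueError):
            brain_mask(clean_seg, threshold=1.0)


class TestMapDefinitions:
    def test_all_kinds_zero_outside_mask(self, clean_subject, clean_seg, template):
        mask = brain_mask(clean_seg)
        jac = clean_subject.deformation.jacobian_det
        maps = [
            gmc_map(clean_seg, mask=mask),
            gmv_map(clean_seg, jac, mask=mask),
            junction_map(clean_seg.bias_corrected[0], clean_seg, mask=mask),
        ]
        outside = ~mask.data.astype(bool)
        for fm in maps:
            assert np.all(fm.data.data[outside] == 0)
            assert np.all(fm.source.data[outside] == 0)
            assert fm.fwhm_mm == 8.0

    def test_gmv_equals_gmc_under_identity_deformation(self, clean_subject, clean_seg):
        mask = brain_mask(clean_seg)
        gmc = gmc_map(clean_seg, mask=mask)
        gmv = gmv_map(clean_seg, clean_subject.deformation.jacobian_det, mask=mask)
        assert np.array_equal(gmc.data.data, gmv.data.data)

    def test_gmv_scales_linearly_with_global_shrink(self, clean_seg):
        mask = brain_mask(clean_seg)
        grid = clean_seg.grid
        gmv_1 = gmv_map(clean_seg, grid.like(np.ones(grid.shape)), mask=mask)
        gmv_09 = gmv_map(clean_seg, grid.like(np.full(grid.shape, 0.9)), mask=mask)
        assert gmv_09.source.data.sum() == pytest.approx(0.9 * gmv_1.source.data.sum())

    def test_gmv_rejects_nonpositive_jacobian(self, clean_seg):
        mask = brain_mask(clean_seg)
        grid = clean_seg.grid
        with pytest.raises(ValueError):
            gmv_map(clean_seg, grid.like(np.zeros(grid.shape)), mask=mask)

    def test_modulated_integral_recovers_native_gm_volume(self, template):
        """Change-of-variables: unsmoothed modulated GM integral = native GM volume."""
        for seed in (3, 4):
            subj = ph.sample_subject(
                template, ph.SubjectRecord(f"s{seed}", "control", 30, seed=seed),
                ph.VariabilitySpec(bias_amplitude=0.0, noise_sd_t1=0.0, noise_sd_flair=0.0),
            )
            native_gm = (subj.true_labels.data == ph.GM).astype(float)
            gm_norm = ph.normalize_to_template(subj.true_labels.like(native_gm), subj.deformation)
            modulated = gm_norm.data * subj.deformation.jacobian_det.data
            assert modulated.sum() == pytest.approx(native_gm.sum(), rel=0.02)


class TestJunctionMap:
    def test_zone_interval_from_class_statistics(self, clean_subject, clean_seg):
        """mu_GM=0.45 sd~0, mu_WM=0.75: zone ~ [0.45+, 0.75-]; midpoint 0.60 is in."""
        mask = brain_mask(clean_seg)
        jm = junction_map(clean_seg.bias_corrected[0], clean_seg, mask=mask)
        lo, hi = jm.provenance["zone"]
        assert 0.45 <= lo < hi <= 0.75
        assert lo <= 0.60 <= hi

    def test_interval_arithmetic_and_membership(self):
        """Quoted rule: [mu_GM + 0.5 sd_GM, mu_WM - 0.5 sd_WM] = [0.475, 0.725]."""
        rng = np.random.default_rng(0)
        shape = (32, 32, 32)
        gm = np.zeros(shape, bool)
        wm = np.zeros(shape, bool)
        gm[:, :, :16], wm[:, :, 16:] = True, True
        t1 = np.where(gm, rng.normal(0.45, 0.05, shape), rng.normal(0.75, 0.05, shape))
        t1[16, 16, 15] = 0.60   # inside zone
        t1[16, 16, 14] = 0.45   # at pure GM mean: below zone
        from vbmcase.segmentation import TissueSegmentation

        vol = _vol(t1)
        zeros = vol.like(np.zeros(shape))
        seg = TissueSegmentation(
            probabilities={"background": zeros, "csf": zeros,
                           "gm": vol.like(gm.astype(float)), "wm": vol.like(wm.astype(float))},
            bias_fields=[], bias_corrected=[vol],
            class_means={}, class_sds={}, mixing_weights={},
        )
        mask = vol.like(np.ones(shape, dtype=np.uint8))
        jm = junction_map(vol, seg, mask=mask)
        lo, hi = jm.provenance["zone"]
        mu_gm, sd_gm = t1[gm].mean(), t1[gm].std(ddof=1)
        mu_wm, sd_wm = t1[wm].mean(), t1[wm].std(ddof=1)
        assert lo == pytest.approx(mu_gm + 0.5 * sd_gm) and lo == pytest.approx(0.475, abs=0.01)
        assert hi == pytest.approx(mu_wm - 0.5 * sd_wm) and hi == pytest.approx(0.725, abs=0.01)
        assert jm.source.data[16, 16, 15] == 1.0
        assert jm.source.data[16, 16, 14] == 0.0

    def test_affine_intensity_rescaling_invariance(self, noisy_subject, noisy_seg):
        """The binary zone is invariant to monotone affine T1 rescaling."""
        mask = brain_mask(noisy_seg)
        t1 = noisy_seg.bias_corrected[0]
        jm = junction_map(t1, noisy_seg, mask=mask)
        jm2 = junction_map(t1.like(3.0 * t1.data + 10.0), noisy_seg, mask=mask)
        assert np.array_equal(jm.source.data > 0, jm2.source.data > 0)

    def test_degenerate_contrast_raises(self, clean_seg):
        mask = brain_mask(clean_seg)
        flat = clean_seg.bias_corrected[0].like(np.full(clean_seg.grid.shape, 0.5))
        with pytest.raises(DegenerateContrastError):
            junction_map(flat, clean_seg, mask=mask)

    def test_blur_lesion_peaks_inside_lesion(self, template, noisy_subject):
        from scipy import ndimage as ndi

        from vbmcase.segmentation import segment_em

        center = ph.pick_interface_center(template, 7.0, np.random.default_rng(8))
        spec = ph.LesionSpec(center_mm=center, radius_mm=7.0, junction_blur=1.0)
        t1p, flp, labp, lesion = ph.plant_fcd(noisy_subject.t1, noisy_subject.flair,
                                              noisy_subject.true_labels, spec, template)
        seg = segment_em(t1p, bias_order=2)
        mask = brain_mask(seg)
        jm = junction_map(seg.bias_corrected[0], seg, mask=mask)
        peak = np.unravel_index(np.argmax(jm.data.data), jm.data.shape)
        near_lesion = ndi.binary_dilation(lesion.data.astype(bool), np.ones((3, 3, 3)))
        assert near_lesion[peak]


class TestNfsi:
    def test_zscore_formula(self):
        rng = np.random.default_rng(1)
        shape = (24, 24, 24)
        wm = np.zeros(shape, bool)
        wm[4:20, 4:20, 4:20] = True
        flair = rng.normal(150.0, 10.0, shape)
        flair[5, 5, 5] = 170.0
        from vbmcase.segmentation import TissueSegmentation

        vol = _vol(flair)
        zeros = vol.like(np.zeros(shape))
        seg = TissueSegmentation(
            probabilities={"background": zeros, "csf": zeros, "gm": zeros,
                           "wm": vol.like(wm.astype(float))},
            bias_fields=[], bias_corrected=[vol],
            class_means={}, class_sds={}, mixing_weights={},
        )
        mask = vol.like(np.ones(shape, dtype=np.uint8))
        fm = nfsi_map(vol, seg, mask=mask)
        m, s = fm.provenance["reference_mean"], fm.provenance["reference_sd"]
        assert fm.source.data[5, 5, 5] == pytest.approx((170.0 - m) / s)
        # normalization identity over the reference region
        ref_vals = fm.source.data[wm]
        assert ref_vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert ref_vals.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_global_scaling_invariance(self, noisy_subject, noisy_seg):
        mask = brain_mask(noisy_seg)
        flair = noisy_seg.bias_corrected[0]
        a = nfsi_map(flair, noisy_seg, mask=mask)
        b = nfsi_map(flair.like(7.0 * flair.data), noisy_seg, mask=mask)
        assert np.allclose(a.source.data, b.source.data, atol=1e-10)

    def test_small_reference_region_raises(self, clean_seg):
        mask = brain_mask(clean_seg)
        import copy

        seg = copy.copy(clean_seg)
        probs = dict(clean_seg.probabilities)
        wm = np.zeros(clean_seg.grid.shape)
        wm[:2, :2, :2] = 1.0
        probs["wm"] = clean_seg.grid.like(wm)
        seg.probabilities = probs
        with pytest.raises(ValueError):
            nfsi_map(clean_seg.bias_corrected[0], seg, mask=mask)

    def test_planted_flair_delta_recovered_above_baseline(self, template, noisy_subject):
        """Planted hyperintensity of 3 WM SDs raises the unsmoothed nFSI in the
        lesion by ~3 reference SDs above the same subject's unplanted baseline."""
        from vbmcase.segmentation import segment_em

        center = ph.pick_interface_center(template, 7.0, np.random.default_rng(12))
        spec = ph.LesionSpec(center_mm=center, radius_mm=7.0, flair_delta=3.0)
        _, flp, _, lesion = ph.plant_fcd(noisy_subject.t1, noisy_subject.flair,
                                         noisy_subject.true_labels, spec, template)

        def nfsi_of(flair):
            seg = segment_em([noisy_subject.t1, flair], bias_order=2)
            return nfsi_map(seg.bias_corrected[1], seg, mask=brain_mask(seg))

        planted, baseline = nfsi_of(flp), nfsi_of(noisy_subject.flair)
        inside = lesion.data.astype(bool)
        delta_z = planted.source.data[inside].mean() - baseline.source.data[inside].mean()
        expected = 3.0 * template.flair_sds[ph.WM] / planted.provenance["reference_sd"]
        assert delta_z == pytest.approx(expected, rel=0.25)
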