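"""Parametric-image construction, segmentation, and conventional features."""

import numpy as np
import pytest

from deltasurv.imaging import (ParametricImage, compute_slope, compute_tbr_image,
                               compute_ttp_image, conventional_features, region_ttp,
                               resample_isotropic, resample_mask_isotropic,
                               segment_striatum, segment_tumor, sphere_peak)
from deltasurv.synthetic import PhantomSpec, generate_dynamic_phantom


def _box_mask(shape, sl):
    m = np.zeros(shape, dtype=bool)
    m[sl] = True
    return m


class TestTBR:
    def test_constant_image_self_normalizes_to_one(self):
        img = np.full((4, 4, 4), 2.0)
        mask = _box_mask(img.shape, (slice(0, 2),))
        tbr = compute_tbr_image(img, mask)
        assert np.allclose(tbr.values, 1.0)

    def test_unit_brain_mean_preserves_tumor_value(self):
        img = np.ones((3, 3, 1))
        img[2, 2, 0] = 3.2
        mask = _box_mask(img.shape, (slice(0, 1),))
        tbr = compute_tbr_image(img, mask)
        assert tbr.values[2, 2, 0] == pytest.approx(3.2)

    def test_brain_mean_is_one_after_normalization(self, phantom):
        tbr = compute_tbr_image(phantom.static, phantom.brain_mask, phantom.spacing)
        assert abs(tbr.values[phantom.brain_mask].mean() - 1.0) < 1e-6

    def test_phantom_contrast_recovered_by_direct_division(self, phantom):
        tbr = compute_tbr_image(phantom.static, phantom.brain_mask, phantom.spacing)
        expected = phantom.static / phantom.static[phantom.brain_mask].mean()
        np.testing.assert_allclose(tbr.values, expected)
        assert np.median(tbr.values[phantom.tumor_truth]) == pytest.approx(2.0, abs=0.05)

    def test_scaling_invariance_of_tbr_and_derived_mask(self, phantom):
        tbr1 = compute_tbr_image(phantom.static, phantom.brain_mask, phantom.spacing)
        tbr2 = compute_tbr_image(37.5 * phantom.static, phantom.brain_mask, phantom.spacing)
        np.testing.assert_allclose(tbr1.values, tbr2.values)
        m1, v1 = segment_tumor(tbr1, phantom.tumor_search)
        m2, v2 = segment_tumor(tbr2, phantom.tumor_search)
        assert np.array_equal(m1, m2) and v1 == v2

    def test_empty_or_nonpositive_brain_errors(self):
        img = np.ones((2, 2, 2))
        with pytest.raises(ValueError):
            compute_tbr_image(img, np.zeros_like(img, dtype=bool))
        with pytest.raises(ValueError):
            compute_tbr_image(-img, np.ones_like(img, dtype=bool))


class TestSegmentation:
    def test_tumor_threshold_selects_voxels_at_1p6(self):
        vals = np.array([1.5, 1.7, 2.0]).reshape(3, 1, 1)
        tbr = ParametricImage(vals, (1, 1, 1))
        mask, mtv = segment_tumor(tbr, np.ones_like(vals, dtype=bool))
        assert mask.sum() == 2
        assert mtv == pytest.approx(2 / 1000)

    def test_all_below_threshold_gives_zero_mtv(self):
        tbr = ParametricImage(np.full((2, 2, 2), 1.5), (1, 1, 1))
        mask, mtv = segment_tumor(tbr, np.ones((2, 2, 2), dtype=bool))
        assert not mask.any() and mtv == 0.0

    def test_mtv_equals_count_times_volume_on_phantom(self):
        # 1 mm voxels: MTV in mL must equal voxel count / 1000 exactly
        ph = generate_dynamic_phantom(PhantomSpec(shape=(40, 40, 24),
                                                  spacing=(1.0, 1.0, 1.0),
                                                  tumor_radii_mm=(6.0, 6.0, 6.0)), seed=3)
        tbr = compute_tbr_image(ph.static, ph.brain_mask, ph.spacing)
        mask, mtv = segment_tumor(tbr, ph.tumor_search)
        assert mtv == pytest.approx(mask.sum() / 1000.0)
        assert mask.any()

    def test_striatum_70pct_of_max(self):
        vals = np.array([10.0, 8.0, 6.9]).reshape(3, 1, 1)
        mask = segment_striatum(vals, np.ones_like(vals, dtype=bool))
        assert mask.ravel().tolist() == [True, True, False]

    def test_striatum_constant_region_fully_selected(self):
        vals = np.full((2, 2, 1), 4.0)
        assert segment_striatum(vals, np.ones_like(vals, dtype=bool)).all()

    def test_striatum_matches_brute_force_recount(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(5, 10, size=(6, 6, 4))
        search = np.ones_like(vals, dtype=bool)
        mask = segment_striatum(vals, search)
        assert mask.sum() == int((vals >= 0.7 * vals.max()).sum())


class TestTTP:
    def test_noiseless_peak_at_frame_seven(self):
        times = np.arange(1.0, 31.0)
        tac = 1.0 + np.exp(-0.5 * (times - 7.0) ** 2 / 9.0)
        dyn = np.tile(tac, (2, 2, 2, 1))
        brain = np.zeros((2, 2, 2), dtype=bool)  # flat reference TAC
        brain[0, 0, 0] = True
        dyn[0, 0, 0] = 1.0
        ttp = compute_ttp_image(dyn, times, brain)
        assert np.all(ttp.values[~brain] == 7.0)

    def test_monotone_tac_peaks_at_final_frame(self):
        times = np.arange(1.0, 31.0)
        dyn = np.tile(times / 30.0, (2, 2, 1, 1))
        # brain flat so normalization keeps monotonicity
        brain = np.zeros((2, 2, 1), dtype=bool)
        brain[0, 0, 0] = True
        dyn[0, 0, 0] = 1.0
        ttp = compute_ttp_image(dyn, times, brain)
        assert ttp.values[1, 1, 0] == 30.0

    def test_all_zero_tac_reported_missing(self):
        times = np.arange(1.0, 31.0)
        dyn = np.ones((2, 1, 1, 30))
        dyn[1, 0, 0] = 0.0
        brain = np.zeros((2, 1, 1), dtype=bool)
        brain[0, 0, 0] = True
        ttp = compute_ttp_image(dyn, times, brain)
        assert np.isnan(ttp.values[1, 0, 0])

    def test_ttp_values_live_on_the_frame_grid(self, phantom):
        ttp = compute_ttp_image(phantom.dynamic, phantom.frame_times,
                                phantom.brain_mask, phantom.spacing)
        finite = ttp.values[np.isfinite(ttp.values)]
        assert np.isin(finite, phantom.frame_times).all()

    def test_phantom_tumor_median_ttp_within_one_minute_over_seeds(self):
        for seed in range(5):
            ph = generate_dynamic_phantom(PhantomSpec(noise_sd=0.05), seed=seed)
            ttp = compute_ttp_image(ph.dynamic, ph.frame_times, ph.brain_mask, ph.spacing)
            med = np.median(ttp.values[ph.tumor_truth])
            assert abs(med - ph.spec.tumor_peak_min) <= 1.0, f"seed {seed}: {med}"
        rttp = region_ttp(ph.dynamic, ph.frame_times, ph.tumor_truth, ph.brain_mask)
        assert abs(rttp - ph.spec.tumor_peak_min) <= 1.0


class TestSlope:
    def test_exact_line_recovered(self):
        times = np.arange(1.0, 31.0)
        assert compute_slope(0.01 * times, times) == pytest.approx(0.01)

    def test_constant_tac_has_zero_slope(self):
        times = np.arange(1.0, 31.0)
        assert compute_slope(np.ones(30), times) == pytest.approx(0.0, abs=1e-12)

    def test_ols_recovers_noisy_slope(self):
        times = np.arange(1.0, 31.0)
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            tac = 0.02 * times + rng.normal(0, 0.001, size=30)
            hits += abs(compute_slope(tac, times) - 0.02) < 0.003
        assert hits >= 38  # ~95% coverage of the OLS sampling band


class TestConventional:
    def test_single_voxel_tumor_mean_equals_max(self):
        static = np.ones((4, 4, 4))
        static[2, 2, 2] = 2.5
        brain = _box_mask(static.shape, (slice(0, 1),))
        tumor = np.zeros_like(brain)
        tumor[2, 2, 2] = True
        stri = np.zeros_like(brain)
        stri[3, 3, 3] = True
        times = np.arange(1.0, 31.0)
        dyn = static[..., None] * np.ones(30)
        feats = conventional_features(static, dyn, times, brain, tumor, stri)
        assert feats["conv_TBR_mean"] == pytest.approx(2.5)
        assert feats["conv_TBR_max"] == pytest.approx(2.5)

    def test_tsr_mean_is_tumor_over_striatum(self):
        static = np.ones((6, 6, 2))
        brain = _box_mask(static.shape, (slice(0, 2),))
        tumor = np.zeros_like(brain)
        tumor[3, 0:3, 0] = [1.8, 2.0, 2.2][0] > 0  # placeholder, set below
        tumor[:] = False
        tumor[3, 0, 0] = tumor[3, 1, 0] = tumor[3, 2, 0] = True
        static[3, 0, 0], static[3, 1, 0], static[3, 2, 0] = 1.8, 2.0, 2.2
        stri = np.zeros_like(brain)
        stri[5, 5, 1] = True
        static[5, 5, 1] = 2.0  # striatum mean = 2x brain mean (brain = 1)
        times = np.arange(1.0, 31.0)
        dyn = static[..., None] * np.ones(30)
        feats = conventional_features(static, dyn, times, brain, tumor, stri)
        assert feats["conv_TSR_mean"] == pytest.approx(1.0)

    def test_exactly_nine_conventional_features(self, phantom):
        from deltasurv.imaging import compute_tbr_image

        tbr = compute_tbr_image(phantom.static, phantom.brain_mask, phantom.spacing)
        tumor, _ = segment_tumor(tbr, phantom.tumor_search)
        stri = segment_striatum(phantom.static, phantom.striatum_search)
        feats = conventional_features(phantom.static, phantom.dynamic, phantom.frame_times,
                                      phantom.brain_mask, tumor, stri, phantom.spacing)
        assert len(feats) == 9
        assert feats["conv_TBR_max"] >= feats["conv_TBR_mean"]
        assert feats["conv_MTV"] >= 0

    def test_empty_striatum_flags_tsr_missing(self, phantom):
        tbr = compute_tbr_image(phantom.static, phantom.brain_mask, phantom.spacing)
        tumor, _ = segment_tumor(tbr, phantom.tumor_search)
        empty = np.zeros_like(tumor)
        feats = conventional_features(phantom.static, phantom.dynamic, phantom.frame_times,
                                      phantom.brain_mask, tumor, empty, phantom.spacing)
        assert np.isnan(feats["conv_TSR_mean"]) and np.isnan(feats["conv_TSR_peak"])
        assert len(feats) == 9


class TestResampling:
    def test_identity_for_already_isotropic(self):
        img = ParametricImage(np.random.default_rng(0).random((5, 5, 5)), (1, 1, 1))
        out = resample_isotropic(img)
        np.testing.assert_array_equal(out.values, img.values)

    def test_constant_image_stays_constant(self):
        img = ParametricImage(np.full((4, 4, 4), 3.3), (2, 2, 2))
        out = resample_isotropic(img)
        assert out.values.shape == (7, 7, 7)
        np.testing.assert_allclose(out.values, 3.3)

    def test_linear_ramp_midpoints_average_neighbours(self):
        ramp = np.arange(5, dtype=float)[:, None, None] * np.ones((1, 3, 3))
        img = ParametricImage(ramp, (2.0, 1.0, 1.0))
        out = resample_isotropic(img)
        # new x-grid at 1 mm: positions 1,3,... are midpoints of 2 mm samples
        np.testing.assert_allclose(out.values[1, 0, 0], (ramp[0, 0, 0] + ramp[1, 0, 0]) / 2)
        np.testing.assert_allclose(out.values[3, 0, 0], (ramp[1, 0, 0] + ramp[2, 0, 0]) / 2)

    def test_mask_resampling_is_binary(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        out = resample_mask_isotropic(mask, (2, 2, 2))
        assert out.dtype == bool and out.any()


def test_sphere_peak_on_uniform_region_is_the_constant():
    vals = np.full((10, 10, 10), 2.0)
    mask = _box_mask(vals.shape, (slice(4, 6),))
    assert sphere_peak(vals, mask, (2.0, 2.0, 2.0)) == pytest.approx(2.0)
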