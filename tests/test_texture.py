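"""Radiomics feature checks against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltasurv.texture import (GLCM_DIRECTIONS, discretize,
                               first_order_features, glcm_features, glcm_matrix,
                               local_intensity_peak, morphology_features,
                               radiomics_vector)


def brute_force_glcm(levels, mask, direction, n_levels):
    """Oracle: explicit voxel-pair enumeration for one direction."""
    mat = np.zeros((n_levels, n_levels))
    nx, ny, nz = levels.shape
    dx, dy, dz = direction
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                xx, yy, zz = x + dx, y + dy, z + dz
                if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz and mask[xx, yy, zz]:
                    mat[levels[x, y, z] - 1, levels[xx, yy, zz] - 1] += 1
    mat = mat + mat.T
    return mat / mat.sum() if mat.sum() else mat


def oracle_cluster_prominence(p):
    n = p.shape[0]
    idx = np.arange(1, n + 1)
    mu_i = sum(i * p[i - 1, j - 1] for i in idx for j in idx)
    mu_j = sum(j * p[i - 1, j - 1] for i in idx for j in idx)
    return sum((i + j - mu_i - mu_j) ** 4 * p[i - 1, j - 1] for i in idx for j in idx)


class TestDiscretize:
    def test_floor_rule(self):
        assert discretize(np.array([1.00, 1.05, 1.19]), 0.1).tolist() == [1, 1, 2]

    def test_constant_region_single_level(self):
        assert np.all(discretize(np.full(10, 3.3), 0.1) == 1)

    def test_uniform_values_match_direct_histogram(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, size=5000)
        levels = discretize(vals, 0.1)
        counts = np.bincount(levels)[1:]
        direct = np.histogram(vals - vals.min(), bins=np.arange(0, 1.2, 0.1))[0]
        assert len(np.unique(levels)) == 10
        np.testing.assert_array_equal(counts[:10], direct[:10])

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            discretize(np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            discretize(np.array([]), 0.1)


class TestGLCM:
    def test_constant_region_is_degenerate_zero(self):
        img = np.full((3, 3, 3), 2.0)
        feats = glcm_features(img, np.ones_like(img, dtype=bool), 0.1)
        assert feats["glcm_ClusterProminence"] == 0.0
        assert feats["glcm_InformationCorrelation2"] == 0.0

    def test_matrix_symmetric_and_normalized(self):
        rng = np.random.default_rng(1)
        img = rng.random((4, 4, 3))
        mask = np.ones_like(img, dtype=bool)
        levels = np.zeros(img.shape, dtype=np.int64)
        levels[mask] = discretize(img[mask], 0.1)
        for d in GLCM_DIRECTIONS[:4]:
            p = glcm_matrix(levels, mask, d, levels.max())
            np.testing.assert_allclose(p, p.T)
            assert p.sum() == pytest.approx(1.0)

    def test_imc2_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            img = np.random.default_rng(seed).random((5, 5, 2))
            feats = glcm_features(img, np.ones_like(img, dtype=bool), 0.2)
            assert 0.0 <= feats["glcm_InformationCorrelation2"] <= 1.0

    def test_checkerboard_cluster_prominence_matches_hand_enumeration(self):
        img = np.indices((4, 4, 1)).sum(axis=0) % 2 * 1.0
        mask = np.ones_like(img, dtype=bool)
        levels = np.zeros(img.shape, dtype=np.int64)
        levels[mask] = discretize(img[mask], 1.0)
        expected = []
        for d in GLCM_DIRECTIONS:
            p = brute_force_glcm(levels, mask, d, 2)
            if p.sum() > 0:
                expected.append(oracle_cluster_prominence(p))
        feats = glcm_features(img, mask, 1.0)
        assert feats["glcm_ClusterProminence"] == pytest.approx(np.mean(expected))

    def test_matches_pair_enumeration_oracle_on_random_phantoms(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            img = rng.random((4, 3, 3))
            mask = rng.random(img.shape) > 0.2
            if mask.sum() < 4:
                continue
            levels = np.zeros(img.shape, dtype=np.int64)
            levels[mask] = discretize(img[mask], 0.25)
            n = levels.max()
            for d in GLCM_DIRECTIONS:
                ours = glcm_matrix(levels, mask, d, n)
                oracle = brute_force_glcm(levels, mask, d, n)
                np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_bin_shift_invariance_of_discretized_features(self):
        rng = np.random.default_rng(3)
        img = rng.random((4, 4, 3))
        mask = np.ones_like(img, dtype=bool)
        a = glcm_features(img, mask, 0.1)
        b = glcm_features(img + 117.3, mask, 0.1)
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-9), key


class TestFirstOrder:
    def test_simple_statistics(self):
        img = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        feats = first_order_features(img, np.ones_like(img, dtype=bool), 0.5)
        assert feats["firstorder_Mean"] == 2.0
        assert feats["firstorder_Range"] == 2.0

    def test_constant_region_zero_spread(self):
        img = np.full((3, 3, 1), 5.0)
        feats = first_order_features(img, np.ones_like(img, dtype=bool), 0.1)
        assert feats["firstorder_StdDev"] == 0.0
        assert feats["firstorder_Entropy"] == 0.0

    def test_gaussian_sample_has_near_zero_skewness(self):
        img = np.random.default_rng(4).standard_normal((25, 25, 16))
        feats = first_order_features(img, np.ones_like(img, dtype=bool), 0.1)
        assert abs(feats["firstorder_Skewness"]) < 0.1

    def test_tiny_region_flags_higher_moments(self):
        img = np.array([1.0, 2.0]).reshape(2, 1, 1)
        feats = first_order_features(img, np.ones_like(img, dtype=bool), 0.1)
        assert np.isnan(feats["firstorder_Skewness"])


class TestMorphologyAndPeak:
    def test_volume_is_count_times_voxel_volume(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        feats = morphology_features(np.ones_like(mask, float), mask, (1.0, 1.0, 1.0))
        assert feats["morph_VolumeML"] == pytest.approx(27 / 1000)

    def test_peak_of_constant_image_is_the_constant(self):
        img = np.full((8, 8, 8), 4.2)
        mask = np.zeros_like(img, dtype=bool)
        mask[4, 4, 4] = True
        assert local_intensity_peak(img, mask, (2.0, 2.0, 2.0)) == pytest.approx(4.2)

    def test_delta_spike_matches_sphere_enumeration(self):
        img = np.zeros((15, 15, 15))
        img[7, 7, 7] = 5.0
        mask = np.ones_like(img, dtype=bool)
        spacing = (2.0, 2.0, 2.0)
        radius = (3.0 * 1000.0 / (4 * np.pi)) ** (1 / 3)
        count = sum(
            1
            for dx in range(-4, 5) for dy in range(-4, 5) for dz in range(-4, 5)
            if (dx * 2) ** 2 + (dy * 2) ** 2 + (dz * 2) ** 2 <= radius**2
        )
        assert local_intensity_peak(img, mask, spacing) == pytest.approx(5.0 / count)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6), st.floats(-50, 50))
def test_constant_shift_never_changes_discretized_levels(seed, shift):
    vals = np.random.default_rng(seed).random(50)
    np.testing.assert_array_equal(discretize(vals, 0.07), discretize(vals + shift, 0.07))


def test_radiomics_vector_names_and_ttp_suffix(phantom):
    from deltasurv.imaging import compute_tbr_image, compute_ttp_image, segment_tumor

    tbr = compute_tbr_image(phantom.static, phantom.brain_mask, phantom.spacing)
    ttp = compute_ttp_image(phantom.dynamic, phantom.frame_times, phantom.brain_mask,
                            phantom.spacing)
    tumor, _ = segment_tumor(tbr, phantom.tumor_search)
    vec = radiomics_vector(tbr, ttp, tumor)
    assert any(k.endswith("_TTP") for k in vec)
    assert "glcm_InformationCorrelation2_TTP" in vec
    assert "glcm_ClusterProminence_TTP" in vec
    assert "morph_VolumeML" in vec
    assert all(np.isfinite(v) for v in vec.values())
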