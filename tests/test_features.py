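import numpy as np
import pytest

from petzones.errors import EmptyMaskError
from petzones.features import (
    ALL_FEATURES,
    CATEGORY_COUNTS,
    ExtractionConfig,
    build_matrices,
    diagnostics_features,
    discretize,
    extract_all,
    firstorder_features,
    glcm_features_single,
    glrlm_features_single,
    shape_features,
    texture_features,
)
from petzones.imaging import ROIMask


class TestDiscretize:
    def test_constant_roi_is_single_level(self, vol_mask_factory):
        vol, mask = vol_mask_factory(np.full((3, 3, 3), 2.5))
        gray = discretize(vol, mask)
        assert gray.n_levels == 1
        assert (gray.levels[mask.values] == 1).all()

    def test_equal_width_bin_assignment(self, vol_mask_factory):
        vals = np.linspace(0, 10, 27).reshape(3, 3, 3)
        vals[0, 0, 0], vals[-1, -1, -1] = 0.0, 10.0
        vals[0, 0, 1] = 3.5
        vol, mask = vol_mask_factory(vals)
        gray = discretize(vol, mask, n_bins=10)
        assert gray.levels[0, 0, 1] == 4  # 3.5 in [3, 4)
        assert gray.levels[-1, -1, -1] == 10  # max folds into top level

    def test_matches_per_voxel_binning_oracle(self, vol_mask_factory):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 9, (4, 4, 4))
        mask = rng.random((4, 4, 4)) < 0.8
        vol, m = vol_mask_factory(vals, mask)
        gray = discretize(vol, m, n_bins=8)
        lo, hi = vals[mask].min(), vals[mask].max()
        width = (hi - lo) / 8
        for idx in zip(*np.nonzero(mask)):
            expected = min(int((vals[idx] - lo) // width) + 1, 8)
            assert gray.levels[idx] == expected

    def test_empty_mask_rejected(self, vol_mask_factory):
        vol, m = vol_mask_factory(np.ones((2, 2, 2)), np.zeros((2, 2, 2)))
        with pytest.raises(EmptyMaskError):
            discretize(vol, m)


class TestMatrices:
    def test_constant_roi_glcm_single_cell_and_flat_ngtdm(self, vol_mask_factory):
        vol, mask = vol_mask_factory(np.full((3, 3, 3), 1.0))
        tm = build_matrices(discretize(vol, mask), mask)
        assert tm.glcm_norm.shape == (1, 1)
        assert tm.glcm_norm[0, 0] == 1.0
        assert (tm.ngtdm_s == 0).all()

    def test_hand_enumerated_pair_counts_2x2(self, vol_mask_factory):
        # levels [[1,2],[1,2]] in a 2x2x1 grid
        vals = np.array([[[1.0], [2.0]], [[1.0], [2.0]]])
        vol, mask = vol_mask_factory(vals)
        tm = build_matrices(discretize(vol, mask, n_bins=2), mask)
        # direction (1,0,0): pairs (1,1) and (2,2), symmetric -> 2 each
        d_x = tm.glcm[0]
        assert d_x[0, 0] == 2 and d_x[1, 1] == 2 and d_x[0, 1] == 0
        # direction (0,1,0): pairs (1,2) twice, symmetric -> (1,2)=(2,1)=2
        d_y = tm.glcm[1]
        assert d_y[0, 1] == 2 and d_y[1, 0] == 2 and d_y[0, 0] == 0

    def test_normalized_glcm_symmetric_and_sums_to_one(self, vol_mask_factory):
        rng = np.random.default_rng(4)
        vol, mask = vol_mask_factory(
            rng.uniform(0, 5, (5, 5, 5)), rng.random((5, 5, 5)) < 0.7
        )
        tm = build_matrices(discretize(vol, mask, n_bins=6), mask)
        assert tm.glcm_norm.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(tm.glcm_norm, tm.glcm_norm.T)
        assert (tm.glcm_norm >= 0).all()

    def test_glrlm_weighted_run_total_equals_voxel_count(self, vol_mask_factory):
        rng = np.random.default_rng(6)
        vol, mask = vol_mask_factory(
            rng.uniform(0, 5, (5, 5, 5)), rng.random((5, 5, 5)) < 0.6
        )
        tm = build_matrices(discretize(vol, mask, n_bins=4), mask)
        for M in tm.glrlm:
            weighted = (M * np.arange(1, M.shape[1] + 1)).sum()
            assert weighted == tm.n_voxels


class TestTextureFeatures:
    def test_imc1_complete_dependency_is_minus_one(self):
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert glcm_features_single(p)["glcm_imc1"] == pytest.approx(-1.0)

    def test_imc1_independent_marginals_is_zero(self):
        p = np.outer([0.3, 0.7], [0.3, 0.7])
        assert glcm_features_single(p)["glcm_imc1"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_image_homogeneity_limits(self, vol_mask_factory):
        vol, mask = vol_mask_factory(np.full((3, 3, 3), 2.0))
        feats = texture_features(build_matrices(discretize(vol, mask), mask))
        assert feats["glcm_idn"] == 1.0
        assert feats["glcm_idmn"] == 1.0
        assert feats["ngtdm_Contrast"] == 0.0
        assert feats["glcm_imc1"] == 0.0
        assert feats["glcm_Correlation"] == 0.0
        assert feats["glcm_JointEntropy"] == 0.0

    def test_single_run_line_has_unit_rln_in_run_direction(self, vol_mask_factory):
        vol, mask = vol_mask_factory(np.full((8, 1, 1), 3.0))
        tm = build_matrices(discretize(vol, mask), mask)
        vals = glrlm_features_single(tm.glrlm[0], tm.levels, tm.n_voxels)
        assert vals["glrlm_rln"] == pytest.approx(1.0)

    def test_imc1_bounds_on_random_inputs(self, vol_mask_factory):
        rng = np.random.default_rng(8)
        for _ in range(20):
            vol, mask = vol_mask_factory(
                rng.uniform(0, 5, (4, 4, 4)), rng.random((4, 4, 4)) < 0.8
            )
            if not mask.values.any():
                continue
            feats = texture_features(build_matrices(discretize(vol, mask, n_bins=4), mask))
            assert -1.0 - 1e-9 <= feats["glcm_imc1"] <= 1e-9
            assert 0.0 <= feats["glcm_idmn"] <= 1.0 + 1e-9
            assert 0.0 <= feats["glcm_idn"] <= 1.0 + 1e-9
            assert feats["ngtdm_Contrast"] >= 0.0


class TestFirstOrder:
    def test_constant_roi(self, vol_mask_factory):
        vol, mask = vol_mask_factory(np.full((3, 3, 3), 4.2))
        f = firstorder_features(vol, mask, discretize(vol, mask))
        assert f["firstorder_Mean"] == pytest.approx(4.2)
        assert f["firstorder_Variance"] == 0.0
        assert f["firstorder_Range"] == 0.0
        assert f["firstorder_Uniformity"] == 1.0

    def test_percentile_convention_on_known_values(self, vol_mask_factory):
        vals = np.array([1.0, 2, 3, 4, 5]).reshape(5, 1, 1)
        vol, mask = vol_mask_factory(vals)
        f = firstorder_features(vol, mask, discretize(vol, mask, n_bins=5))
        assert f["firstorder_Median"] == 3.0
        assert f["firstorder_10Percentile"] == pytest.approx(1.4)
        assert f["firstorder_InterquartileRange"] == pytest.approx(2.0)

    def test_order_statistics_ordering(self, vol_mask_factory):
        rng = np.random.default_rng(12)
        vol, mask = vol_mask_factory(rng.uniform(0, 9, (4, 4, 4)))
        f = firstorder_features(vol, mask, discretize(vol, mask))
        assert f["firstorder_Minimum"] <= f["firstorder_Median"] <= f["firstorder_Maximum"]


def _ball_mask(radius_vox, spacing=(1.0, 1.0, 1.0)):
    n = int(2 * radius_vox + 5)
    c = (n - 1) / 2
    X, Y, Z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    return ROIMask(
        (X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 <= radius_vox ** 2, spacing
    )


class TestShape:
    def test_ball_sphericity_approaches_one(self):
        f = shape_features(_ball_mask(20))
        assert f["shape_Sphericity"] == pytest.approx(1.0, abs=0.02)

    def test_ball_surface_volume_ratio_closed_form(self):
        # SVR of a ball of radius r is 3/r
        f = shape_features(_ball_mask(16))
        assert f["shape_SurfaceVolumeRatio"] == pytest.approx(3.0 / 16.0, rel=0.1)

    def test_cube_closed_forms(self):
        cube = np.zeros((16, 16, 16), bool)
        cube[3:13, 3:13, 3:13] = True
        f = shape_features(ROIMask(cube, (1, 1, 1)))
        assert f["shape_Sphericity"] == pytest.approx((np.pi / 6) ** (1 / 3), rel=0.12)
        assert f["shape_SurfaceVolumeRatio"] == pytest.approx(0.6, rel=0.10)
        assert f["shape_VoxelVolume"] == 1000.0

    def test_sphericity_refines_toward_one(self):
        s = [shape_features(_ball_mask(r))["shape_Sphericity"] for r in (4, 8, 16)]
        assert s[0] < s[2] <= 1.0 + 1e-9

    def test_ellipsoid_axis_ratios(self):
        n = 45
        c = (n - 1) / 2
        X, Y, Z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        ell = ((X - c) / 20) ** 2 + ((Y - c) / 10) ** 2 + ((Z - c) / 5) ** 2 <= 1
        f = shape_features(ROIMask(ell, (1, 1, 1)))
        # semi-axes 20:10:5 -> axis lengths about 4:2:1
        assert f["shape_MajorAxisLength"] / f["shape_MinorAxisLength"] == pytest.approx(2.0, rel=0.05)
        assert f["shape_MajorAxisLength"] / f["shape_LeastAxisLength"] == pytest.approx(4.0, rel=0.08)

    def test_mesh_volume_near_voxel_volume_for_large_convex_mask(self):
        f = shape_features(_ball_mask(10))
        assert f["shape_MeshVolume"] == pytest.approx(f["shape_VoxelVolume"], rel=0.10)

    def test_single_voxel_meshes_the_voxel_cube(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        f = shape_features(ROIMask(m, (2, 2, 2)))
        assert f["shape_MeshVolume"] > 0
        assert f["shape_SurfaceArea"] > 0


class TestDiagnostics:
    def test_interpolated_minimum_without_resampling(self, vol_mask_factory):
        vals = np.array([0.2, 0.5, 1.1, 9.0]).reshape(4, 1, 1)
        mask = np.array([True, True, True, False]).reshape(4, 1, 1)
        vol, m = vol_mask_factory(vals, mask)
        d = diagnostics_features(vol, m)
        assert d["diagnostics_Mask-interpolated_Minimum"] == pytest.approx(0.2)
        assert d["diagnostics_Mask-original_VoxelNum"] == 3

    def test_two_blobs_give_two_components(self, vol_mask_factory):
        mask = np.zeros((9, 4, 4), bool)
        mask[0:2, :2, :2] = True
        mask[6:8, :2, :2] = True
        vol, m = vol_mask_factory(np.ones((9, 4, 4)), mask)
        d = diagnostics_features(vol, m)
        assert d["diagnostics_Mask-original_VolumeNum"] == 2
        # brute-force: the two blobs are farther than one step apart
        assert d["diagnostics_Mask-original_VoxelNum"] == mask.sum()


class TestExtractAll:
    def test_exact_feature_set_and_category_counts(self, hot_spot_phantom):
        vol, gland = hot_spot_phantom
        fv = extract_all(vol, gland)
        assert len(fv) == 119
        assert list(fv.entries) == ALL_FEATURES
        assert fv.category_counts() == CATEGORY_COUNTS

    def test_deterministic_for_identical_inputs(self, hot_spot_phantom):
        vol, gland = hot_spot_phantom
        a = extract_all(vol, gland).as_array()
        b = extract_all(vol, gland).as_array()
        np.testing.assert_array_equal(a, b)

    def test_zone1_vector_differs_from_zone3(self, hot_spot_phantom):
        from petzones.segmentation import build_zones

        vol, gland = hot_spot_phantom
        zones = build_zones(vol, gland)
        fv1 = extract_all(vol, zones.zone1)
        fv3 = extract_all(vol, zones.zone3)
        assert fv1["shape_MeshVolume"] != fv3["shape_MeshVolume"]

    def test_all_values_finite_even_on_tiny_masks(self, vol_mask_factory):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        mask[2, 2, 2] = True
        vol, m = vol_mask_factory(np.arange(64, dtype=float).reshape(4, 4, 4), mask)
        fv = extract_all(vol, m)
        assert np.isfinite(fv.as_array()).all()

    def test_resampling_config_feeds_interpolated_diagnostics(self, hot_spot_phantom):
        vol, gland = hot_spot_phantom
        fv = extract_all(vol, gland, ExtractionConfig(resample_spacing=(1.0, 1.0, 1.0)))
        assert fv["diagnostics_Mask-interpolated_VoxelNum"] > fv["diagnostics_Mask-original_VoxelNum"]
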