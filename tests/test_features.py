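"""The 92-feature catalog: shape/histogram/matrix/Gabor features."""

import numpy as np
import pytest

from lipomics.features import (
    FEATURE_CATALOG,
    GABOR_NAMES,
    GLCM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    HIST_NAMES,
    NGTDM_NAMES,
    SHAPE_NAMES,
    ExtractionConfig,
    extract_case,
    gabor_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    histogram_features,
    ngtdm_features,
    shape_features,
)
from lipomics.phantom import VolumeWithMask


class TestCatalog:
    def test_group_sizes_and_total(self):
        groups = [SHAPE_NAMES, HIST_NAMES, GLCM_NAMES, GLRLM_NAMES, GLSZM_NAMES, NGTDM_NAMES, GABOR_NAMES]
        assert [len(g) for g in groups] == [14, 14, 21, 13, 13, 5, 12]
        assert len(FEATURE_CATALOG) == 92
        assert len(set(FEATURE_CATALOG)) == 92


class TestShapeFeatures:
    def test_sphere_sphericity_near_one(self, sphere_volume):
        f = shape_features(sphere_volume.mask, sphere_volume.spacing)
        assert 0.95 <= f["shape_sphericity"] <= 1.005

    def test_box_volume_exact(self):
        mask = np.zeros((10, 12, 14), dtype=bool)
        mask[2:7, 3:9, 4:11] = True  # 5 x 6 x 7 box
        f = shape_features(mask, (2.0, 1.0, 1.5))
        assert f["shape_voxel_count"] == 5 * 6 * 7
        assert f["shape_volume_mm3"] == pytest.approx(5 * 6 * 7 * 3.0)

    def test_prolate_ellipsoid_elongation(self):
        z, y, x = np.mgrid[:50, :30, :30]
        mask = ((z - 25) / 20.0) ** 2 + ((y - 15) / 10.0) ** 2 + ((x - 15) / 10.0) ** 2 <= 1
        f = shape_features(mask, (1.0, 1.0, 1.0))
        assert f["shape_elongation"] == pytest.approx(0.5, rel=0.05)
        assert f["shape_major_axis_length_mm"] > f["shape_least_axis_length_mm"]

    def test_spacing_scales_diameter_and_volume(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        f1 = shape_features(mask, (1.0, 1.0, 1.0))
        f2 = shape_features(mask, (2.0, 2.0, 2.0))
        assert f2["shape_max_3d_diameter_mm"] == pytest.approx(2 * f1["shape_max_3d_diameter_mm"])
        assert f2["shape_volume_mm3"] == pytest.approx(8 * f1["shape_volume_mm3"])

    def test_multi_component_mask_rejected(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[0:2, 0:2, 0:2] = True
        mask[4:6, 4:6, 4:6] = True
        mask[3, 3, 3] = False
        with pytest.raises(ValueError, match="components"):
            shape_features(mask, (1.0, 1.0, 1.0))


class TestHistogramFeatures:
    def test_constant_input_degenerate_values(self):
        f = histogram_features(np.full(50, 3.7))
        assert f["hist_variance"] == pytest.approx(0.0, abs=1e-20)
        assert f["hist_entropy"] == 0
        assert f["hist_uniformity"] == 1
        assert f["hist_skewness"] == 0

    def test_symmetric_input_zero_skewness(self):
        f = histogram_features(np.array([1.0, 2.0, 3.0]))
        assert f["hist_skewness"] == pytest.approx(0.0, abs=1e-12)
        assert f["hist_median"] == 2.0
        assert f["hist_range"] == 2.0

    def test_normal_sample_moments(self, rng):
        x = rng.normal(size=10_000)
        f = histogram_features(x)
        assert f["hist_mean"] == pytest.approx(0.0, abs=0.05)
        assert f["hist_skewness"] == pytest.approx(0.0, abs=0.1)
        assert f["hist_kurtosis"] == pytest.approx(0.0, abs=0.2)  # excess kurtosis
        assert f["hist_energy"] == pytest.approx((x**2).sum())


class TestMatrixFeatures:
    def test_constant_image_glcm_conventions(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        f = glcm_features(P)
        assert f["glcm_energy"] == 1.0
        assert f["glcm_entropy"] == 0.0
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_max_probability"] == 1.0
        assert f["glcm_correlation"] == 1.0  # zero-variance convention

    def test_worked_example_contrast(self):
        # normalized symmetric GLCM of the 2x2 slice [[1,1],[1,2]] at 0 deg
        P = np.array([[0.5, 0.25], [0.25, 0.0]])
        f = glcm_features(P)
        assert f["glcm_contrast"] == pytest.approx(0.5)
        assert f["glcm_energy"] == pytest.approx(0.375)
        assert f["glcm_dissimilarity"] == pytest.approx(0.5)

    def test_glcm_hand_expansion_random_matrix(self, rng):
        raw = rng.random((5, 5))
        P = (raw + raw.T) / (raw + raw.T).sum()
        f = glcm_features(P)
        i = np.arange(1, 6)
        I, J = np.meshgrid(i, i, indexing="ij")
        assert f["glcm_autocorrelation"] == pytest.approx((I * J * P).sum())
        assert f["glcm_contrast"] == pytest.approx(((I - J) ** 2 * P).sum())
        mu = (I * P).sum()
        var = (((I - mu) ** 2) * P).sum()
        assert f["glcm_variance"] == pytest.approx(var)
        assert f["glcm_correlation"] == pytest.approx(((I * J * P).sum() - mu**2) / var)

    def test_run_length_statistics_hand_check(self):
        M = np.zeros((2, 3))
        M[0, 1] = 1  # one run: level 1, length 2
        M[1, 0] = 1  # one run: level 2, length 1
        f = glrlm_features(M, n_voxels=3)
        assert f["glrlm_sre"] == pytest.approx((1 / 4 + 1) / 2)
        assert f["glrlm_lre"] == pytest.approx((4 + 1) / 2)
        assert f["glrlm_run_percentage"] == pytest.approx(2 / 3)
        assert f["glrlm_gln"] == pytest.approx(1.0)

    def test_size_zone_single_zone(self):
        M = np.zeros((3, 100))
        M[1, 99] = 1  # one zone of level 2, size 100
        f = glszm_features(M, n_voxels=100)
        assert f["glszm_zone_percentage"] == pytest.approx(0.01)
        assert f["glszm_lae"] == pytest.approx(100**2)
        assert f["glszm_glv"] == 0.0

    def test_constant_lesion_ngtdm_conventions(self):
        p = np.array([0.0, 1.0, 0.0])
        s = np.zeros(3)
        n = np.array([0.0, 27.0, 0.0])
        f = ngtdm_features(p, s, n)
        assert f["ngtdm_busyness"] == 0.0
        assert f["ngtdm_complexity"] == 0.0
        assert f["ngtdm_coarseness"] == 1e6  # capped
        assert f["ngtdm_contrast"] == 0.0


class TestGaborFeatures:
    def _volume(self, img2d, reps=3):
        vol = np.stack([img2d] * reps)
        mask = np.ones_like(vol, dtype=bool)
        return VolumeWithMask(vol, (1.0, 1.0, 1.0), mask)

    def test_white_noise_orientation_isotropy(self, rng):
        img = rng.normal(size=(48, 48))
        f = gabor_features(self._volume(img))
        means = [f[f"gabor_mean_theta{int(round(np.degrees(t))):03d}"] for t in
                 [k * np.pi / 6 for k in range(6)]]
        assert max(means) / min(means) < 1.35  # no preferred direction

    def test_horizontal_grating_peaks_at_zero_orientation(self):
        x = np.arange(64)
        img = np.tile(np.sin(2 * np.pi * x / 6.0), (64, 1))
        f = gabor_features(self._volume(img))
        names = [f"gabor_mean_theta{d:03d}" for d in (0, 30, 60, 90, 120, 150)]
        vals = [f[n] for n in names]
        assert np.argmax(vals) == 0
        assert vals[0] > 1.5 * max(vals[1:])

    def test_dc_invariance(self, rng):
        img = rng.normal(size=(40, 40))
        f1 = gabor_features(self._volume(img))
        f2 = gabor_features(self._volume(img + 500.0))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-6, abs=1e-9)


class TestExtractCase:
    def test_output_length_and_order(self, small_case):
        f = extract_case(small_case)
        assert list(f) == list(FEATURE_CATALOG)
        assert all(np.isfinite(v) for v in f.values())

    def test_intensity_shift_moves_only_location_features(self, small_case):
        cfg = ExtractionConfig()
        f1 = extract_case(small_case, cfg)
        shifted = VolumeWithMask(
            small_case.intensities + 100.0, small_case.spacing, small_case.mask
        )
        f2 = extract_case(shifted, cfg)
        moved = {"hist_mean", "hist_median", "hist_minimum", "hist_maximum",
                 "hist_p10", "hist_p90", "hist_energy"}
        for name in FEATURE_CATALOG:
            if name in moved:
                assert f2[name] != pytest.approx(f1[name], rel=1e-12)
            elif name.split("_")[0] in ("glcm", "glrlm", "glszm", "ngtdm"):
                # rank-based quantization: texture is shift-invariant
                assert f2[name] == pytest.approx(f1[name], rel=1e-9)
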