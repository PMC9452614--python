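"""Quantization and texture-matrix builders against brute-force oracles."""

import numpy as np
import pytest

from lipomics.preprocessing import ResampledVolume
from lipomics.quantize import (
    DIRECTIONS,
    QuantizedVolume,
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    equal_probability_quantize,
)

from oracles import (
    glcm_oracle,
    glrlm_oracle,
    glszm_oracle,
    ngtdm_oracle,
    quantize_oracle,
    random_masked_levels,
)


def _vol(values, mask=None):
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values, dtype=bool) if mask is None else mask
    return ResampledVolume(values, (1.0, 1.0, 1.0), mask)


class TestEqualProbabilityQuantize:
    def test_forced_equal_split(self):
        v = _vol(np.arange(1, 9, dtype=float).reshape(1, 2, 4))
        q = equal_probability_quantize(v, 4)
        assert q.levels.ravel().tolist() == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_occupancies_equal_for_distinct_values(self):
        rng = np.random.default_rng(0)
        vals = rng.random(1000)
        v = _vol(vals.reshape(10, 10, 10))
        q = equal_probability_quantize(v, 8)
        counts = np.bincount(q.levels.ravel(), minlength=9)[1:]
        assert (counts == 125).all()

    @pytest.mark.parametrize("ng", [2, 3, 5, 8, 16])
    def test_matches_sort_and_split_oracle(self, ng, rng):
        vals = rng.normal(size=200)
        v = _vol(vals.reshape(8, 5, 5))
        q = equal_probability_quantize(v, ng)
        expected = quantize_oracle(vals, ng)
        assert (q.levels.ravel() == expected).all()

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=120).reshape(6, 4, 5)
        q1 = equal_probability_quantize(_vol(vals), 8)
        q2 = equal_probability_quantize(_vol(np.exp(3 * vals) + 7), 8)
        assert (q1.levels == q2.levels).all()

    def test_ties_map_to_lower_level(self):
        # 4 copies of each of 4 values, ng=2: ties straddle the median
        vals = np.repeat([1.0, 2.0, 3.0, 4.0], 4).reshape(1, 4, 4)
        q = equal_probability_quantize(_vol(vals), 2)
        counts = np.bincount(q.levels.ravel(), minlength=3)[1:]
        assert counts.tolist() == [8, 8]

    def test_too_few_distinct_values_raises(self):
        v = _vol(np.repeat([1.0, 2.0], 50).reshape(4, 5, 5))
        with pytest.raises(ValueError, match="distinct"):
            equal_probability_quantize(v, 4)


def _q(levels, ng):
    return QuantizedVolume(np.asarray(levels, dtype=np.int32), ng, np.array([]))


class TestGLCM:
    def test_worked_single_slice_example(self):
        q = _q([[[1, 1], [1, 2]]], 2)
        P = build_glcm(q, 0)
        # horizontal pairs (1,1) and (1,2); symmetrized and normalized
        assert P[0, 0] == pytest.approx(0.5)
        assert P[0, 1] == pytest.approx(0.25)
        assert P[1, 0] == pytest.approx(0.25)
        assert (P**2).sum() == pytest.approx(0.375)

    def test_constant_lesion_single_diagonal_entry(self):
        q = _q(np.ones((2, 4, 4), dtype=int), 3)
        P = build_glcm(q, 45)
        assert P[0, 0] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_matches_enumeration_oracle(self, direction, rng):
        for _ in range(25):
            lev = random_masked_levels(rng, ng=8)
            if (lev > 0).sum() < 4:
                continue
            q = _q(lev, 8)
            try:
                P = build_glcm(q, direction)
            except ValueError:
                continue
            expected = glcm_oracle(lev, 8, direction)
            np.testing.assert_allclose(P, expected, atol=1e-12)

    def test_symmetry_and_normalization(self, rng):
        lev = random_masked_levels(rng, shape=(4, 6, 6), ng=5)
        q = _q(lev, 5)
        P = build_glcm(q, 135)
        np.testing.assert_allclose(P, P.T, atol=0)
        assert P.sum() == pytest.approx(1.0, abs=1e-9)


class TestGLRLM:
    def test_row_run_example(self):
        q = _q([[[1, 1, 2]]], 2)
        M = build_glrlm(q, 0)
        assert M[0, 1] == 1  # level 1, length 2
        assert M[1, 0] == 1  # level 2, length 1
        assert M.sum() == 2

    def test_constant_row_single_run(self):
        q = _q([[[2] * 7]], 2)
        M = build_glrlm(q, 0)
        assert M[1, 6] == 1
        assert M.sum() == 1

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_matches_line_walking_oracle(self, direction, rng):
        for _ in range(25):
            lev = random_masked_levels(rng, ng=6)
            q = _q(lev, 6)
            M = build_glrlm(q, direction)
            expected = glrlm_oracle(lev, 6, direction, M.shape[1])
            np.testing.assert_allclose(M, expected)

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_run_mass_partitions_masked_voxels(self, direction, rng):
        lev = random_masked_levels(rng, shape=(3, 7, 7), ng=4)
        q = _q(lev, 4)
        M = build_glrlm(q, direction)
        lengths = np.arange(1, M.shape[1] + 1)
        assert (M * lengths).sum() == (lev > 0).sum()


class TestGLSZM:
    def test_constant_lesion_single_zone(self):
        lev = np.zeros((5, 6, 6), dtype=int)
        lev[1:4, 1:5, 1:5] = 2
        q = _q(lev, 3)
        M = build_glszm(q)
        size = int((lev == 2).sum())
        assert M[1, size - 1] == 1
        assert M.sum() == 1

    def test_corner_touch_is_one_zone(self):
        lev = np.zeros((2, 2, 2), dtype=int)
        lev[0, 0, 0] = 1
        lev[1, 1, 1] = 1  # touches only at the corner
        M = build_glszm(_q(lev, 1))
        assert M[0, 1] == 1  # one zone of size 2

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(25):
            lev = random_masked_levels(rng, shape=(4, 4, 4), ng=3)
            M = build_glszm(_q(lev, 3))
            zones = glszm_oracle(lev, 3)
            expected = np.zeros_like(M)
            for (lv, size), cnt in zones.items():
                expected[lv - 1, size - 1] = cnt
            np.testing.assert_allclose(M, expected)


class TestNGTDM:
    def test_constant_lesion_zero_differences(self):
        lev = np.full((3, 3, 3), 2, dtype=int)
        p, s, n = build_ngtdm(_q(lev, 3))
        assert s.sum() == 0
        assert p.sum() == pytest.approx(1.0)

    def test_single_bright_centre_voxel(self):
        lev = np.ones((3, 3, 3), dtype=int)
        lev[1, 1, 1] = 2
        p, s, n = build_ngtdm(_q(lev, 2))
        assert s[1] == pytest.approx(1.0)  # |2 - mean(26 ones)| = 1
        ep, es, en = ngtdm_oracle(lev, 2)
        np.testing.assert_allclose(s, es, atol=1e-12)
        np.testing.assert_allclose(p, ep, atol=1e-12)

    def test_matches_neighbourhood_oracle(self, rng):
        for _ in range(25):
            lev = random_masked_levels(rng, ng=5)
            if (lev > 0).sum() == 0:
                continue
            p, s, n = build_ngtdm(_q(lev, 5))
            ep, es, en = ngtdm_oracle(lev, 5)
            np.testing.assert_allclose(p, ep, atol=1e-12)
            np.testing.assert_allclose(s, es, atol=1e-10)
            np.testing.assert_allclose(n, en)


class TestGeometricInvariances:
    def test_slice_order_irrelevant_for_glcm_glrlm(self, rng):
        lev = random_masked_levels(rng, shape=(5, 5, 5), ng=4)
        perm = rng.permutation(5)
        for d in DIRECTIONS:
            np.testing.assert_allclose(
                build_glcm(_q(lev, 4), d), build_glcm(_q(lev[perm], 4), d)
            )
            np.testing.assert_allclose(
                build_glrlm(_q(lev, 4), d), build_glrlm(_q(lev[perm], 4), d)
            )

    def test_translation_invariance_glszm_ngtdm(self, rng):
        lev = np.zeros((6, 8, 8), dtype=int)
        lev[1:4, 1:4, 1:4] = random_masked_levels(rng, shape=(3, 3, 3), ng=3)
        shifted = np.roll(lev, (1, 2, 3), axis=(0, 1, 2))
        np.testing.assert_allclose(build_glszm(_q(lev, 3)), build_glszm(_q(shifted, 3)))
        for a, b in zip(build_ngtdm(_q(lev, 3)), build_ngtdm(_q(shifted, 3))):
            np.testing.assert_allclose(a, b, atol=1e-12)
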