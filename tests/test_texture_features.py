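import numpy as np
import pytest

from ctradiomics.preprocessing import (
    DEFAULT_G_LEVELS,
    IsotropicRoi,
    QuantizedRoi,
    quantize_equal_probability,
)
from ctradiomics.texture_features import (
    DIRECTIONS,
    cooccurrence_matrix,
    first_order,
    glcm_features,
    gliding_box_lacunarity,
    glrlm_features,
    glszm_features,
    lacunarity,
    ngtdm_features,
    ngtdm_table,
    run_length_matrix,
    size_zone_counts,
    size_zone_matrix,
)
from tests.conftest import random_roi, small_quantized
from tests.oracles import brute_glcm, brute_glrlm, brute_glszm_zones, brute_ngtdm


def quantized_from_levels(levels, mask, g):
    return QuantizedRoi(levels, mask, g, np.arange(1, g) + 0.5, 1.0)


def constant_quantized(shape=(4, 4, 3), g=8):
    mask = np.ones(shape, dtype=bool)
    return quantized_from_levels(np.ones(shape, dtype=np.int64), mask, g)


@pytest.fixture
def random_quantized(rng):
    return small_quantized(rng, g=5, shape=(6, 6, 6))


class TestFirstOrder:
    def test_constant_roi(self):
        roi = IsotropicRoi(np.full((5, 5, 3), 12.0), np.ones((5, 5, 3), bool), 1.0)
        f = first_order(roi)
        assert f["entropy"] == 0.0
        assert f["variance"] == 0.0
        assert f["skewness"] == 0.0
        assert f["kurtosis"] == 0.0
        assert f["energy"] == 1.0

    def test_symmetric_bimodal_skewness(self, rng):
        n = 4000
        vals = np.concatenate([np.full(n, -50.0), np.full(n, 50.0)])
        vals += rng.normal(0, 1, size=2 * n)
        vals = np.sort(vals)  # symmetrize pairing exactly: v and -v
        vals = np.concatenate([vals, -vals])
        shape = (len(vals), 1, 1)
        roi = IsotropicRoi(vals.reshape(shape), np.ones(shape, bool), 1.0)
        assert abs(first_order(roi)["skewness"]) < 0.05

    def test_uniform_noise_entropy(self, rng):
        vals = rng.uniform(-1000, 1000, size=100_000)
        shape = (100, 100, 10)
        roi = IsotropicRoi(vals.reshape(shape), np.ones(shape, bool), 1.0)
        entropy = first_order(roi)["entropy"]
        assert abs(entropy - np.log2(256)) / np.log2(256) < 0.02


class TestGlcm:
    def test_constant_roi(self):
        f = glcm_features(constant_quantized())
        assert f["energy"] == 1.0
        assert f["contrast"] == 0.0

    def test_checkerboard_contrast_exact(self):
        # 2-D checkerboard of levels {1,2}: every horizontal pair differs by 1
        x, y = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        levels = ((x + y) % 2 + 1).astype(np.int64)[:, :, None]
        mask = np.ones_like(levels, dtype=bool)
        q = quantized_from_levels(levels, mask, 2)
        p = cooccurrence_matrix(q, (1, 0, 0))
        g = np.arange(1, 3)
        contrast = (p * (g[:, None] - g[None, :]) ** 2).sum()
        assert contrast == 1.0

    def test_normalized_sums_to_one(self, random_quantized):
        for d in DIRECTIONS:
            p = cooccurrence_matrix(random_quantized, d)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        for trial in range(3):
            q = small_quantized(np.random.default_rng(trial), g=4, shape=(6, 5, 4))
            for d in DIRECTIONS:
                ours = cooccurrence_matrix(q, d, normalized=False)
                brute = brute_glcm(
                    np.where(q.mask, q.levels, 0), q.mask, q.n_levels, d
                )
                np.testing.assert_array_equal(ours, brute)


class TestGlrlm:
    def test_constant_line_lre(self):
        levels = np.ones((9, 1, 1), dtype=np.int64)
        mask = np.ones_like(levels, dtype=bool)
        q = quantized_from_levels(levels, mask, 2)
        mat = run_length_matrix(q, (1, 0, 0))
        assert mat.shape[1] == 9
        assert mat[0, 8] == 1 and mat.sum() == 1
        from ctradiomics.texture_features import _glrlm_features_one

        assert _glrlm_features_one(mat, 9)["long_run_emphasis"] == 81.0

    def test_alternating_levels_rp_one(self):
        levels = (np.arange(10) % 2 + 1).astype(np.int64).reshape(10, 1, 1)
        mask = np.ones_like(levels, dtype=bool)
        q = quantized_from_levels(levels, mask, 2)
        mat = run_length_matrix(q, (1, 0, 0))
        assert mat.shape[1] == 1  # all runs length 1
        from ctradiomics.texture_features import _glrlm_features_one

        assert _glrlm_features_one(mat, 10)["run_percentage"] == 1.0

    def test_conservation_identity(self, random_quantized):
        n_voxels = random_quantized.mask.sum()
        for d in DIRECTIONS:
            mat = run_length_matrix(random_quantized, d)
            r = np.arange(1, mat.shape[1] + 1)
            assert (mat * r).sum() == n_voxels

    def test_matches_brute_force(self):
        for trial in range(3):
            q = small_quantized(np.random.default_rng(100 + trial), g=4, shape=(5, 6, 4))
            for d in DIRECTIONS:
                ours = run_length_matrix(q, d)
                brute = brute_glrlm(
                    np.where(q.mask, q.levels, 0), q.mask, q.n_levels, d
                )
                assert ours.shape == brute.shape
                np.testing.assert_array_equal(ours, brute)


class TestGlszm:
    def test_constant_roi_single_zone(self):
        q = constant_quantized(shape=(4, 4, 3))
        f = glszm_features(q)
        n = 4 * 4 * 3
        assert f["zone_percentage"] == pytest.approx(1.0 / n)
        levels, sizes = size_zone_counts(q)
        assert list(sizes) == [n]

    def test_two_blobs_conservation(self):
        levels = np.zeros((12, 6, 6), dtype=np.int64)
        mask = np.zeros_like(levels, dtype=bool)
        levels[0:2, 0:2, 0:2] = 3
        mask[0:2, 0:2, 0:2] = True  # 8 voxels
        levels[6:9, 2:5, 2:5] = 3
        mask[6:9, 2:5, 2:5] = True  # 27 voxels
        q = quantized_from_levels(levels, mask, 4)
        mat = size_zone_matrix(q)
        s = np.arange(1, mat.shape[1] + 1)
        assert (mat * s).sum() == 35.0
        _lv, sizes = size_zone_counts(q)
        assert sorted(sizes) == [8, 27]

    def test_parity_pattern_all_singletons(self):
        x, y, z = np.meshgrid(*[np.arange(4)] * 3, indexing="ij")
        levels = ((x + y + z) % 2 + 1).astype(np.int64)
        # 26-connectivity joins diagonal same-parity voxels, so use a
        # 4-level pattern that separates every voxel from all 26 neighbours
        levels = (x % 2 + 2 * (y % 2) + 1).astype(np.int64)
        levels = levels + 4 * (z % 2)  # 8 interleaved level classes
        mask = np.ones_like(levels, dtype=bool)
        q = quantized_from_levels(levels, mask, 8)
        _lv, sizes = size_zone_counts(q)
        brute = brute_glszm_zones(levels, mask)
        assert sorted(sizes) == sorted(s for _g, s in brute)

    def test_matches_brute_force(self):
        for trial in range(3):
            q = small_quantized(np.random.default_rng(200 + trial), g=3, shape=(6, 6, 5))
            ours = sorted(zip(*size_zone_counts(q)))
            brute = sorted(brute_glszm_zones(np.where(q.mask, q.levels, 0), q.mask))
            assert ours == brute

    def test_conservation_identity(self, random_quantized):
        mat = size_zone_matrix(random_quantized)
        s = np.arange(1, mat.shape[1] + 1)
        assert (mat * s).sum() == random_quantized.mask.sum()


class TestNgtdm:
    def test_constant_roi_zero_contrast(self):
        f = ngtdm_features(constant_quantized())
        assert f["contrast"] == 0.0

    def test_occurrence_conservation(self, random_quantized):
        n_g, _s_g = ngtdm_table(random_quantized)
        # voxels with at least one in-mask 26-neighbour
        from scipy import ndimage

        kernel = np.ones((3, 3, 3))
        kernel[1, 1, 1] = 0
        cnt = ndimage.convolve(
            random_quantized.mask.astype(float), kernel, mode="constant"
        )
        expected = (random_quantized.mask & (cnt > 0)).sum()
        assert n_g.sum() == expected

    def test_matches_brute_force(self):
        for trial in range(3):
            q = small_quantized(np.random.default_rng(300 + trial), g=4, shape=(5, 5, 5))
            n_g, s_g = ngtdm_table(q)
            bn, bs = brute_ngtdm(np.where(q.mask, q.levels, 0), q.mask, q.n_levels)
            np.testing.assert_array_equal(n_g, bn)
            np.testing.assert_allclose(s_g, bs, atol=1e-9)

    def test_contrast_increases_with_noise(self):
        rng = np.random.default_rng(7)
        base = np.tile(np.linspace(0, 100, 12), (12, 10, 1)).transpose(2, 0, 1)
        mask = np.ones_like(base, dtype=bool)
        contrasts = []
        for sd in (1.0, 20.0, 60.0):
            noisy = base + np.random.default_rng(7).normal(0, sd, base.shape)
            roi = IsotropicRoi(noisy, mask, 1.0)
            q = quantize_equal_probability(roi, 8)
            contrasts.append(ngtdm_features(q)["contrast"])
        assert contrasts[0] < contrasts[1] < contrasts[2]


class TestLacunarity:
    def test_solid_cube_unity(self):
        mask = np.ones((12, 12, 12), dtype=bool)
        curve = gliding_box_lacunarity(mask)
        for r, val in curve.items():
            assert abs(val - 1.0) < 0.05, (r, val)

    def test_sparse_exceeds_solid(self, rng):
        solid = np.ones((12, 12, 12), dtype=bool)
        sparse = rng.random((12, 12, 12)) < 0.05
        sparse[0, 0, 0] = sparse[-1, -1, -1] = True  # pin the bounding box
        solid_l2 = gliding_box_lacunarity(solid, [2])[2]
        sparse_l2 = gliding_box_lacunarity(sparse, [2])[2]
        assert sparse_l2 > solid_l2

    def test_translation_invariance(self):
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[2:8, 3:9, 4:10] = True
        shifted = np.roll(mask, (2, 1, 3), axis=(0, 1, 2))
        # bounding-box cropping makes gliding boxes translation invariant
        assert gliding_box_lacunarity(mask) == gliding_box_lacunarity(shifted)
        assert lacunarity(mask) == lacunarity(shifted)


class TestInvariants:
    @pytest.mark.parametrize("g", DEFAULT_G_LEVELS)
    def test_matrix_identities_all_g(self, g, rng):
        roi = random_roi(rng, shape=(10, 9, 8))
        q = quantize_equal_probability(roi, g)
        n_voxels = q.mask.sum()
        for d in DIRECTIONS:
            p = cooccurrence_matrix(q, d)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            mat = run_length_matrix(q, d)
            r = np.arange(1, mat.shape[1] + 1)
            assert (mat * r).sum() == n_voxels
        zmat = size_zone_matrix(q)
        s = np.arange(1, zmat.shape[1] + 1)
        assert (zmat * s).sum() == n_voxels

    def test_level_relabelling_equivariance(self, rng):
        q = small_quantized(rng, g=4, shape=(6, 6, 5))
        # strictly increasing relabelling 1,2,3,4 -> 2,4,6,8 with G=8
        relabelled = quantized_from_levels(
            np.where(q.mask, q.levels * 2, 0), q.mask, 8
        )
        f1, f2 = glrlm_features(q), glrlm_features(relabelled)
        assert f1["gray_level_nonuniformity"] == pytest.approx(
            f2["gray_level_nonuniformity"]
        )
        z1, z2 = glszm_features(q), glszm_features(relabelled)
        assert z1["gray_level_nonuniformity"] == pytest.approx(
            z2["gray_level_nonuniformity"]
        )
        assert z1["zone_size_nonuniformity"] == pytest.approx(
            z2["zone_size_nonuniformity"]
        )
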