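import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ihcloc.engineered_features import (
    GLCM_OFFSETS,
    N_ENGINEERED,
    HaralickConfig,
    dna_features,
    engineered_block_index,
    engineered_column_names,
    featurize_patch,
    glcm,
    haralick_features,
    haralick_stats,
    lbp_features,
    wavelet_subbands,
)
from ihcloc.patching import PatchSet


class TestDnaFeatures:
    def test_perfect_colocalization(self):
        rng = np.random.default_rng(0)
        w = rng.random((16, 16)) + 0.1
        f = dna_features(w, w.copy())
        assert np.allclose(f[[1, 2, 4, 5, 6]], 1.0, atol=1e-9)
        assert abs(f[7]) < 1e-9
        assert np.allclose(f[8:16], 0.0, atol=1e-9)

    def test_disjoint_blobs_have_zero_overlap(self):
        p = np.zeros((16, 16))
        d = np.zeros((16, 16))
        p[2:6, 2:6] = 1.0
        d[10:14, 10:14] = 1.0
        f = dna_features(p, d)
        assert f[1] == 0.0 and f[2] == 0.0

    def test_distance_stats_match_bruteforce(self):
        p = np.zeros((8, 8))
        d = np.zeros((8, 8))
        p[1:3, 1:3] = 1.0
        d[5:7, 4:7] = 1.0
        f = dna_features(p, d)
        diag = np.hypot(8, 8)
        P = np.argwhere(p > 0)
        D = np.argwhere(d > 0)
        dists = np.array([min(np.hypot(*(pp - dd)) for dd in D) for pp in P]) / diag
        assert abs(f[8] - dists.mean()) < 1e-9
        assert abs(f[9] - np.median(dists)) < 1e-9
        assert abs(f[10] - dists.std()) < 1e-9
        assert abs(f[11] - dists.max()) < 1e-9

    def test_empty_masks_imputed_not_nan(self):
        f = dna_features(np.zeros((8, 8)), np.zeros((8, 8)))
        assert np.isfinite(f).all()
        assert np.allclose(f[8:16], 1.0)  # maximal (diagonal) distance


class TestWaveletSubbands:
    def test_subband_count(self):
        assert len(wavelet_subbands(np.random.rand(64, 64), "db4", 5)) == 16

    def test_constant_window_zero_details(self):
        sb = wavelet_subbands(np.full((32, 32), 5.0), "db2", 5)
        for detail in sb[1:]:
            assert np.abs(detail).max() < 1e-9

    def test_haar_2x2_closed_form(self):
        sb = wavelet_subbands(np.array([[1.0, 2.0], [3.0, 4.0]]), "db1", 1)
        # orthonormal Haar: cA=(a+b+c+d)/2, cH=rows-diff/2, cV=cols-diff/2, cD=cross/2
        assert abs(sb[0][0, 0] - 5.0) < 1e-12
        assert abs(sb[1][0, 0] - (-2.0)) < 1e-12
        assert abs(sb[2][0, 0] - (-1.0)) < 1e-12
        assert abs(sb[3][0, 0] - 0.0) < 1e-12

    def test_too_small_window_names_minimum(self):
        with pytest.raises(ValueError, match="32"):
            wavelet_subbands(np.zeros((16, 16)), "db1", 5)


class TestGLCM:
    def test_hand_counted_2x2(self):
        P = glcm(np.array([[0, 0], [1, 1]]), (0, 1), 2)
        assert np.allclose(P, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_window_single_entry(self):
        P = glcm(np.full((4, 4), 3), (0, 1), 8)
        assert P[3, 3] == 1.0 and P.sum() == 1.0

    def test_matches_skimage_for_canonical_offsets(self):
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(0)
        q = rng.integers(0, 8, (16, 16))
        # skimage's angle convention has the row axis pointing down, so its
        # 45-degree offset is (1, 1) — our up-right (-1, 1) is its 135
        angles = {(0, 1): 0.0, (-1, 1): 3 * np.pi / 4, (-1, 0): np.pi / 2,
                  (-1, -1): np.pi / 4}
        for off in GLCM_OFFSETS:
            ours = glcm(q, off, 8)
            theirs = graycomatrix(q.astype(np.uint8), [1], [angles[off]], levels=8,
                                  symmetric=True, normed=True)[:, :, 0, 0]
            assert np.allclose(ours, theirs, atol=1e-12), off

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(arrays(np.int64, (6, 6), elements=st.integers(0, 7)))
    def test_normalization_and_symmetry(self, q):
        P = glcm(q, (0, 1), 8)
        assert abs(P.sum() - 1.0) < 1e-12
        assert np.allclose(P, P.T)


class TestHaralickStats:
    def test_diagonal_glcm_closed_form(self):
        s = haralick_stats(np.diag([0.5, 0.5]))
        energy, contrast, corr, var, hom, sumavg, ent, sument, diffent = s
        assert energy == 0.5 and contrast == 0.0 and abs(ent - 1.0) < 1e-12
        assert abs(corr - 1.0) < 1e-12 and abs(var - 0.25) < 1e-12
        assert hom == 1.0 and abs(sumavg - 1.0) < 1e-12

    def test_uniform_glcm_closed_form(self):
        s = haralick_stats(np.full((2, 2), 0.25))
        assert s[0] == 0.25 and abs(s[6] - 2.0) < 1e-12  # energy, entropy
        assert abs(s[7] - 1.5) < 1e-12  # sum entropy of (0.25, 0.5, 0.25)

    def test_finite_on_random_glcms(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            M = rng.random((8, 8))
            M = (M + M.T)
            M /= M.sum()
            assert np.isfinite(haralick_stats(M)).all()


class TestHaralickFeatures:
    def test_length_576(self):
        v = haralick_features(np.random.default_rng(0).random((64, 64)))
        assert v.shape == (576,)

    def test_constant_window_imputed_not_nan(self):
        v = haralick_features(np.full((64, 64), 2.0))
        assert v.shape == (576,) and np.isfinite(v).all()

    def test_db1_differs_from_db10_on_texture(self):
        rng = np.random.default_rng(3)
        w = rng.random((64, 64))
        a = haralick_features(w, HaralickConfig(wavelet_filter="db1"))
        b = haralick_features(w, HaralickConfig(wavelet_filter="db10"))
        assert np.abs(a - b).max() > 0


class TestLBP:
    def test_constant_window_all_mass_at_255(self):
        h = lbp_features(np.full((7, 7), 4.0))
        assert h[255] == 1.0

    def test_hand_enumerated_5x5(self):
        rng = np.random.default_rng(5)
        w = rng.random((5, 5))
        h = lbp_features(w)
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
        expected = np.zeros(256)
        for r in range(1, 4):
            for c in range(1, 4):
                code = sum((1 << b) for b, (dr, dc) in enumerate(offsets)
                           if w[r + dr, c + dc] >= w[r, c])
                expected[code] += 1
        expected /= expected.sum()
        assert np.allclose(h, expected, atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(arrays(np.float64, (6, 6), elements=st.floats(0, 1, allow_nan=False)))
    def test_histogram_sums_to_one(self, w):
        assert abs(lbp_features(w).sum() - 1.0) < 1e-12


@pytest.fixture(scope="module")
def windows():
    rng = np.random.default_rng(7)
    return rng.random((48, 48)), rng.random((48, 48))


class TestFeaturizePatch:
    def test_length_and_block_layout(self, windows):
        v = featurize_patch(*windows)
        assert v.shape == (N_ENGINEERED,) == (848,)
        idx = engineered_block_index()
        assert idx["dna"] == (0, 16)
        assert idx["har.db4"] == (16, 592)
        assert idx["lbp"] == (592, 848)
        assert len(engineered_column_names()) == 848

    def test_deterministic(self, windows):
        assert np.array_equal(featurize_patch(*windows), featurize_patch(*windows))

    def test_intensity_scale_leaves_texture_blocks_unchanged(self, windows):
        p, d = windows
        a = featurize_patch(p, d)
        b = featurize_patch(3.7 * p, 3.7 * d)
        # LBP and GLCM-derived features are scale-free (per-subband min-max
        # quantization); DNA ratio features are scale-free by construction
        assert np.allclose(a[592:], b[592:], atol=1e-9)
        assert np.allclose(a[16:592], b[16:592], atol=1e-7)
        assert np.allclose(a[:16], b[:16], atol=1e-9)

    def test_no_nan_fuzz_sweep(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            kind = rng.integers(0, 4)
            if kind == 0:
                p = np.zeros((32, 32))
            elif kind == 1:
                p = np.full((32, 32), float(rng.integers(0, 3)))
            else:
                p = rng.random((32, 32)) * rng.choice([1e-8, 1.0, 1e6])
            d = rng.random((32, 32)) if rng.integers(0, 2) else np.zeros((32, 32))
            v = featurize_patch(p, d)
            assert np.isfinite(v).all()


class TestFeaturizeImage:
    def test_single_patch_equals_patch_vector(self):
        rng = np.random.default_rng(0)
        p, d = rng.random((48, 48)), rng.random((48, 48))
        ps = PatchSet(image_ref="x", size=48, coords=[(0, 0)], scores=[1.0],
                      protein_windows=[p], dna_windows=[d])
        from ihcloc.engineered_features import featurize_image

        assert np.allclose(featurize_image(ps), featurize_patch(p, d), atol=1e-12)

    def test_mean_matches_bruteforce_over_35_patches(self):
        from ihcloc.engineered_features import featurize_image

        rng = np.random.default_rng(1)
        prot = [rng.random((32, 32)) for _ in range(35)]
        dna = [rng.random((32, 32)) for _ in range(35)]
        ps = PatchSet(image_ref="x", size=32, coords=[(0, 0)] * 35,
                      scores=[0.0] * 35, protein_windows=prot, dna_windows=dna)
        got = featurize_image(ps)
        expected = np.zeros(848)
        for p, d in zip(prot, dna):
            expected += featurize_patch(p, d)
        expected /= 35
        assert np.allclose(got, expected, atol=1e-10)

    def test_empty_patchset_rejected(self):
        from ihcloc.engineered_features import featurize_image

        ps = PatchSet(image_ref="x", size=32, coords=[], scores=[],
                      protein_windows=[], dna_windows=[])
        with pytest.raises(ValueError, match="empty"):
            featurize_image(ps)
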